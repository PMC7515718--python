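"""Synthetic input generator with planted, parameterised structure.

Everything the pipeline consumes can be generated here: a multi-cell-type
CTCF peak compendium with tunable cross-cell-type conservation, factor peak
sets with a planted fraction of peaks centred on CTCF summits, loops whose
anchors are CTCF sites and whose PET counts optionally depend on planted
"loop-promoting" factors, two-condition loop counts with planted fold
changes, an 18-state-style chromatin segmentation, and TSS/enhancer tracks
with an active-transcription interval track.  Every planted quantity is
returned as a ground-truth table so downstream statistics can be validated
exactly.

Randomness: a single integer seed drives one root ``SeedSequence``;
per-output sub-streams are derived with fixed spawn keys, so adding a new
output never perturbs existing ones and the same seed yields byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    ChromSizes,
    GenomicInterval,
    Loop,
    Peak,
    PeakSet,
    write_bed,
    write_bedpe_loops,
    write_narrowpeak,
)

__all__ = [
    "SimConfig",
    "FactorSpec",
    "STATE18_LABELS",
    "simulate_compendium",
    "simulate_factor",
    "simulate_loops",
    "simulate_conditions",
    "simulate_states_and_ep",
    "simulate_all",
    "write_simulation",
]

#: the 18 segmentation labels of the Roadmap-style chromatin-state model
STATE18_LABELS = [
    "TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "Tx", "TxWk",
    "EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk", "ZNF/Rpts",
    "Het", "TssBiv", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
]

# genome-wide state frequencies, quiescent-dominated like a real segmentation
_STATE_PROBS = np.array(
    [0.02, 0.015, 0.01, 0.01, 0.05, 0.12,
     0.015, 0.015, 0.02, 0.02, 0.05, 0.02,
     0.04, 0.01, 0.015, 0.03, 0.08, 0.46]
)

# fixed spawn keys: one RNG sub-stream per output family
_STREAM_COMPENDIUM = 0
_STREAM_FACTOR_BASE = 100
_STREAM_LOOPS = 200
_STREAM_CONDITIONS = 300
_STREAM_STATES = 400


@dataclass
class FactorSpec:
    """One simulated co-factor: planted co-binding fraction ``f`` and the
    number of extra background peaks placed away from CTCF sites."""

    name: str
    f: float
    n_extra: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"co-binding fraction must be in [0,1], got {self.f}")
        if self.n_extra < 0:
            raise ValueError("n_extra must be >= 0")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate a desk-scale version of the real inputs: two 10 Mb
    chromosomes, 2,000 CTCF sites shared across 4 cell types at 90%
    conservation, lognormal peak signal, 2,000 loops with mean PET ~6 and
    a 2x multiplier per planted promoting factor bound at an anchor.
    """

    seed: int = 0
    genome: ChromSizes = field(
        default_factory=lambda: ChromSizes({"chr1": 10_000_000, "chr2": 10_000_000})
    )
    n_ctcf: int = 2000
    n_cell_types: int = 4
    conservation_prob: float = 0.9
    #: coupling in [0,1] between signal quantile and presence probability;
    #: > 0 plants "conserved sites bind more strongly"
    conservation_signal_coupling: float = 0.0
    signal_mu: float = 3.0
    signal_sigma: float = 1.0
    ctcf_site_width: int = 500
    factor_peak_width: int = 200
    factor_specs: list[FactorSpec] = field(default_factory=list)
    # loop spec
    n_loops: int = 2000
    anchor_width: int = 500
    pet_lam: float = 5.0
    loop_boost: float = 1.0
    promoting_factors: list[str] = field(default_factory=list)
    # two-condition spec
    diff_fraction: float = 0.2
    diff_fold: float = 8.0
    # chromatin states / EP spec
    n_tss: int = 400
    n_enhancers: int = 400
    active_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name, p in [
            ("conservation_prob", self.conservation_prob),
            ("diff_fraction", self.diff_fraction),
            ("active_fraction", self.active_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        for name, n in [
            ("n_ctcf", self.n_ctcf),
            ("n_cell_types", self.n_cell_types),
            ("n_loops", self.n_loops),
            ("n_tss", self.n_tss),
            ("n_enhancers", self.n_enhancers),
        ]:
            if n < 0 or (name in ("n_ctcf", "n_cell_types") and n < 1):
                raise ValueError(f"{name} must be positive, got {n}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "genome" in raw:
            raw["genome"] = ChromSizes({k: int(v) for k, v in raw["genome"].items()})
        if "factor_specs" in raw:
            raw["factor_specs"] = [FactorSpec(**fs) for fs in raw["factor_specs"]]
        return cls(**raw)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))
    )


# ---------------------------------------------------------------------------
# CTCF compendium
# ---------------------------------------------------------------------------

def _master_positions(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Place n_ctcf summits on a jittered grid, >= 1 kb apart, spread over
    chromosomes proportionally to length."""
    chroms = list(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=float)
    counts = np.floor(config.n_ctcf * lengths / lengths.sum()).astype(int)
    for i in range(config.n_ctcf - counts.sum()):
        counts[i % len(chroms)] += 1
    spacing = 2000
    positions: list[tuple[str, int]] = []
    for chrom, n in zip(chroms, counts):
        n_cells = (config.genome[chrom] - spacing) // spacing
        if n > n_cells:
            raise ValueError(f"cannot place {n} CTCF sites on {chrom}: too dense")
        cells = rng.choice(n_cells, size=n, replace=False)
        cells.sort()
        jitter = rng.integers(-500, 501, size=n)
        for cell, j in zip(cells, jitter):
            positions.append((chrom, int(spacing // 2 + cell * spacing + j)))
    return positions


def simulate_compendium(
    config: SimConfig,
    n_cell_types: int | None = None,
    label_prefix: str = "ct",
    stream: int = _STREAM_COMPENDIUM,
):
    """Simulate a multi-cell-type CTCF compendium.

    Returns ``(master_sites, peaksets, presence)``: the master site list
    (one summit-centred Peak per CTCF site), one PeakSet per cell type in
    which each master site appears with probability ``conservation_prob``
    (jittered by <= 50 bp), and the boolean site x cell-type presence truth
    table.
    """
    rng = _rng(config, stream)
    n_ct = n_cell_types if n_cell_types is not None else config.n_cell_types
    positions = _master_positions(config, rng)
    signals = rng.lognormal(config.signal_mu, config.signal_sigma, size=len(positions))

    half = config.ctcf_site_width // 2
    master: list[Peak] = []
    for i, ((chrom, summit), sig) in enumerate(zip(positions, signals)):
        start = max(summit - half, 0)
        end = min(summit + (config.ctcf_site_width - half), config.genome[chrom])
        master.append(
            Peak(GenomicInterval(chrom, start, end), summit - start, float(sig), f"ctcf_{i}")
        )

    # presence probability, optionally coupled to the signal quantile
    probs = np.full(len(master), config.conservation_prob)
    if config.conservation_signal_coupling > 0:
        q = (np.argsort(np.argsort(signals)) + 0.5) / len(signals)
        probs = np.clip(
            probs + config.conservation_signal_coupling * (q - 0.5), 0.0, 1.0
        )

    labels = [f"{label_prefix}{k}" for k in range(n_ct)]
    present = rng.random((len(master), n_ct)) < probs[:, None]
    peaksets: dict[str, PeakSet] = {}
    for k, label in enumerate(labels):
        jitters = rng.integers(-50, 51, size=len(master))
        noise = rng.lognormal(0.0, 0.25, size=len(master))
        peaks: list[Peak] = []
        for i, site in enumerate(master):
            if not present[i, k]:
                continue
            summit = site.summit + int(jitters[i])
            start = max(summit - half, 0)
            end = min(summit + (config.ctcf_site_width - half), config.genome[site.interval.chrom])
            peaks.append(
                Peak(
                    GenomicInterval(site.interval.chrom, start, end),
                    summit - start,
                    float(site.signal * noise[i]),
                    f"ctcf_{i}",
                )
            )
        peaksets[label] = PeakSet(factor="CTCF", cell_type=label, peaks=peaks)

    presence = pd.DataFrame(present, columns=labels)
    presence.index.name = "site"
    return master, peaksets, presence


# ---------------------------------------------------------------------------
# co-factor peak sets
# ---------------------------------------------------------------------------

def simulate_factor(
    config: SimConfig,
    master_sites: list[Peak],
    name: str,
    f: float,
    n_extra: int = 0,
    stream_offset: int = 0,
):
    """Simulate one factor: ``round(f * n_sites)`` peaks centred within
    +/- 50 bp of distinct CTCF summits plus ``n_extra`` background peaks
    placed uniformly with summits > 500 bp from every CTCF summit.

    Returns ``(peakset, truth)`` where *truth* records, per peak, whether it
    was planted on a CTCF site and which site.
    """
    rng = _rng(config, _STREAM_FACTOR_BASE + stream_offset)
    n_planted = int(round(f * len(master_sites)))
    chosen = rng.choice(len(master_sites), size=n_planted, replace=False)
    chosen.sort()

    width = config.factor_peak_width
    half = width // 2
    peaks: list[Peak] = []
    rows: list[tuple[int, bool, int]] = []
    offsets = rng.integers(-50, 51, size=n_planted)
    signals = rng.lognormal(config.signal_mu, config.signal_sigma, size=n_planted + n_extra)
    for j, site_idx in enumerate(chosen):
        site = master_sites[site_idx]
        summit = site.summit + int(offsets[j])
        start = max(summit - half, 0)
        end = min(summit + (width - half), config.genome[site.interval.chrom])
        peaks.append(
            Peak(
                GenomicInterval(site.interval.chrom, start, end),
                summit - start,
                float(signals[j]),
                f"{name}_p{j}",
            )
        )
        rows.append((len(peaks) - 1, True, int(site_idx)))

    # background summits, rejected within 500 bp of any CTCF summit
    summits_by_chrom: dict[str, np.ndarray] = {}
    for site in master_sites:
        summits_by_chrom.setdefault(site.interval.chrom, [])
    for site in master_sites:
        summits_by_chrom[site.interval.chrom].append(site.summit)
    summits_by_chrom = {c: np.sort(np.array(v)) for c, v in summits_by_chrom.items()}

    chroms = list(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=float)
    chrom_probs = lengths / lengths.sum()
    placed = 0
    j = n_planted
    while placed < n_extra:
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
        pos = int(rng.integers(half, config.genome[chrom] - half))
        near = summits_by_chrom.get(chrom)
        if near is not None and near.size:
            k = int(np.searchsorted(near, pos))
            if (k < near.size and abs(int(near[k]) - pos) <= 500) or (
                k > 0 and abs(int(near[k - 1]) - pos) <= 500
            ):
                continue
        peaks.append(
            Peak(
                GenomicInterval(chrom, pos - half, pos + (width - half)),
                half,
                float(signals[j]),
                f"{name}_bg{placed}",
            )
        )
        rows.append((len(peaks) - 1, False, -1))
        placed += 1
        j += 1

    truth = pd.DataFrame(rows, columns=["peak", "planted", "site"]).set_index("peak")
    return PeakSet(factor=name, cell_type="sim", peaks=peaks), truth


def simulate_factors(config: SimConfig, master_sites: list[Peak]):
    """Simulate every factor in ``config.factor_specs``; returns
    ``(dict name -> PeakSet, dict name -> truth table)``."""
    sets: dict[str, PeakSet] = {}
    truths: dict[str, pd.DataFrame] = {}
    for i, spec in enumerate(config.factor_specs):
        ps, truth = simulate_factor(
            config, master_sites, spec.name, spec.f, spec.n_extra, stream_offset=i
        )
        sets[spec.name] = ps
        truths[spec.name] = truth
    return sets, truths


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------

def simulate_loops(
    config: SimConfig,
    master_sites: list[Peak],
    factor_sets: dict[str, PeakSet] | None = None,
):
    """Simulate CTCF loops between master sites.

    Every anchor is a width-resized CTCF site (anchors may be reused);
    PET counts follow ``1 + Poisson(pet_lam)``, multiplied by
    ``loop_boost`` once for each promoting factor with a peak overlapping
    either anchor.  Returns ``(loops, truth)`` with per-loop site indices
    and boost flags per promoting factor.
    """
    rng = _rng(config, _STREAM_LOOPS)
    factor_sets = factor_sets or {}
    half = config.anchor_width // 2

    anchors: list[GenomicInterval] = []
    for site in master_sites:
        start = max(site.summit - half, 0)
        end = min(
            site.summit + (config.anchor_width - half), config.genome[site.interval.chrom]
        )
        anchors.append(GenomicInterval(site.interval.chrom, start, end))

    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(anchors):
        by_chrom.setdefault(iv.chrom, []).append(i)
    usable = {c: idx for c, idx in by_chrom.items() if len(idx) >= 2}
    if config.n_loops > 0 and not usable:
        raise ValueError("need >= 2 CTCF sites on one chromosome to form loops")

    # which promoting factors touch each anchor
    from .pairs import factors_at_anchor  # local import avoids cycle at import time

    promoting = [f for f in config.promoting_factors if f in factor_sets]
    prom_sets = [factor_sets[f] for f in promoting]
    anchor_flags = np.zeros((len(anchors), len(promoting)), dtype=bool)
    if promoting:
        for i, iv in enumerate(anchors):
            bound = factors_at_anchor(iv, prom_sets)
            for j, f in enumerate(promoting):
                anchor_flags[i, j] = f in bound

    chroms = sorted(usable)
    weights = np.array([len(usable[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    loops: list[Loop] = []
    rows = []
    for li in range(config.n_loops):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        ia, ib = rng.choice(len(usable[chrom]), size=2, replace=False)
        sa, sb = usable[chrom][int(ia)], usable[chrom][int(ib)]
        if anchors[sa].start > anchors[sb].start:
            sa, sb = sb, sa
        base = 1 + int(rng.poisson(config.pet_lam))
        boosted = anchor_flags[sa] | anchor_flags[sb]
        n_boost = int(boosted.sum())
        pet = max(1, int(round(base * config.loop_boost**n_boost)))
        loops.append(Loop(anchors[sa], anchors[sb], pet, name=f"loop_{li}"))
        rows.append((li, sa, sb, base, n_boost, *boosted.tolist()))

    truth = pd.DataFrame(
        rows, columns=["loop", "site_a", "site_b", "base_pet", "n_boost", *promoting]
    ).set_index("loop") if rows else pd.DataFrame(
        columns=["loop", "site_a", "site_b", "base_pet", "n_boost", *promoting]
    ).set_index("loop")
    return loops, truth


def simulate_conditions(
    loops: list[Loop],
    config: SimConfig,
    diff_fraction: float | None = None,
    fold: float | None = None,
):
    """Attach two-condition counts (control vs knockdown) to loops.

    Non-differential loops draw both counts from Poisson with the loop's PET
    count as mean; planted differential loops split the fold symmetrically
    (control mean = pet*sqrt(fold), knockdown mean = pet/sqrt(fold)), i.e.
    the loop is decreased in the knockdown.  Returns ``(loops, truth)``.
    """
    rng = _rng(config, _STREAM_CONDITIONS)
    frac = config.diff_fraction if diff_fraction is None else diff_fraction
    fold_ = config.diff_fold if fold is None else fold
    out: list[Loop] = []
    rows = []
    for i, loop in enumerate(loops):
        is_diff = bool(rng.random() < frac)
        base = float(loop.pet_count)
        if is_diff and fold_ != 1.0:
            mu_c, mu_k = base * fold_**0.5, base / fold_**0.5
        else:
            mu_c = mu_k = base
        cc = int(rng.poisson(mu_c))
        ck = int(rng.poisson(mu_k))
        out.append(
            Loop(
                loop.anchor_a,
                loop.anchor_b,
                loop.pet_count,
                count_control=cc,
                count_kd=ck,
                fdr=loop.fdr,
                name=loop.name,
            )
        )
        rows.append((i, is_diff, mu_c, mu_k, cc, ck))
    truth = pd.DataFrame(
        rows, columns=["loop", "planted_diff", "mu_control", "mu_kd", "count_control", "count_kd"]
    ).set_index("loop")
    return out, truth


# ---------------------------------------------------------------------------
# chromatin states, TSS / enhancer tracks
# ---------------------------------------------------------------------------

def simulate_states_and_ep(config: SimConfig):
    """Simulate the chromatin-state segmentation and TSS/enhancer tracks.

    Returns a dict with keys ``states`` (list of (interval, label) tiling
    each chromosome without gaps), ``tss`` (intervals of width 1 at TSS
    positions), ``enhancers``, ``transcribed`` (active-transcription
    intervals covering exactly the active elements) and ``truth`` (per
    element: kind, position, active flag).
    """
    rng = _rng(config, _STREAM_STATES)

    states: list[tuple[GenomicInterval, str]] = []
    for chrom, size in config.genome.items():
        pos = 0
        while pos < size:
            length = int(rng.integers(1000, 20001))
            end = min(pos + length, size)
            label = STATE18_LABELS[int(rng.choice(len(STATE18_LABELS), p=_STATE_PROBS))]
            states.append((GenomicInterval(chrom, pos, end), label))
            pos = end

    # TSS and enhancer centres share one jittered grid (>= 3 kb apart) so
    # candidate regions never collide and the active truth table is exact
    chroms = list(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=float)
    n_total = config.n_tss + config.n_enhancers
    counts = np.floor(n_total * lengths / lengths.sum()).astype(int)
    for i in range(n_total - counts.sum()):
        counts[i % len(chroms)] += 1
    spacing = 3000
    centres: list[tuple[str, int]] = []
    for chrom, n in zip(chroms, counts):
        n_cells = (config.genome[chrom] - spacing) // spacing
        if n > n_cells:
            raise ValueError(f"cannot place {n} elements on {chrom}: too dense")
        cells = rng.choice(n_cells, size=n, replace=False)
        cells.sort()
        jitter = rng.integers(-400, 401, size=n)
        for cell, j in zip(cells, jitter):
            centres.append((chrom, int(spacing // 2 + cell * spacing + j)))
    kinds = np.array(["tss"] * config.n_tss + ["enhancer"] * config.n_enhancers)
    rng.shuffle(kinds)

    active = rng.random(n_total) < config.active_fraction
    tss: list[GenomicInterval] = []
    enhancers: list[GenomicInterval] = []
    transcribed: list[GenomicInterval] = []
    rows = []
    enh_halves = rng.integers(100, 1001, size=n_total)
    for i, ((chrom, centre), kind) in enumerate(zip(centres, kinds)):
        if kind == "tss":
            element = GenomicInterval(chrom, centre, centre + 1)
            tss.append(element)
        else:
            h = int(enh_halves[i])
            element = GenomicInterval(chrom, max(centre - h, 0), centre + h)
            enhancers.append(element)
        if active[i]:
            transcribed.append(GenomicInterval(chrom, max(centre - 100, 0), centre + 100))
        rows.append((i, kind, chrom, centre, bool(active[i])))

    truth = pd.DataFrame(
        rows, columns=["element", "kind", "chrom", "centre", "active"]
    ).set_index("element")
    return {
        "states": states,
        "tss": tss,
        "enhancers": enhancers,
        "transcribed": transcribed,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# orchestration / file emission
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig) -> dict:
    """Run every simulator; returns a dict of all outputs and truth tables."""
    master, ctcf_sets, presence = simulate_compendium(config)
    factor_sets, factor_truth = simulate_factors(config, master)
    loops, loop_truth = simulate_loops(config, master, factor_sets)
    cond_loops, cond_truth = simulate_conditions(loops, config)
    ep = simulate_states_and_ep(config)
    return {
        "master_sites": master,
        "ctcf_sets": ctcf_sets,
        "presence": presence,
        "factor_sets": factor_sets,
        "factor_truth": factor_truth,
        "loops": loops,
        "loop_truth": loop_truth,
        "condition_loops": cond_loops,
        "condition_truth": cond_truth,
        **ep,
    }


def write_simulation(config: SimConfig, outdir) -> dict:
    """Simulate everything and emit narrowPeak/BED/BEDPE files plus one
    ``truth_*.tsv`` per planted structure.  Returns the in-memory results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = simulate_all(config)

    master_set = PeakSet("CTCF", "master", res["master_sites"])
    write_narrowpeak(master_set, outdir / "ctcf_master.narrowPeak")
    (outdir / "compendium").mkdir(exist_ok=True)
    for label, ps in res["ctcf_sets"].items():
        write_narrowpeak(ps, outdir / "compendium" / f"CTCF_{label}.narrowPeak")
    (outdir / "factors").mkdir(exist_ok=True)
    for name, ps in res["factor_sets"].items():
        write_narrowpeak(ps, outdir / "factors" / f"{name}.narrowPeak")
    write_bedpe_loops(res["loops"], outdir / "loops.bedpe")
    write_bedpe_loops(res["condition_loops"], outdir / "loops_conditions.bedpe")
    write_bed(res["states"], outdir / "states.bed")
    write_bed(res["tss"], outdir / "tss.bed")
    write_bed(res["enhancers"], outdir / "enhancers.bed")
    write_bed(res["transcribed"], outdir / "transcribed.bed")
    with open(outdir / "chrom.sizes", "w") as handle:
        for chrom, size in config.genome.items():
            handle.write(f"{chrom}\t{size}\n")

    res["presence"].to_csv(outdir / "truth_presence.tsv", sep="\t")
    for name, truth in res["factor_truth"].items():
        truth.to_csv(outdir / f"truth_factor_{name}.tsv", sep="\t")
    res["loop_truth"].to_csv(outdir / "truth_loops.tsv", sep="\t")
    res["condition_truth"].to_csv(outdir / "truth_conditions.tsv", sep="\t")
    res["truth"].to_csv(outdir / "truth_elements.tsv", sep="\t")
    return res
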