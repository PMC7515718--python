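"""Loop-anchor statistics and the screens built on them.

An anchor is retained only when it contains exactly one CTCF peak, so each
anchor corresponds to one binding site.  Its loop strength is the sum of
PET tag counts over all loops it mediates.  Three screens consume this:

* co-binding vs non-co-binding loop-strength comparison (one-sided Wilcoxon
  rank-sum, Bonferroni-adjusted across factors; the adjusted value is
  reported as "FDR" for continuity with common usage, though it is a
  family-wise correction);
* chromatin-state-stratified Pearson correlation between normalised factor
  binding and log2 loop strength, with a reliability gate that zeroes the
  reported score for small strata or weak evidence;
* the two-condition differential-loop rule (max-count filter, fold change
  on counts + 1, > 2-fold in either direction).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    ChromSizes,
    GenomicInterval,
    Loop,
    Peak,
    PeakSet,
    build_interval_trees,
    overlapping_mask,
    resize_to_summit,
)

__all__ = [
    "Loop",
    "AnchorRecord",
    "FactorLoopTest",
    "STATE_CATEGORY_MAP",
    "STATE_CATEGORIES",
    "assign_unique_ctcf",
    "anchor_loop_strength",
    "cobinding_strength_test",
    "normalize_binding",
    "log2_strength",
    "state_category",
    "stratified_correlation",
    "differential_loops",
    "strength_change_by_binding_change",
]

logger = logging.getLogger(__name__)

#: collapse of the 18 chromatin states into five functional categories
STATE_CATEGORY_MAP = {
    "TssA": "promoter", "TssFlnk": "promoter", "TssFlnkU": "promoter",
    "TssFlnkD": "promoter", "TssBiv": "promoter",
    "EnhG1": "enhancer", "EnhG2": "enhancer", "EnhA1": "enhancer",
    "EnhA2": "enhancer", "EnhWk": "enhancer", "EnhBiv": "enhancer",
    "Tx": "transcription", "TxWk": "transcription",
    "ReprPCWk": "reprPCWk",
}
#: category priority for ties (highest first)
STATE_CATEGORIES = ["promoter", "enhancer", "transcription", "reprPCWk", "quies"]


@dataclass
class AnchorRecord:
    """A retained loop anchor with its unique CTCF peak and statistics."""

    anchor: GenomicInterval
    ctcf_peak: Peak
    loop_strength: int = 0
    cobound_factors: set[str] = field(default_factory=set)
    state_category: str | None = None


@dataclass
class FactorLoopTest:
    """Result of one factor's co-binding loop-strength test."""

    factor: str
    n_cobound: int
    n_noncobound: int
    statistic: float
    p: float
    fdr: float
    passes_screen: bool
    untestable: bool = False


def assign_unique_ctcf(
    anchors: list[GenomicInterval], ctcf: PeakSet
) -> list[AnchorRecord]:
    """Retain anchors containing exactly one CTCF peak.

    Anchors with zero or two-plus contained CTCF peaks are dropped (the
    filter that makes anchor <-> binding site one-to-one); drop counts are
    logged.
    """
    trees = {}
    from intervaltree import IntervalTree

    for peak in ctcf.peaks:
        trees.setdefault(peak.interval.chrom, IntervalTree()).addi(
            peak.interval.start, peak.interval.end, peak
        )
    records: list[AnchorRecord] = []
    n_zero = n_multi = 0
    for anchor in anchors:
        tree = trees.get(anchor.chrom)
        hits = list(tree.overlap(anchor.start, anchor.end)) if tree is not None else []
        if len(hits) == 1:
            records.append(AnchorRecord(anchor=anchor, ctcf_peak=hits[0].data))
        elif not hits:
            n_zero += 1
        else:
            n_multi += 1
    logger.info(
        "assign_unique_ctcf: retained %d anchors, dropped %d (no CTCF) + %d (multiple CTCF)",
        len(records), n_zero, n_multi,
    )
    return records


def anchor_loop_strength(
    records: list[AnchorRecord], loops: list[Loop]
) -> list[AnchorRecord]:
    """Sum PET tag counts of all loops mediated by each anchor.

    Each loop end overlapping the anchor contributes the loop's PET count,
    so a self-looping anchor (both ends overlap it) contributes twice.
    Strengths are written in place and the records returned.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(records):
        rec.loop_strength = 0
        trees.setdefault(rec.anchor.chrom, IntervalTree()).addi(
            rec.anchor.start, rec.anchor.end, i
        )
    for loop in loops:
        for end in (loop.anchor_a, loop.anchor_b):
            tree = trees.get(end.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(end.start, end.end):
                records[hit.data].loop_strength += loop.pet_count
    return records


def cobinding_strength_test(
    records: list[AnchorRecord],
    factor: str,
    factor_peaks: PeakSet,
    n_factors_tested: int = 1,
    resize_width: int = 200,
    sizes: ChromSizes | None = None,
    alternative: str = "greater",
    exact_max_n: int = 60,
) -> FactorLoopTest:
    """Compare loop strength between factor co-bound and non-co-bound anchors.

    Anchors are partitioned by whether their CTCF peak (summit-resized to
    ``resize_width``, the screening convention) overlaps a factor peak, and
    a one-sided Wilcoxon rank-sum test (co-bound greater) is applied.  The
    reported ``fdr`` is the Bonferroni-adjusted p-value, min(1, p * number
    of factors tested); the screen gate is -log10(fdr) >= 20.  An empty
    stratum yields an untestable result (excluded from the screen).

    The exact null distribution is used when both strata have at most
    ``exact_max_n`` anchors, which makes extreme separations resolvable far
    below the asymptotic tail.
    """
    ctcf_regions = [
        resize_to_summit(rec.ctcf_peak, resize_width, sizes).interval for rec in records
    ]
    factor_resized = [resize_to_summit(p, resize_width, sizes) for p in factor_peaks.peaks]
    cobound_mask = overlapping_mask(ctcf_regions, factor_resized)
    strengths = np.array([rec.loop_strength for rec in records], dtype=float)
    mask = np.asarray(cobound_mask)
    for rec, hit in zip(records, mask):
        if hit:
            rec.cobound_factors.add(factor)
    cobound = strengths[mask]
    noncobound = strengths[~mask]
    if cobound.size == 0 or noncobound.size == 0:
        return FactorLoopTest(
            factor=factor,
            n_cobound=int(cobound.size),
            n_noncobound=int(noncobound.size),
            statistic=float("nan"),
            p=float("nan"),
            fdr=float("nan"),
            passes_screen=False,
            untestable=True,
        )
    method = "exact" if max(cobound.size, noncobound.size) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(cobound, noncobound, alternative=alternative, method=method)
    p = float(res.pvalue)
    fdr = min(1.0, p * n_factors_tested)
    neglog = -math.log10(fdr) if fdr > 0 else math.inf
    return FactorLoopTest(
        factor=factor,
        n_cobound=int(cobound.size),
        n_noncobound=int(noncobound.size),
        statistic=float(res.statistic),
        p=p,
        fdr=fdr,
        passes_screen=bool(neglog >= 20),
    )


def normalize_binding(read_count: float, region_length: int) -> float:
    """Depth/length-normalised log2 binding: log2(count * 1e9 / (length * 1e6)).

    A zero count takes a +1 pseudocount so the logarithm is defined.
    """
    if region_length <= 0:
        raise ValueError("region length must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    count = read_count if read_count > 0 else 1.0
    return math.log2(count * 1e9 / (region_length * 1e6))


def log2_strength(strength: float) -> float:
    """log2 loop strength with the same zero-handling pseudocount rule."""
    return math.log2(strength if strength > 0 else 1.0)


def state_category(
    site: GenomicInterval, segments: list[tuple[GenomicInterval, str]]
) -> str:
    """Collapse 18-state labels to 5 categories and pick by max base overlap.

    Ties (and zero overlap) resolve by the fixed priority
    promoter > enhancer > transcription > reprPCWk > quies.
    """
    cover = dict.fromkeys(STATE_CATEGORIES, 0)
    for iv, label in segments:
        if iv.chrom != site.chrom:
            continue
        bases = min(iv.end, site.end) - max(iv.start, site.start)
        if bases > 0:
            cover[STATE_CATEGORY_MAP.get(label, "quies")] += bases
    return max(STATE_CATEGORIES, key=lambda c: (cover[c], -STATE_CATEGORIES.index(c)))


def annotate_state_categories(
    records: list[AnchorRecord], segments: list[tuple[GenomicInterval, str]]
) -> list[AnchorRecord]:
    """Assign each anchor's CTCF site a collapsed chromatin-state category."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for iv, label in segments:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, label)
    for rec in records:
        site = rec.ctcf_peak.interval
        tree = trees.get(site.chrom)
        local = (
            [(GenomicInterval(site.chrom, h.begin, h.end), h.data)
             for h in tree.overlap(site.start, site.end)]
            if tree is not None
            else []
        )
        rec.state_category = state_category(site, local)
    return records


def stratified_correlation(
    records: list[AnchorRecord],
    binding: np.ndarray,
    n_tests: int = 1,
    min_n: int = 1000,
    max_p: float = 0.01,
) -> pd.DataFrame:
    """Per-category Pearson correlation of binding vs log2 loop strength.

    *binding* holds one normalised binding value per record.  Per category
    the Pearson r and p are computed, p is Bonferroni-adjusted by
    ``n_tests``, and the reported score -log10(p_adj) is forced to exactly
    0.0 whenever the stratum has fewer than ``min_n`` anchors or the raw p
    exceeds ``max_p`` (the reliability gate).
    """
    binding = np.asarray(binding, dtype=float)
    if binding.shape[0] != len(records):
        raise ValueError("binding values must align with anchor records")
    strengths = np.array([log2_strength(r.loop_strength) for r in records])
    cats = np.array([r.state_category or "quies" for r in records])
    rows = []
    for cat in STATE_CATEGORIES:
        sel = cats == cat
        n = int(sel.sum())
        if n < 2 or np.ptp(binding[sel]) == 0 or np.ptp(strengths[sel]) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(binding[sel], strengths[sel])
        p_adj = min(1.0, p * n_tests) if not math.isnan(p) else float("nan")
        if n < min_n or math.isnan(p) or p > max_p:
            reported = 0.0
        else:
            reported = -math.log10(max(p_adj, 1e-300))
        rows.append(
            {"category": cat, "n": n, "r": r, "p": p, "p_adj": p_adj,
             "reported_score": reported}
        )
    return pd.DataFrame(rows)


def differential_loops(
    loops: list[Loop], min_max: int = 2, fold_threshold: float = 2.0
) -> pd.DataFrame:
    """Apply the two-condition differential-loop rule.

    Loops where max(count_control, count_kd) < ``min_max`` are filtered;
    the fold change is (control + 1) / (kd + 1) and a loop is differential
    iff the change exceeds ``fold_threshold`` in either direction (strict).
    Returns one row per loop with columns ``status`` (filtered / stable /
    differential) and ``direction`` (down = decreased in knockdown).
    """
    rows = []
    for i, loop in enumerate(loops):
        if loop.count_control is None or loop.count_kd is None:
            raise ValueError(f"loop {loop.name or i} lacks per-condition counts")
        cc, ck = loop.count_control, loop.count_kd
        fc = (cc + 1) / (ck + 1)
        if max(cc, ck) < min_max:
            status, direction = "filtered", "none"
        elif fc > fold_threshold:
            status, direction = "differential", "down"
        elif 1.0 / fc > fold_threshold:
            status, direction = "differential", "up"
        else:
            status, direction = "stable", "none"
        rows.append(
            {
                "loop": loop.name or str(i),
                "count_control": cc,
                "count_kd": ck,
                "fold_change": fc,
                "status": status,
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["loop", "count_control", "count_kd", "fold_change", "status", "direction"],
    )


DEFAULT_FC_BIN_EDGES = (-1.0, -math.log2(1.2), math.log2(1.2), 1.0)


def strength_change_by_binding_change(
    binding_log2fc,
    strength_fc,
    bin_edges: tuple[float, ...] = DEFAULT_FC_BIN_EDGES,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Loop-strength fold-change distributions, binned by CTCF-binding change.

    Anchors are binned by their binding log2 fold change at ``bin_edges``
    (defaults: +/- 2-fold and +/- 1.2-fold), and the per-bin loop-strength
    fold-change distributions are compared pairwise with two-sided Wilcoxon
    rank-sum tests.  With fewer than two occupied bins no tests run and a
    warning is raised.
    """
    binding_log2fc = np.asarray(binding_log2fc, dtype=float)
    strength_fc = np.asarray(strength_fc, dtype=float)
    if binding_log2fc.shape != strength_fc.shape:
        raise ValueError("binding and strength arrays must align")
    edges = np.asarray(bin_edges, dtype=float)
    labels = []
    prev = "-inf"
    for e in edges:
        labels.append(f"({prev}, {e:g}]")
        prev = f"{e:g}"
    labels.append(f"({prev}, inf)")
    idx = np.digitize(binding_log2fc, edges, right=True)
    groups = {
        labels[b]: strength_fc[idx == b] for b in range(len(labels)) if (idx == b).any()
    }
    if len(groups) < 2:
        warnings.warn("fewer than two occupied binding-change bins; no tests run",
                      stacklevel=2)
        return groups, pd.DataFrame(
            columns=["bin1", "bin2", "n1", "n2", "median1", "median2", "statistic", "p"]
        )
    rows = []
    for (l1, v1), (l2, v2) in itertools.combinations(groups.items(), 2):
        res = stats.mannwhitneyu(v1, v2, alternative="two-sided")
        rows.append(
            {
                "bin1": l1, "bin2": l2, "n1": int(v1.size), "n2": int(v2.size),
                "median1": float(np.median(v1)), "median2": float(np.median(v2)),
                "statistic": float(res.statistic), "p": float(res.pvalue),
            }
        )
    return groups, pd.DataFrame(rows)
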