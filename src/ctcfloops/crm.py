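"""Candidate regulatory modules (CRMs) and their co-binding structure.

A CRM is the merge of all summit-resized factor peaks that chain together
by overlap; the set of factors with a peak inside the region describes its
co-binding pattern.  CTCF CRMs (exactly one CTCF peak, optionally with
cohesin and ChIA-PET support) are clustered by co-binding into
dense / medium / light / CTCF-solo groups, and CTCF signal or anchor loop
strength is compared across groups with Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .intervals import (
    ChromSizes,
    GenomicInterval,
    Peak,
    PeakSet,
    overlapping_mask,
    resize_to_summit,
)

__all__ = [
    "CRM",
    "COHESIN_FACTORS",
    "build_crms",
    "select_ctcf_crms",
    "width_percentile_interval",
    "cluster_crms",
    "compare_groups",
]

#: cohesin-complex subunit names recognised by default
COHESIN_FACTORS = frozenset(
    {"RAD21", "SMC1", "SMC1A", "SMC3", "SA1", "SA2", "STAG1", "STAG2"}
)

GROUP_LABELS_4 = ["dense", "medium", "light", "ctcf_solo"]


@dataclass
class CRM:
    """A merged regulatory region with its co-binding membership."""

    region: GenomicInterval
    member_factors: set[str] = field(default_factory=set)
    ctcf_peaks: list[Peak] = field(default_factory=list)
    has_cohesin: bool = False
    overlaps_chiapet: bool = False
    group_label: str = "unassigned"
    #: max member-peak signal per factor (fuels the signal-matrix variant)
    factor_signals: dict[str, float] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.region.length

    @property
    def n_cobinding(self) -> int:
        """Number of non-CTCF member factors."""
        return len(self.member_factors - {"CTCF"})


def build_crms(
    all_factor_sets: list[PeakSet],
    peak_width: int = 100,
    sizes: ChromSizes | None = None,
    ctcf_factor: str = "CTCF",
    cohesin_factors: frozenset[str] = COHESIN_FACTORS,
    chiapet_peaks: list[Peak] | None = None,
) -> list[CRM]:
    """Merge width-resized peaks from all factors into CRMs.

    Every input peak lands in exactly one CRM (the merge is a partition of
    the resized peaks); member factors, contained CTCF peaks and the
    cohesin / ChIA-PET annotations are populated during the sweep.
    """
    events: list[tuple[str, int, int, str, Peak]] = []
    for ps in all_factor_sets:
        for peak in ps.peaks:
            rp = resize_to_summit(peak, peak_width, sizes)
            iv = rp.interval
            events.append((iv.chrom, iv.start, iv.end, ps.factor, rp))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    crms: list[CRM] = []
    cur: list[tuple[str, Peak]] = []
    cur_chrom, cur_start, cur_end = None, 0, 0

    def _flush() -> None:
        if not cur:
            return
        crm = CRM(region=GenomicInterval(cur_chrom, cur_start, cur_end))
        for factor, peak in cur:
            crm.member_factors.add(factor)
            prev = crm.factor_signals.get(factor)
            if prev is None or peak.signal > prev:
                crm.factor_signals[factor] = peak.signal
            if factor == ctcf_factor:
                crm.ctcf_peaks.append(peak)
            if factor in cohesin_factors:
                crm.has_cohesin = True
        crms.append(crm)

    for chrom, start, end, factor, peak in events:
        if cur and chrom == cur_chrom and start <= cur_end:
            cur_end = max(cur_end, end)
            cur.append((factor, peak))
        else:
            _flush()
            cur = [(factor, peak)]
            cur_chrom, cur_start, cur_end = chrom, start, end
    _flush()

    if chiapet_peaks is not None:
        hits = overlapping_mask([c.region for c in crms], chiapet_peaks)
        for crm, hit in zip(crms, hits):
            crm.overlaps_chiapet = hit
    return crms


def select_ctcf_crms(
    crms: list[CRM],
    require_cohesin: bool = False,
    require_chiapet: bool = False,
) -> list[CRM]:
    """CTCF CRMs: exactly one CTCF peak, optional cohesin/ChIA-PET support."""
    out = [c for c in crms if len(c.ctcf_peaks) == 1]
    if require_cohesin:
        out = [c for c in out if c.has_cohesin]
    if require_chiapet:
        out = [c for c in out if c.overlaps_chiapet]
    return out


def width_percentile_interval(
    crms: list[CRM], central_mass: float = 0.90
) -> tuple[float, float]:
    """Symmetric percentile interval of CRM widths covering *central_mass*
    (default the central 90%, i.e. the 5th and 95th percentiles)."""
    if not crms:
        raise ValueError("no CRMs given")
    if not 0.0 < central_mass <= 1.0:
        raise ValueError("central_mass must be in (0, 1]")
    widths = np.array([c.width for c in crms], dtype=float)
    tail = (1.0 - central_mass) / 2.0 * 100.0
    low, high = np.percentile(widths, [tail, 100.0 - tail])
    return float(low), float(high)


def membership_matrix(
    crms: list[CRM], factor_panel: list[str], use_signal: bool = False
) -> pd.DataFrame:
    """CRM x factor matrix: binary membership (default) or, with
    ``use_signal``, the maximum member-peak signal per factor."""
    mat = np.zeros((len(crms), len(factor_panel)), dtype=float)
    index = {f: j for j, f in enumerate(factor_panel)}
    for i, crm in enumerate(crms):
        for f in crm.member_factors:
            j = index.get(f)
            if j is not None:
                mat[i, j] = crm.factor_signals.get(f, 1.0) if use_signal else 1.0
    return pd.DataFrame(mat, columns=factor_panel)


def cluster_crms(
    crms: list[CRM],
    factor_panel: list[str],
    k: int = 4,
    use_signal: bool = False,
) -> list[str]:
    """Group CRMs by co-binding pattern with Ward hierarchical clustering.

    The CRM x factor binary matrix is clustered (Ward linkage, Euclidean),
    the tree cut at *k*, and clusters relabelled by descending mean
    co-binding count: dense > medium > light > ctcf_solo for k = 4.
    Labels are written onto ``crm.group_label`` and returned.
    """
    if not factor_panel:
        raise ValueError("factor panel must be non-empty")
    if len(crms) < k:
        raise ValueError(f"need >= {k} CRMs to form {k} clusters, got {len(crms)}")
    mat = membership_matrix(crms, factor_panel, use_signal=use_signal).to_numpy()
    Z = linkage(mat, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    found = np.unique(raw)
    if found.size < k:
        raise ValueError(
            f"only {found.size} distinct clusters reachable (degenerate rows), needed {k}"
        )
    counts = (mat > 0).sum(axis=1)
    # order clusters by descending mean co-binding count; cluster id breaks ties
    order = sorted(found, key=lambda c: (-counts[raw == c].mean(), c))
    names = GROUP_LABELS_4 if k == 4 else [f"group{i + 1}" for i in range(k)]
    mapping = {c: names[i] for i, c in enumerate(order)}
    labels = [mapping[c] for c in raw]
    for crm, label in zip(crms, labels):
        crm.group_label = label
    return labels


def compare_groups(
    values, labels, group_order: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between label groups.

    *values* is one number per CRM (CTCF signal or anchor loop strength).
    Pairs with an empty group are skipped with a warning.  Returns a table
    with group names, sizes, medians, the statistic and the p-value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must align")
    groups = group_order or list(dict.fromkeys(labels.tolist()))
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        v1 = values[labels == g1]
        v2 = values[labels == g2]
        if v1.size == 0 or v2.size == 0:
            warnings.warn(f"skipping pair ({g1}, {g2}): empty group", stacklevel=2)
            continue
        res = stats.mannwhitneyu(v1, v2, alternative="two-sided")
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "n1": int(v1.size),
                "n2": int(v2.size),
                "median1": float(np.median(v1)),
                "median2": float(np.median(v2)),
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group1", "group2", "n1", "n2", "median1", "median2", "statistic", "p"],
    )
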