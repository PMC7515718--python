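"""Factor-vs-CTCF overlap-ratio screen.

For each factor ChIP-seq dataset the screen reports the fraction of
reference CTCF sites that are co-bound: reference sites and factor peaks
are summit-resized to 200 bp, the factor's peaks are capped at the top
100,000 by signal, and the ratio is (reference sites hit) / (reference
sites).  Factors are ranked by their maximum ratio over datasets, and
hscCTCF-based ratios can be regressed against genome-wide top-K ratios to
check that the conserved-site screen is a faithful proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    ChromSizes,
    Peak,
    PeakSet,
    count_overlapping,
    resize_to_summit,
)

__all__ = ["OverlapRecord", "overlap_ratio", "rank_factors", "ratio_scaling",
           "select_max_peak_dataset"]


@dataclass(frozen=True)
class OverlapRecord:
    """One dataset's overlap with the reference CTCF sites."""

    factor: str
    dataset_id: str
    cell_type: str
    n_reference: int
    n_overlapped: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_overlapped <= self.n_reference:
            raise ValueError("n_overlapped must be in [0, n_reference]")

    @property
    def ratio(self) -> float:
        return self.n_overlapped / self.n_reference


def overlap_ratio(
    factor_set: PeakSet,
    reference: list[Peak],
    cap: int = 100_000,
    resize_width: int = 200,
    sizes: ChromSizes | None = None,
    dataset_id: str | None = None,
) -> OverlapRecord:
    """Fraction of reference sites overlapping >= 1 retained factor peak.

    Factor peaks are sorted by signal descending (position breaks ties),
    truncated to the top ``cap``, and both sides are summit-resized to
    ``resize_width`` before bedtools-style intersection.
    """
    if not reference:
        raise ValueError("reference site list is empty")
    retained = factor_set.sorted_by_signal()[:cap]
    factor_resized = [resize_to_summit(p, resize_width, sizes) for p in retained]
    ref_resized = [resize_to_summit(p, resize_width, sizes) for p in reference]
    n_hit = count_overlapping(ref_resized, factor_resized)
    return OverlapRecord(
        factor=factor_set.factor,
        dataset_id=dataset_id or f"{factor_set.factor}:{factor_set.cell_type}",
        cell_type=factor_set.cell_type,
        n_reference=len(reference),
        n_overlapped=n_hit,
    )


def rank_factors(records: list[OverlapRecord], top_n: int = 50) -> pd.DataFrame:
    """Rank factors by maximum overlap ratio over their datasets.

    Returns one row per factor (``factor, max_ratio, n_datasets, ratios``),
    sorted by max ratio descending with lexicographic tie-break, truncated
    to ``top_n``.  The per-dataset dot list is retained in ``ratios``.
    """
    by_factor: dict[str, list[float]] = {}
    for rec in records:
        by_factor.setdefault(rec.factor, []).append(rec.ratio)
    rows = [
        {
            "factor": factor,
            "max_ratio": max(ratios),
            "n_datasets": len(ratios),
            "ratios": sorted(ratios, reverse=True),
        }
        for factor, ratios in by_factor.items()
    ]
    table = pd.DataFrame(rows, columns=["factor", "max_ratio", "n_datasets", "ratios"])
    table = table.sort_values(
        ["max_ratio", "factor"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table.head(top_n)


def ratio_scaling(
    records_hsc: list[OverlapRecord],
    records_topk: dict[object, list[OverlapRecord]],
) -> pd.DataFrame:
    """Regress top-K genome-wide ratios on conserved-site ratios, per K.

    Records are paired by (factor, dataset_id).  Returns one row per K with
    the least-squares slope/intercept, the Pearson r and the pair count; a
    degenerate axis (zero variance) is flagged and reported as r = 0.
    """
    hsc = {(r.factor, r.dataset_id): r.ratio for r in records_hsc}
    rows = []
    for key, records in records_topk.items():
        x, y = [], []
        for rec in records:
            k = (rec.factor, rec.dataset_id)
            if k in hsc:
                x.append(hsc[k])
                y.append(rec.ratio)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 2:
            raise ValueError(f"K={key!r}: need >= 2 paired records, got {x.size}")
        degenerate = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
        if degenerate:
            slope, intercept, r = float("nan"), float("nan"), 0.0
        else:
            fit = stats.linregress(x, y)
            slope, intercept, r = fit.slope, fit.intercept, fit.rvalue
        rows.append(
            {
                "K": key,
                "n_pairs": int(x.size),
                "slope": slope,
                "intercept": intercept,
                "pearson_r": r,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def select_max_peak_dataset(datasets: list[PeakSet]) -> PeakSet:
    """Among replicate datasets of one factor, pick the one with the most
    peaks (ties broken by cell-type label for determinism)."""
    if not datasets:
        raise ValueError("no datasets given")
    return max(datasets, key=lambda ps: (len(ps), ps.cell_type))
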