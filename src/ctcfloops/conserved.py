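"""Construction of super-conserved CTCF binding sites.

CTCF binds a large core of positions almost independently of cell type.
This module intersects ChIA-PET peak sets from several cell types to find
the conserved loop-competent sites, then requires support from a large
ChIP-seq compendium to call "super conserved" (hscCTCF-style) sites, and
reports the compendium-support distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .intervals import (
    ChromSizes,
    GenomicInterval,
    Peak,
    PeakSet,
    build_interval_trees,
    overlapping_mask,
    resize_to_summit,
)

__all__ = [
    "ConservedSite",
    "resize_peakset",
    "conserved_chiapet_peaks",
    "hsc_sites",
    "conservation_histogram",
]


@dataclass(frozen=True)
class ConservedSite:
    """A conserved CTCF site with its cross-dataset support counts."""

    interval: GenomicInterval
    n_chiapet_cell_types: int
    n_compendium_datasets: int
    mean_signal: float
    name: str | None = None


def resize_peakset(
    peakset: PeakSet, width: int, sizes: ChromSizes | None = None
) -> PeakSet:
    """Summit-centred resize of every peak in a set (500 bp for ChIA-PET
    peaks, 200 bp for the screening convention)."""
    return PeakSet(
        factor=peakset.factor,
        cell_type=peakset.cell_type,
        peaks=[resize_to_summit(p, width, sizes) for p in peakset.peaks],
    )


def conserved_chiapet_peaks(
    peaksets: list[PeakSet], min_cell_types: int | None = None
) -> list[Peak]:
    """Peaks of the reference (first) set supported by the other cell types.

    A reference peak is conserved when it overlaps >= 1 peak in at least
    ``min_cell_types - 1`` of the other sets; the default requires support
    in every set.  Peaks are assumed already resized (500 bp convention).
    """
    if len(peaksets) < 2:
        raise ValueError("need >= 2 ChIA-PET peak sets")
    if min_cell_types is None:
        min_cell_types = len(peaksets)
    if not 1 <= min_cell_types <= len(peaksets):
        raise ValueError(
            f"min_cell_types must be in [1, {len(peaksets)}], got {min_cell_types}"
        )
    reference, others = peaksets[0], peaksets[1:]
    support = np.zeros(len(reference), dtype=int)
    for other in others:
        support += np.asarray(overlapping_mask(reference, other), dtype=int)
    return [
        peak
        for peak, n_other in zip(reference.peaks, support)
        if n_other + 1 >= min_cell_types
    ]


def hsc_sites(
    conserved: list[Peak],
    compendium: list[PeakSet],
    min_datasets: int | None = None,
    n_chiapet_cell_types: int = 0,
) -> list[ConservedSite]:
    """Filter conserved peaks by ChIP-seq compendium support.

    Keeps peaks overlapped by >= ``min_datasets`` compendium sets (default:
    all of them, the "super conserved" notion) and annotates each with its
    support count and the mean signal of the supporting compendium peaks.
    """
    if not compendium:
        raise ValueError("compendium must be non-empty")
    if min_datasets is None:
        min_datasets = len(compendium)
    if not 1 <= min_datasets <= len(compendium):
        raise ValueError(
            f"min_datasets must be in [1, {len(compendium)}], got {min_datasets}"
        )
    support = np.zeros(len(conserved), dtype=int)
    signal_sum = np.zeros(len(conserved), dtype=float)
    for dataset in compendium:
        trees: dict[str, "object"] = {}
        from intervaltree import IntervalTree

        for peak in dataset.peaks:
            trees.setdefault(peak.interval.chrom, IntervalTree()).addi(
                peak.interval.start, peak.interval.end, peak
            )
        for i, peak in enumerate(conserved):
            iv = peak.interval
            tree = trees.get(iv.chrom)
            hits = tree.overlap(iv.start, iv.end) if tree is not None else ()
            if hits:
                support[i] += 1
                # signal of the best-overlapping compendium peak
                best = max(
                    hits,
                    key=lambda h: min(h.end, iv.end) - max(h.begin, iv.start),
                )
                signal_sum[i] += best.data.signal
    out: list[ConservedSite] = []
    for i, peak in enumerate(conserved):
        if support[i] >= min_datasets:
            mean_signal = (
                signal_sum[i] / support[i] if support[i] else peak.signal
            )
            out.append(
                ConservedSite(
                    interval=peak.interval,
                    n_chiapet_cell_types=n_chiapet_cell_types,
                    n_compendium_datasets=int(support[i]),
                    mean_signal=float(mean_signal),
                    name=peak.name,
                )
            )
    return out


def conservation_histogram(sites: list[ConservedSite]) -> dict[int, int]:
    """Distribution of compendium support counts (sums to ``len(sites)``)."""
    return dict(sorted(Counter(s.n_compendium_datasets for s in sites).items()))
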