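"""Genomic-interval data model, standard-format I/O and overlap primitives.

All coordinates are 0-based half-open (BED native), on disk and in memory.
A :class:`Peak` is an interval plus a summit offset and a signal value (the
narrowPeak ``signalValue`` column); a :class:`Loop` is a pair of anchor
intervals with a PET tag count and optional per-condition counts.  Every
downstream stage of the pipeline builds on the primitives here:
summit-centred resizing, bedtools-style overlap counting and bookend-aware
interval merging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "ChromSizes",
    "Loop",
    "overlaps",
    "resize_to_summit",
    "count_overlapping",
    "overlapping_mask",
    "merge_intervals",
    "exclude_regions",
    "build_interval_trees",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed",
    "read_named_bed",
    "write_bed",
    "read_bedpe_loops",
    "write_bedpe_loops",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)


@dataclass(frozen=True)
class Peak:
    """A called peak: interval, summit offset from start, and signal.

    ``signal`` is the enrichment score (narrowPeak column 7); the summit
    position ``start + summit_offset`` must lie inside the interval.
    """

    interval: GenomicInterval
    summit_offset: int
    signal: float
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.summit_offset < self.interval.length:
            raise ValueError(
                f"summit offset {self.summit_offset} outside interval of "
                f"length {self.interval.length}"
            )
        if math.isnan(self.signal) or self.signal < 0:
            raise ValueError(f"signal must be non-negative, got {self.signal}")

    @property
    def summit(self) -> int:
        """Absolute summit coordinate."""
        return self.interval.start + self.summit_offset


@dataclass
class PeakSet:
    """One ChIP-seq (or ChIA-PET peak) dataset for one factor and cell type."""

    factor: str
    cell_type: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def sorted_by_signal(self) -> list[Peak]:
        """Peaks by signal descending; position breaks ties deterministically."""
        return sorted(
            self.peaks,
            key=lambda p: (-p.signal, p.interval.chrom, p.interval.start, p.interval.end),
        )


class ChromSizes(dict):
    """Mapping of chromosome name to length in bp (lengths must be positive)."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for chrom, size in self.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")


@dataclass
class Loop:
    """A chromatin loop: two anchors plus a PET tag count.

    Anchors are stored in genomic order (``anchor_a`` before ``anchor_b`` by
    (chrom, start)).  ``count_control``/``count_kd`` carry per-condition loop
    counts for differential calling; ``fdr`` is an upstream loop-call FDR.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pet_count: int
    count_control: int | None = None
    count_kd: int | None = None
    fdr: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.pet_count < 1:
            raise ValueError(f"pet_count must be >= 1, got {self.pet_count}")
        a, b = self.anchor_a, self.anchor_b
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            self.anchor_a, self.anchor_b = b, a

    @property
    def span(self) -> GenomicInterval | None:
        """Outer span [min start, max end] for intra-chromosomal loops."""
        if self.anchor_a.chrom != self.anchor_b.chrom:
            return None
        return GenomicInterval(
            self.anchor_a.chrom,
            min(self.anchor_a.start, self.anchor_b.start),
            max(self.anchor_a.end, self.anchor_b.end),
        )


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on one chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def resize_to_summit(peak: Peak, width: int, sizes: ChromSizes | None = None) -> Peak:
    """Return a copy of *peak* re-centred on its summit with total *width*.

    Even widths split symmetrically; odd widths put the extra base on the
    right.  The interval is clipped to ``[0, chrom length)`` (clip, never
    discard); signal and name are preserved and the summit offset updated.
    When *sizes* is omitted only the ``start >= 0`` clip applies.
    """
    if width < 1:
        raise ValueError(f"width must be positive, got {width}")
    chrom = peak.interval.chrom
    if sizes is not None and chrom not in sizes:
        raise KeyError(f"unknown chromosome {chrom!r}")
    summit = peak.summit
    half = width // 2
    start = max(summit - half, 0)
    end = summit + (width - half)
    if sizes is not None:
        end = min(end, sizes[chrom])
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        summit_offset=summit - start,
        signal=peak.signal,
        name=peak.name,
    )


def _as_intervals(obj) -> list[GenomicInterval]:
    """Normalise PeakSet / Peak / GenomicInterval collections to intervals."""
    if isinstance(obj, PeakSet):
        return [p.interval for p in obj.peaks]
    out: list[GenomicInterval] = []
    for item in obj:
        if isinstance(item, Peak):
            out.append(item.interval)
        elif isinstance(item, GenomicInterval):
            out.append(item)
        else:
            raise TypeError(f"cannot interpret {type(item).__name__} as an interval")
    return out


def build_interval_trees(intervals) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees (half-open semantics) for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in _as_intervals(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlapping_mask(query, subject) -> list[bool]:
    """For each query interval, whether it overlaps >= 1 subject interval."""
    trees = build_interval_trees(subject)
    mask = []
    for iv in _as_intervals(query):
        tree = trees.get(iv.chrom)
        mask.append(bool(tree is not None and tree.overlap(iv.start, iv.end)))
    return mask


def count_overlapping(query, subject) -> int:
    """Number of query peaks overlapping >= 1 subject peak (each counted once).

    bedtools-intersect semantics: half-open, >= 1 shared bp, same chromosome.
    """
    return sum(overlapping_mask(query, subject))


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Merge overlapping-or-bookended intervals (bedtools merge, distance 0).

    Output is sorted and non-overlapping; the union of covered bases is
    preserved and bookended inputs (gap 0) land in the same output region.
    """
    ivs = sorted(_as_intervals(intervals))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def exclude_regions(peakset: PeakSet, regions) -> PeakSet:
    """Drop peaks overlapping any excluded region (blacklist-style filter)."""
    mask = overlapping_mask(peakset, regions)
    kept = [p for p, hit in zip(peakset.peaks, mask) if not hit]
    return PeakSet(factor=peakset.factor, cell_type=peakset.cell_type, peaks=kept)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _data_lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_narrowpeak(path, factor: str | None = None, cell_type: str = "") -> PeakSet:
    """Read a narrowPeak (BED6+4) file into a :class:`PeakSet`.

    Column 7 is the signal, column 10 the summit offset from start; a summit
    of −1 falls back to the interval midpoint.  Malformed lines and summits
    outside the interval raise :class:`ValueError` naming the line.
    """
    path = Path(path)
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 10:
            raise ValueError(
                f"{path.name} line {lineno}: expected 10 narrowPeak columns, got {len(fields)}"
            )
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name = None if fields[3] in (".", "") else fields[3]
            signal = float(fields[6])
            summit = int(fields[9])
        except ValueError as exc:
            raise ValueError(f"{path.name} line {lineno}: {exc}") from None
        length = end - start
        if summit == -1:
            summit = length // 2
        if not 0 <= summit < length:
            raise ValueError(
                f"{path.name} line {lineno}: summit offset {summit} outside interval"
            )
        try:
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), summit, signal, name)
            )
        except ValueError as exc:
            raise ValueError(f"{path.name} line {lineno}: {exc}") from None
    return PeakSet(factor=factor or path.stem, cell_type=cell_type, peaks=peaks)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    """Write a :class:`PeakSet` in narrowPeak format (round-trips all fields)."""
    with open(path, "w") as handle:
        for peak in peakset.peaks:
            iv = peak.interval
            handle.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        peak.name or ".",
                        "0",
                        ".",
                        repr(peak.signal),
                        "-1",
                        "-1",
                        str(peak.summit_offset),
                    ]
                )
                + "\n"
            )


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file as plain intervals (extra columns ignored)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path.name} line {lineno}: expected >= 3 BED columns")
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise ValueError(f"{path.name} line {lineno}: {exc}") from None
    return out


def read_named_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED4+ file as (interval, name) pairs (e.g. chromatin states)."""
    path = Path(path)
    out: list[tuple[GenomicInterval, str]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path.name} line {lineno}: expected >= 4 BED columns")
        try:
            out.append((GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3]))
        except ValueError as exc:
            raise ValueError(f"{path.name} line {lineno}: {exc}") from None
    return out


def write_bed(rows, path) -> None:
    """Write intervals, or (interval, name[, score]) tuples, as BED."""
    with open(path, "w") as handle:
        for row in rows:
            if isinstance(row, GenomicInterval):
                fields = [row.chrom, str(row.start), str(row.end)]
            else:
                iv, *rest = row
                fields = [iv.chrom, str(iv.start), str(iv.end)] + [str(x) for x in rest]
            handle.write("\t".join(fields) + "\n")


_BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tpet_count"
    "\tcount_control\tcount_kd\tfdr\n"
)


def read_bedpe_loops(path) -> list[Loop]:
    """Read loops from BEDPE; PET count in the score column, optional
    per-condition counts in columns 9–10 and FDR in column 11."""
    path = Path(path)
    loops: list[Loop] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 8:
            raise ValueError(
                f"{path.name} line {lineno}: expected >= 8 BEDPE columns, got {len(fields)}"
            )
        try:
            a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            name = None if fields[6] in (".", "") else fields[6]
            pet = int(float(fields[7]))
            cc = ck = None
            fdr = None
            if len(fields) >= 10 and fields[8] not in (".", ""):
                cc, ck = int(fields[8]), int(fields[9])
            if len(fields) >= 11 and fields[10] not in (".", ""):
                fdr = float(fields[10])
            loops.append(
                Loop(a, b, pet, count_control=cc, count_kd=ck, fdr=fdr, name=name)
            )
        except ValueError as exc:
            raise ValueError(f"{path.name} line {lineno}: {exc}") from None
    return loops


def write_bedpe_loops(loops: Sequence[Loop], path) -> None:
    """Write loops as BEDPE; an empty collection yields a header-only file."""
    with open(path, "w") as handle:
        handle.write(_BEDPE_HEADER)
        for loop in loops:
            a, b = loop.anchor_a, loop.anchor_b
            cc = "." if loop.count_control is None else str(loop.count_control)
            ck = "." if loop.count_kd is None else str(loop.count_kd)
            fdr = "." if loop.fdr is None else repr(loop.fdr)
            handle.write(
                "\t".join(
                    [
                        a.chrom, str(a.start), str(a.end),
                        b.chrom, str(b.start), str(b.end),
                        loop.name or ".", str(loop.pet_count), cc, ck, fdr,
                    ]
                )
                + "\n"
            )


def write_edge_list(rows: Iterable[tuple[str, str, float]], path) -> None:
    """Write a Cytoscape-loadable edge list: factorA<TAB>factorB<TAB>score."""
    with open(path, "w") as handle:
        handle.write("factor_a\tfactor_b\tscore\n")
        for a, b, score in rows:
            handle.write(f"{a}\t{b}\t{score!r}\n")


def read_edge_list(path) -> list[tuple[str, str, float]]:
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("factor_a\t", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path.name} line {lineno}: expected 3 columns")
            rows.append((fields[0], fields[1], float(fields[2])))
    return rows
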