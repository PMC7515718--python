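"""Enhancer-promoter loops and CTCF-loop classification against them.

Active promoters are TSS +/- 500 bp regions intersecting transcribed
intervals; active enhancers are annotated enhancer segments doing the same.
A loop qualifies as an enhancer-promoter (EP) loop when one anchor hits
>= 1 active enhancer and the other >= 1 active promoter; because loop
resolution (10 kb anchors) can place several elements in one anchor, each
qualifying loop is expanded into one EP loop per (enhancer, promoter)
cross pair.

Differential CTCF loops are classified against EP loops into five
positional categories: (1) CTCF loop contains the EP loop, (2) EP loop
contains the CTCF loop, (3) the loops intersect, (4) the loops are the
same (reciprocal anchor overlap), (5) no intersection.  Precedence is
4 > 1 > 2 > 3 > 5; containment is judged strictly on loop spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    ChromSizes,
    GenomicInterval,
    Loop,
    build_interval_trees,
    overlapping_mask,
)

__all__ = [
    "EPLoop",
    "LoopRelation",
    "candidate_promoters",
    "active_elements",
    "extract_ep_loops",
    "classify_relation",
    "classify_all",
    "relation_summary",
    "expression_by_category",
]


@dataclass(frozen=True)
class EPLoop:
    """One enhancer-promoter pair from an expanded qualifying loop."""

    enhancer_anchor: GenomicInterval
    promoter_anchor: GenomicInterval
    enhancer_id: str
    promoter_id: str
    source_loop_id: str

    @property
    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        a, b = self.enhancer_anchor, self.promoter_anchor
        return (a, b) if (a.chrom, a.start, a.end) <= (b.chrom, b.start, b.end) else (b, a)


@dataclass(frozen=True)
class LoopRelation:
    """Positional category (1-5) of a CTCF loop relative to an EP loop."""

    ctcf_loop_id: str
    ep_loop_id: str
    category: int

    def __post_init__(self) -> None:
        if self.category not in (1, 2, 3, 4, 5):
            raise ValueError(f"category must be 1..5, got {self.category}")


def candidate_promoters(
    tss: list[GenomicInterval], flank: int = 500, sizes: ChromSizes | None = None
) -> list[GenomicInterval]:
    """TSS +/- ``flank`` bp candidate promoter regions, one per transcript
    (not merged), clipped to the chromosome."""
    out = []
    for t in tss:
        pos = t.start
        start = max(pos - flank, 0)
        end = pos + flank
        if sizes is not None and t.chrom in sizes:
            end = min(end, sizes[t.chrom])
        out.append(GenomicInterval(t.chrom, start, end))
    return out


def active_elements(
    candidates: list[GenomicInterval], transcribed: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Candidates intersecting >= 1 transcribed interval (active elements)."""
    mask = overlapping_mask(candidates, transcribed)
    return [c for c, hit in zip(candidates, mask) if hit]


def extract_ep_loops(
    loops: list[Loop],
    promoters: list[GenomicInterval],
    enhancers: list[GenomicInterval],
) -> list[EPLoop]:
    """Expand qualifying loops into all (enhancer, promoter) combinations.

    A loop qualifies when one anchor hits >= 1 enhancer and the *other*
    anchor hits >= 1 promoter (an anchor hitting both element types on the
    same side does not qualify by itself).  Both orientations are expanded;
    element identifiers encode position so the expansion is reproducible.
    """
    from intervaltree import IntervalTree

    def tree_of(elements: list[GenomicInterval], prefix: str):
        trees: dict[str, IntervalTree] = {}
        ids: dict[GenomicInterval, str] = {}
        for i, iv in enumerate(elements):
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
            ids[iv] = f"{prefix}{i}"
        return trees, ids

    prom_trees, _ = tree_of(promoters, "P")
    enh_trees, _ = tree_of(enhancers, "E")

    def hits(trees, anchor: GenomicInterval) -> list[int]:
        tree = trees.get(anchor.chrom)
        if tree is None:
            return []
        return sorted(h.data for h in tree.overlap(anchor.start, anchor.end))

    out: list[EPLoop] = []
    for li, loop in enumerate(loops):
        loop_id = loop.name or f"loop_{li}"
        for enh_anchor, prom_anchor in (
            (loop.anchor_a, loop.anchor_b),
            (loop.anchor_b, loop.anchor_a),
        ):
            for ei in hits(enh_trees, enh_anchor):
                for pi in hits(prom_trees, prom_anchor):
                    out.append(
                        EPLoop(
                            enhancer_anchor=enh_anchor,
                            promoter_anchor=prom_anchor,
                            enhancer_id=f"E{ei}",
                            promoter_id=f"P{pi}",
                            source_loop_id=loop_id,
                        )
                    )
    return out


def _oriented_anchors(loop) -> tuple[GenomicInterval, GenomicInterval]:
    if isinstance(loop, EPLoop):
        return loop.anchors
    a, b = loop.anchor_a, loop.anchor_b
    return (a, b) if (a.chrom, a.start, a.end) <= (b.chrom, b.start, b.end) else (b, a)


def _ivl_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def classify_relation(
    ctcf_loop: Loop,
    ep_loop,
    ctcf_loop_id: str | None = None,
    ep_loop_id: str | None = None,
) -> LoopRelation:
    """Assign the positional category of a CTCF loop relative to an EP loop.

    Rules, in precedence order on genomic-order-oriented loops:
    4 - reciprocal anchor overlap (first anchors overlap and second anchors
    overlap); 1 - EP span strictly inside CTCF span; 2 - CTCF span strictly
    inside EP span; 3 - spans overlap without containment; 5 - disjoint or
    different chromosomes.  Total and single-valued for every pair.
    """
    c1, c2 = _oriented_anchors(ctcf_loop)
    e1, e2 = _oriented_anchors(ep_loop)
    cid = ctcf_loop_id or getattr(ctcf_loop, "name", None) or "ctcf"
    eid = ep_loop_id or getattr(ep_loop, "source_loop_id", None) or "ep"

    if c1.chrom != c2.chrom or e1.chrom != e2.chrom or c1.chrom != e1.chrom:
        return LoopRelation(cid, eid, 5)
    if _ivl_overlap(c1, e1) and _ivl_overlap(c2, e2):
        return LoopRelation(cid, eid, 4)
    cs, ce = c1.start, c2.end
    es, ee = e1.start, e2.end
    if cs < es and ee < ce:
        return LoopRelation(cid, eid, 1)
    if es < cs and ce < ee:
        return LoopRelation(cid, eid, 2)
    if cs < ee and es < ce:
        return LoopRelation(cid, eid, 3)
    return LoopRelation(cid, eid, 5)


def classify_all(ctcf_loops: list[Loop], ep_loops: list[EPLoop]) -> list[LoopRelation]:
    """Classify every (CTCF loop, EP loop) pair."""
    out = []
    for i, cl in enumerate(ctcf_loops):
        cid = cl.name or f"ctcf_{i}"
        for j, el in enumerate(ep_loops):
            out.append(classify_relation(cl, el, ctcf_loop_id=cid, ep_loop_id=f"ep_{j}"))
    return out


def relation_summary(
    relations: list[LoopRelation],
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-category pair counts plus the per-CTCF-loop category rollup.

    A CTCF loop can participate in several categories across its EP-loop
    pairings; the rollup lists each loop's sorted category multiset.
    """
    counts = pd.Series(0, index=[1, 2, 3, 4, 5], name="n_pairs")
    per_loop: dict[str, list[int]] = {}
    for rel in relations:
        counts[rel.category] += 1
        per_loop.setdefault(rel.ctcf_loop_id, []).append(rel.category)
    rollup = pd.DataFrame(
        [
            {"ctcf_loop_id": k, "categories": sorted(v),
             "distinct_categories": sorted(set(v))}
            for k, v in per_loop.items()
        ],
        columns=["ctcf_loop_id", "categories", "distinct_categories"],
    )
    return counts, rollup


def expression_by_category(
    gene_log2fc: pd.Series, gene_category: pd.Series
) -> tuple[pd.DataFrame, float, float]:
    """Compare expression fold changes across loop-relation gene groups.

    Genes are grouped by the category membership of their promoters and the
    per-group log2 fold-change distributions compared with a Kruskal-Wallis
    test.  Returns (group summary, H statistic, p-value).
    """
    joined = pd.DataFrame({"log2fc": gene_log2fc, "category": gene_category}).dropna()
    groups = [g["log2fc"].to_numpy() for _, g in joined.groupby("category") if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty gene groups")
    h, p = stats.kruskal(*groups)
    summary = (
        joined.groupby("category")["log2fc"]
        .agg(["count", "median", "mean"])
        .reset_index()
    )
    return summary, float(h), float(p)
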