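"""Factor-pair analysis at paired loop anchors.

Factors bound at the two anchors of a loop may form a complex that promotes
the loop.  Every cross-anchor factor pair of every loop is scored with the
loop's strength, scores are summed over loops for the same unordered pair,
and the result is exported as a weighted factor-factor network.

Counting is by ordered cross product (a in anchor-A factors, b in anchor-B
factors), folded onto unordered edges: this makes the conservation law
sum(edge scores) = sum over loops of s * |A| * |B| exact and the result
independent of anchor labelling.  Self-pairs (x, x) are retained; they
carry the homotypic CTCF-CTCF signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .intervals import (
    GenomicInterval,
    Loop,
    PeakSet,
    build_interval_trees,
    write_edge_list,
)

__all__ = [
    "FactorPairEdge",
    "factors_at_anchor",
    "annotate_loop_factors",
    "pair_scores",
    "build_pair_network",
    "export_network",
    "to_graph",
]


@dataclass(frozen=True)
class FactorPairEdge:
    """An unordered factor pair with its aggregated loop-strength score."""

    factor_x: str
    factor_y: str
    score: float
    n_loops: int

    def __post_init__(self) -> None:
        if self.factor_x > self.factor_y:
            raise ValueError("factors must be in canonical (lexicographic) order")
        if self.score < 0:
            raise ValueError("score must be non-negative")


def factors_at_anchor(anchor: GenomicInterval, factor_sets: list[PeakSet]) -> set[str]:
    """Names of factors with >= 1 peak overlapping the anchor."""
    found: set[str] = set()
    for ps in factor_sets:
        if ps.factor in found:
            continue
        for peak in ps.peaks:
            iv = peak.interval
            if iv.chrom == anchor.chrom and iv.start < anchor.end and anchor.start < iv.end:
                found.add(ps.factor)
                break
    return found


def annotate_loop_factors(
    loops: list[Loop], factor_sets: list[PeakSet]
) -> list[tuple[set[str], set[str]]]:
    """Per loop, the factor sets bound at anchor A and anchor B."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for ps in factor_sets:
        for peak in ps.peaks:
            trees.setdefault(peak.interval.chrom, IntervalTree()).addi(
                peak.interval.start, peak.interval.end, ps.factor
            )

    def lookup(anchor: GenomicInterval) -> set[str]:
        tree = trees.get(anchor.chrom)
        if tree is None:
            return set()
        return {h.data for h in tree.overlap(anchor.start, anchor.end)}

    return [(lookup(l.anchor_a), lookup(l.anchor_b)) for l in loops]


def pair_scores(
    items: list[tuple[set[str], set[str], float]]
) -> list[FactorPairEdge]:
    """Accumulate factor-pair scores over loops.

    *items* holds one (factors at anchor A, factors at anchor B, strength)
    triple per loop.  Each ordered occurrence (a, b) with a in A and b in B
    contributes the strength to the unordered edge {a, b}; ``n_loops``
    counts loops contributing at least once to the edge.
    """
    scores: dict[tuple[str, str], float] = {}
    support: dict[tuple[str, str], int] = {}
    for a_set, b_set, strength in items:
        if strength < 0:
            raise ValueError("loop strength must be non-negative")
        touched: set[tuple[str, str]] = set()
        for a in a_set:
            for b in b_set:
                key = (a, b) if a <= b else (b, a)
                scores[key] = scores.get(key, 0) + strength
                touched.add(key)
        for key in touched:
            support[key] = support.get(key, 0) + 1
    edges = [
        FactorPairEdge(factor_x=x, factor_y=y, score=s, n_loops=support[(x, y)])
        for (x, y), s in scores.items()
    ]
    edges.sort(key=lambda e: (-e.score, e.factor_x, e.factor_y))
    return edges


def build_pair_network(
    loops: list[Loop],
    factor_sets: list[PeakSet],
    strengths: list[float] | None = None,
) -> list[FactorPairEdge]:
    """End-to-end: annotate anchors with factors and accumulate pair scores.

    By default a loop's strength is its PET count; pass *strengths* to use
    another per-loop score.
    """
    annotated = annotate_loop_factors(loops, factor_sets)
    if strengths is None:
        strengths = [float(l.pet_count) for l in loops]
    if len(strengths) != len(loops):
        raise ValueError("strengths must align with loops")
    return pair_scores(
        [(a, b, s) for (a, b), s in zip(annotated, strengths)]
    )


def export_network(
    edges: list[FactorPairEdge],
    path,
    min_score: float = 0.0,
    top_edges: int | None = None,
) -> list[FactorPairEdge]:
    """Write a Cytoscape-loadable TSV edge list, thresholded and ordered.

    Edges below ``min_score`` are dropped, the rest ordered by score
    descending (then name), optionally truncated to ``top_edges``.  The
    retained edges are returned.
    """
    kept = sorted(
        (e for e in edges if e.score >= min_score),
        key=lambda e: (-e.score, e.factor_x, e.factor_y),
    )
    if top_edges is not None:
        kept = kept[:top_edges]
    write_edge_list([(e.factor_x, e.factor_y, e.score) for e in kept], path)
    return kept


def to_graph(edges: list[FactorPairEdge]) -> nx.Graph:
    """Weighted undirected factor-factor graph (self-loops kept)."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.factor_x, e.factor_y, weight=e.score, n_loops=e.n_loops)
    return g
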