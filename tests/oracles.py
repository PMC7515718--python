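"""Independent brute-force oracles for interval operations.

These are deliberately naive (all-pairs loops, per-base boolean masks) and
shared by the unit and acceptance suites; they never call the library code
they are used to check.
"""

import numpy as np


def brute_count_overlapping(query, subject):
    """All-pairs O(n*m) overlap count of query intervals hit by subject."""
    n = 0
    for q in query:
        for s in subject:
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                n += 1
                break
    return n


def brute_overlap_mask(query, subject):
    return [
        any(
            q.chrom == s.chrom and q.start < s.end and s.start < q.end
            for s in subject
        )
        for q in query
    ]


def brute_merge(intervals, chrom_len=100_000):
    """Paint covered bases per chromosome, then extract maximal runs.

    Bookended inputs produce contiguous runs, matching merge distance 0.
    """
    chroms = sorted({iv.chrom for iv in intervals})
    out = []
    for chrom in chroms:
        mask = np.zeros(chrom_len + 1, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                mask[iv.start:iv.end] = True
        diff = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1
        ends = np.flatnonzero(diff == -1) + 1
        if mask[0]:
            starts = np.concatenate([[0], starts])
        for s, e in zip(starts, ends):
            out.append((chrom, int(s), int(e)))
    return out


def brute_state_category(site, segments, category_map, categories):
    """Per-base category vote with fixed priority tie-break."""
    cover = {c: 0 for c in categories}
    for iv, label in segments:
        if iv.chrom != site.chrom:
            continue
        for base in range(max(iv.start, site.start), min(iv.end, site.end)):
            cover[category_map.get(label, "quies")] += 1
    best = None
    for c in categories:  # priority order: first max wins
        if best is None or cover[c] > cover[best]:
            best = c
    return best


def brute_pair_scores(items):
    """Triple-loop accumulation of unordered factor-pair scores."""
    scores = {}
    for a_set, b_set, s in items:
        for a in a_set:
            for b in b_set:
                key = tuple(sorted((a, b)))
                scores[key] = scores.get(key, 0) + s
    return scores
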