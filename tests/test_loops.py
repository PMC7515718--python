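import math

import numpy as np
import pytest

from ctcfloops.intervals import GenomicInterval, Loop, Peak, PeakSet
from ctcfloops.loops import (
    STATE_CATEGORIES,
    STATE_CATEGORY_MAP,
    AnchorRecord,
    anchor_loop_strength,
    annotate_state_categories,
    assign_unique_ctcf,
    cobinding_strength_test,
    differential_loops,
    log2_strength,
    normalize_binding,
    state_category,
    stratified_correlation,
    strength_change_by_binding_change,
)

from oracles import brute_state_category


def _peak(chrom, summit, width=200, signal=5.0):
    return Peak(GenomicInterval(chrom, summit - width // 2, summit + width // 2),
                width // 2, signal)


class TestAssignUniqueCtcf:
    def test_zero_one_multi(self):
        anchors = [
            GenomicInterval("chr1", 0, 1000),      # no CTCF
            GenomicInterval("chr1", 4000, 5000),   # one
            GenomicInterval("chr1", 8000, 9000),   # two
        ]
        ctcf = PeakSet("CTCF", "ct", [
            _peak("chr1", 4500), _peak("chr1", 8200), _peak("chr1", 8800),
        ])
        records = assign_unique_ctcf(anchors, ctcf)
        assert len(records) == 1
        assert records[0].anchor == anchors[1]
        assert records[0].ctcf_peak.summit == 4500

    def test_matches_brute_force(self):
        rng = np.random.default_rng(51)
        for _ in range(30):
            anchors = [
                GenomicInterval("chr1", int(s), int(s) + 500)
                for s in rng.integers(0, 99_000, size=int(rng.integers(5, 60)))
            ]
            peaks = [_peak("chr1", int(s))
                     for s in rng.integers(200, 99_500, size=int(rng.integers(5, 80)))]
            ctcf = PeakSet("CTCF", "ct", peaks)
            got = {(r.anchor.chrom, r.anchor.start) for r in assign_unique_ctcf(anchors, ctcf)}
            expected = set()
            for a in anchors:
                n = sum(
                    1 for p in peaks
                    if p.interval.start < a.end and a.start < p.interval.end
                )
                if n == 1:
                    expected.add((a.chrom, a.start))
            assert got == expected


class TestAnchorStrength:
    def test_examples(self):
        a1 = GenomicInterval("chr1", 0, 500)
        a2 = GenomicInterval("chr1", 10_000, 10_500)
        a3 = GenomicInterval("chr1", 50_000, 50_500)
        records = [AnchorRecord(anchor=a, ctcf_peak=_peak(a.chrom, a.start + 250))
                   for a in (a1, a2, a3)]
        loops = [Loop(a1, a2, 3), Loop(a1, a3, 5)]
        anchor_loop_strength(records, loops)
        assert [r.loop_strength for r in records] == [8, 3, 5]

    def test_anchor_in_no_loop_zero(self):
        a = GenomicInterval("chr2", 0, 500)
        rec = AnchorRecord(anchor=a, ctcf_peak=_peak("chr2", 250))
        anchor_loop_strength([rec], [])
        assert rec.loop_strength == 0

    def test_conservation_law_random(self):
        rng = np.random.default_rng(52)
        for _ in range(20):
            anchors = [
                GenomicInterval("chr1", int(i) * 1000, int(i) * 1000 + 500)
                for i in rng.choice(100, size=int(rng.integers(5, 40)), replace=False)
            ]
            records = [AnchorRecord(anchor=a, ctcf_peak=_peak(a.chrom, a.start + 250))
                       for a in anchors]
            loops = []
            for _ in range(int(rng.integers(1, 60))):
                s1, s2 = rng.choice(100, size=2, replace=False)
                loops.append(
                    Loop(GenomicInterval("chr1", int(s1) * 1000, int(s1) * 1000 + 500),
                         GenomicInterval("chr1", int(s2) * 1000, int(s2) * 1000 + 500),
                         int(rng.integers(1, 20)))
                )
            anchor_loop_strength(records, loops)
            total = sum(r.loop_strength for r in records)
            expected = 0
            for loop in loops:
                for end in (loop.anchor_a, loop.anchor_b):
                    hits = sum(
                        1 for r in records
                        if r.anchor.start < end.end and end.start < r.anchor.end
                    )
                    expected += loop.pet_count * hits
            assert total == expected


class TestCobindingTest:
    def _records(self, strengths, chrom="chr1"):
        records = []
        for i, s in enumerate(strengths):
            a = GenomicInterval(chrom, i * 10_000, i * 10_000 + 500)
            rec = AnchorRecord(anchor=a, ctcf_peak=_peak(chrom, i * 10_000 + 250))
            rec.loop_strength = int(s)
            records.append(rec)
        return records

    def test_full_separation_passes_gate(self):
        records = self._records([100] * 50 + [1] * 50)
        factor = PeakSet("X", "ct", [
            _peak("chr1", i * 10_000 + 250) for i in range(50)
        ])
        t = cobinding_strength_test(records, "X", factor, n_factors_tested=100)
        assert t.n_cobound == 50 and t.n_noncobound == 50
        assert t.p < 1e-15
        assert -math.log10(t.fdr) >= 20 and t.passes_screen

    def test_identical_strata_p_near_one(self):
        records = self._records([7] * 40)
        factor = PeakSet("X", "ct", [
            _peak("chr1", i * 10_000 + 250) for i in range(20)
        ])
        t = cobinding_strength_test(records, "X", factor)
        assert t.p > 0.4 and not t.passes_screen

    def test_empty_stratum_untestable(self):
        records = self._records([5] * 10)
        factor = PeakSet("X", "ct", [_peak("chr2", 500)])
        t = cobinding_strength_test(records, "X", factor)
        assert t.untestable and not t.passes_screen

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(53)
        strengths = rng.integers(1, 100, size=80)
        records = self._records(strengths)
        factor = PeakSet("X", "ct", [
            _peak("chr1", i * 10_000 + 250) for i in range(0, 80, 2)
        ])
        p1 = cobinding_strength_test(records, "X", factor).p
        records2 = self._records(strengths**2)  # strictly monotone transform
        p2 = cobinding_strength_test(records2, "X", factor).p
        assert p1 == pytest.approx(p2)

    def test_permutation_null_alpha_level(self):
        rng = np.random.default_rng(54)
        strengths = rng.poisson(10, size=400) + 1
        n_perm, hits = 300, 0
        for _ in range(n_perm):
            idx = rng.choice(400, size=120, replace=False)
            records = self._records(strengths)
            factor = PeakSet("X", "ct", [
                _peak("chr1", int(i) * 10_000 + 250) for i in idx
            ])
            t = cobinding_strength_test(records, "X", factor)
            hits += int(t.p < 0.05)
        rate = hits / n_perm
        assert rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_perm)


class TestNormalization:
    @pytest.mark.parametrize(
        "count,length,expected",
        [
            (1, 1000, 0.0),
            (1000, 1000, math.log2(1000)),
            (0, 500, 1.0),  # pseudocount rule
        ],
    )
    def test_values(self, count, length, expected):
        assert normalize_binding(count, length) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            normalize_binding(1, 0)
        with pytest.raises(ValueError):
            normalize_binding(-1, 100)

    def test_log2_strength_zero_handling(self):
        assert log2_strength(0) == 0.0
        assert log2_strength(8) == 3.0


class TestStateCategory:
    def test_fully_inside_tssa(self):
        site = GenomicInterval("chr1", 100, 300)
        segments = [(GenomicInterval("chr1", 0, 1000), "TssA")]
        assert state_category(site, segments) == "promoter"

    def test_max_overlap_rule(self):
        site = GenomicInterval("chr1", 0, 100)
        segments = [
            (GenomicInterval("chr1", 0, 60), "EnhA1"),
            (GenomicInterval("chr1", 60, 200), "Tx"),
        ]
        assert state_category(site, segments) == "enhancer"

    def test_tie_priority_promoter_first(self):
        site = GenomicInterval("chr1", 0, 100)
        segments = [
            (GenomicInterval("chr1", 0, 50), "Tx"),
            (GenomicInterval("chr1", 50, 100), "TssA"),
        ]
        assert state_category(site, segments) == "promoter"

    def test_unknown_label_quies(self):
        site = GenomicInterval("chr1", 0, 100)
        assert state_category(site, [(GenomicInterval("chr1", 0, 100), "Het")]) == "quies"

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(55)
        labels = list(STATE_CATEGORY_MAP) + ["Quies", "Het", "ZNF/Rpts"]
        for _ in range(30):
            # random tiling of [0, 2000)
            cuts = np.sort(rng.choice(np.arange(1, 2000), size=8, replace=False))
            bounds = [0, *cuts.tolist(), 2000]
            segments = [
                (GenomicInterval("chr1", bounds[i], bounds[i + 1]),
                 labels[int(rng.integers(len(labels)))])
                for i in range(len(bounds) - 1)
            ]
            s = int(rng.integers(0, 1800))
            site = GenomicInterval("chr1", s, s + int(rng.integers(50, 200)))
            assert state_category(site, segments) == brute_state_category(
                site, segments, STATE_CATEGORY_MAP, STATE_CATEGORIES
            )


class TestStratifiedCorrelation:
    def _records_with_category(self, n, rng, category="promoter"):
        records = []
        for i in range(n):
            a = GenomicInterval("chr1", i * 2000, i * 2000 + 500)
            rec = AnchorRecord(anchor=a, ctcf_peak=_peak("chr1", i * 2000 + 250))
            rec.state_category = category
            records.append(rec)
        return records

    def test_planted_linear_relation_recovered(self):
        rng = np.random.default_rng(56)
        n = 2000
        records = self._records_with_category(n, rng)
        x = rng.normal(0, 1, n)
        noise = rng.normal(0, 0.5, n)
        for rec, xi, e in zip(records, x, noise):
            rec.loop_strength = max(0, int(round(2 ** (2 * xi + e + 5))))
        table = stratified_correlation(records, x)
        row = table[table.category == "promoter"].iloc[0]
        # population r for y = 2x + e with sd(x)=1, sd(e)=0.5 (log2 strength
        # re-discretised, so allow 3 SE around the closed form)
        pop_r = 2.0 / math.sqrt(4.0 + 0.25)
        se = (1 - pop_r**2) / math.sqrt(n - 3)
        assert abs(row.r - pop_r) < 3 * se + 0.02
        assert row.reported_score > 0

    def test_small_stratum_gated_to_zero(self):
        rng = np.random.default_rng(57)
        records = self._records_with_category(500, rng)
        x = rng.normal(0, 1, 500)
        for rec, xi in zip(records, x):
            rec.loop_strength = max(0, int(round(2 ** (2 * xi + 5))))
        row = stratified_correlation(records, x).iloc[0]
        assert row.reported_score == 0.0 and row.r > 0.9

    def test_null_relation_gated(self):
        rng = np.random.default_rng(58)
        gated = 0
        n_sims = 100
        for _ in range(n_sims):
            records = self._records_with_category(1200, rng)
            x = rng.normal(0, 1, 1200)
            for rec in records:
                rec.loop_strength = int(rng.poisson(20))
            row = stratified_correlation(records, x).iloc[0]
            if row.reported_score == 0.0:
                gated += 1
        assert gated >= 0.95 * n_sims

    def test_score_exactly_zero_never_nan(self):
        records = self._records_with_category(10, np.random.default_rng(59))
        for rec in records:
            rec.loop_strength = 5
        table = stratified_correlation(records, np.zeros(10))
        for score in table.reported_score:
            assert score == 0.0 and not math.copysign(1, score) < 0


class TestDifferentialLoops:
    def _loops(self, counts):
        out = []
        for i, (cc, ck) in enumerate(counts):
            a = GenomicInterval("chr1", i * 10_000, i * 10_000 + 500)
            b = GenomicInterval("chr1", i * 10_000 + 5000, i * 10_000 + 5500)
            out.append(Loop(a, b, 1, count_control=cc, count_kd=ck, name=f"l{i}"))
        return out

    def test_printed_rule_fixtures(self):
        table = differential_loops(self._loops([(3, 0), (1, 1), (4, 2)]))
        assert table.loc[0, "status"] == "differential"
        assert table.loc[0, "fold_change"] == pytest.approx(4.0)
        assert table.loc[0, "direction"] == "down"
        assert table.loc[1, "status"] == "filtered"
        assert table.loc[2, "status"] == "stable"
        assert table.loc[2, "fold_change"] == pytest.approx(5 / 3)

    def test_zero_zero_always_filtered(self):
        table = differential_loops(self._loops([(0, 0)]))
        assert table.loc[0, "status"] == "filtered"

    def test_condition_swap_symmetry(self):
        rng = np.random.default_rng(60)
        counts = [(int(a), int(b)) for a, b in rng.integers(0, 30, size=(200, 2))]
        fwd = differential_loops(self._loops(counts))
        rev = differential_loops(self._loops([(b, a) for a, b in counts]))
        assert (fwd["status"] == rev["status"]).all()
        swap = {"up": "down", "down": "up", "none": "none"}
        assert (fwd["direction"].map(swap) == rev["direction"]).all()

    def test_missing_counts_rejected(self):
        loop = Loop(GenomicInterval("chr1", 0, 500),
                    GenomicInterval("chr1", 5000, 5500), 3)
        with pytest.raises(ValueError):
            differential_loops([loop])


class TestStrengthChangeByBindingChange:
    def test_planted_coupling_monotone_medians(self):
        rng = np.random.default_rng(61)
        binding = rng.uniform(-2, 2, 2000)
        strength_fc = 2.0**binding * rng.lognormal(0, 0.1, 2000)
        groups, tests = strength_change_by_binding_change(binding, strength_fc)
        medians = [np.median(v) for v in groups.values()]
        assert medians == sorted(medians)
        assert (tests["p"] < 0.01).all()

    def test_null_alpha_level(self):
        rng = np.random.default_rng(62)
        rates = []
        for _ in range(100):
            binding = rng.uniform(-2, 2, 300)
            strength_fc = rng.lognormal(0, 0.3, 300)
            _, tests = strength_change_by_binding_change(binding, strength_fc)
            rates.append((tests["p"] < 0.05).mean())
        assert np.mean(rates) < 0.05 + 2 * np.std(rates) / 10 + 0.03

    def test_single_bin_warns_no_tests(self):
        with pytest.warns(UserWarning, match="bins"):
            groups, tests = strength_change_by_binding_change(
                np.zeros(10), np.ones(10)
            )
        assert len(groups) == 1 and tests.empty
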