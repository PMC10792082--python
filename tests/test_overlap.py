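"""Overlap statistics, paired Wilcoxon, BH correction, Bray-Curtis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oralgut import (
    AnalysisConfig,
    UndefinedTestError,
    bh_adjust,
    bray_curtis,
    build_sample_pairs,
    compare_niche_abundances,
    find_overlapping_species,
    paired_wilcoxon,
    pairwise_overlap_frequency,
    prevalence_filter,
)
from oralgut.overlap import box_summary, log_transform

from conftest import make_table


def _paired_table(presence, oral_site="saliva", fecal_val=1.0, oral_val=1.0):
    """n-pair table; presence[i] = (in_stool, in_oral) for species SpX."""
    meta, rows = [], []
    for i, (in_st, in_or) in enumerate(presence):
        st_id, or_id = f"st{i}", f"or{i}"
        meta += [(st_id, f"u{i}", "stool"), (or_id, f"u{i}", oral_site)]
        rows += [(st_id, "Filler", 50.0), (or_id, "Filler", 50.0)]
        if in_st:
            rows.append((st_id, "SpX", fecal_val))
        if in_or:
            rows.append((or_id, "SpX", oral_val))
    return make_table(meta, rows)


class TestPrevalenceFilter:
    def _table(self, n_samples, n_detected):
        meta = [(f"s{i:03d}", f"u{i}", "stool") for i in range(n_samples)]
        rows = [(f"s{i:03d}", "Common", 50.0) for i in range(n_samples)]
        rows += [(f"s{i:03d}", "Rare", 1.0) for i in range(n_detected)]
        return make_table(meta, rows)

    @pytest.mark.parametrize(
        "n_samples, n_detected, kept",
        [(20, 3, True), (20, 2, False), (100, 9, False), (100, 10, True)],
    )
    def test_threshold_is_max_of_count_and_fraction(self, n_samples, n_detected, kept):
        table = self._table(n_samples, n_detected)
        sids = sorted(table.meta.index)
        result = prevalence_filter(table, sids)
        assert ("Rare" in result) is kept
        assert "Common" in result

    def test_empty_sample_list_rejected(self):
        table = self._table(5, 5)
        with pytest.raises(ValueError, match="non-empty"):
            prevalence_filter(table, [])

    def test_output_sorted_lexicographically(self):
        table = self._table(5, 5)
        assert prevalence_filter(table, sorted(table.meta.index)) == ["Common", "Rare"]

    def test_raising_thresholds_never_enlarges_set(self):
        rng = np.random.default_rng(9)
        meta = [(f"s{i}", f"u{i}", "stool") for i in range(30)]
        rows = []
        for sp in "ABCDEFG":
            for i in range(30):
                if rng.random() < 0.4:
                    rows.append((f"s{i}", f"Sp{sp}", float(rng.uniform(0.01, 5))))
        table = make_table(meta, rows)
        sids = sorted(table.meta.index)
        base = set(prevalence_filter(table, sids))
        stricter_count = set(
            prevalence_filter(table, sids, AnalysisConfig(prevalence_min_count=8))
        )
        stricter_frac = set(
            prevalence_filter(table, sids, AnalysisConfig(prevalence_min_fraction=0.5))
        )
        assert stricter_count <= base
        assert stricter_frac <= base


class TestPairwiseOverlap:
    def test_two_of_three_pairs(self):
        table = _paired_table([(1, 1), (1, 1), (1, 0)])
        pairs = build_sample_pairs(table, "saliva")
        assert pairwise_overlap_frequency(table, pairs, "SpX") == (3, 2, 2 / 3)

    def test_absent_species_zero(self):
        table = _paired_table([(0, 0), (0, 0)])
        pairs = build_sample_pairs(table, "saliva")
        assert pairwise_overlap_frequency(table, pairs, "Nowhere")[2] == 0.0

    def test_one_sided_presence_zero(self):
        table = _paired_table([(1, 0), (1, 0), (1, 0)])
        pairs = build_sample_pairs(table, "saliva")
        assert pairwise_overlap_frequency(table, pairs, "SpX")[2] == 0.0

    def test_niche_swap_symmetry(self):
        rng = np.random.default_rng(4)
        presence = [(rng.integers(2), rng.integers(2)) for _ in range(20)]
        fwd = _paired_table(presence)
        rev = _paired_table([(b, a) for a, b in presence])
        pf = build_sample_pairs(fwd, "saliva")
        pr = build_sample_pairs(rev, "saliva")
        assert (
            pairwise_overlap_frequency(fwd, pf, "SpX")
            == pairwise_overlap_frequency(rev, pr, "SpX")
        )

    def test_raising_presence_threshold_never_increases_frequency(self):
        table = _paired_table([(1, 1)] * 10, fecal_val=0.05, oral_val=2.0)
        pairs = build_sample_pairs(table, "saliva")
        f0 = pairwise_overlap_frequency(table, pairs, "SpX")[2]
        f1 = pairwise_overlap_frequency(
            table, pairs, "SpX", AnalysisConfig(presence_threshold=0.1)
        )[2]
        f2 = pairwise_overlap_frequency(
            table, pairs, "SpX", AnalysisConfig(presence_threshold=10.0)
        )[2]
        assert f0 >= f1 >= f2
        assert (f0, f2) == (1.0, 0.0)


class TestFindOverlappingSpecies:
    def test_ten_percent_boundary_inclusive(self):
        # 10 pairs, SpX overlaps in exactly 1 -> retained at the boundary
        table = _paired_table([(1, 1)] + [(1, 0)] * 9)
        pairs = build_sample_pairs(table, "saliva")
        cfg = AnalysisConfig(prevalence_min_count=1)
        assert "SpX" in find_overlapping_species(table, pairs, cfg)

    def test_zero_overlap_excluded(self):
        table = _paired_table([(1, 0)] * 10)
        pairs = build_sample_pairs(table, "saliva")
        cfg = AnalysisConfig(prevalence_min_count=1)
        assert "SpX" not in find_overlapping_species(table, pairs, cfg)

    def test_equal_frequency_ties_lexicographic(self):
        meta, rows = [], []
        for i in range(4):
            meta += [(f"st{i}", f"u{i}", "stool"), (f"or{i}", f"u{i}", "saliva")]
            for sp in ("SpB", "SpA"):
                rows += [(f"st{i}", sp, 1.0), (f"or{i}", sp, 1.0)]
        table = make_table(meta, rows)
        pairs = build_sample_pairs(table, "saliva")
        cfg = AnalysisConfig(prevalence_min_count=1)
        assert find_overlapping_species(table, pairs, cfg) == ["SpA", "SpB"]


class TestPairedWilcoxon:
    def test_n5_all_positive_exact(self):
        assert paired_wilcoxon([2, 3, 4, 5, 6], [1, 1, 1, 1, 1]) == pytest.approx(0.0625)

    def test_identical_vectors_undefined(self):
        with pytest.raises(UndefinedTestError):
            paired_wilcoxon([1.0, 2.0], [1.0, 2.0])

    def test_single_nonzero_pair(self):
        assert paired_wilcoxon([2.0], [1.0]) == pytest.approx(1.0)

    def test_matches_scipy_exact_without_ties(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        checked = 0
        while checked < 30:
            n = int(rng.integers(3, 15))
            f = np.round(rng.normal(size=n), 3)
            o = np.round(rng.normal(size=n), 3)
            d = f - o
            d = d[d != 0]
            if d.size == 0 or len(np.unique(np.abs(d))) != d.size:
                continue
            assert paired_wilcoxon(f, o) == pytest.approx(
                stats.wilcoxon(f, o, method="exact").pvalue, abs=1e-12
            )
            checked += 1

    def test_matches_scipy_normal_approximation_large_n(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        for _ in range(10):
            f = rng.normal(size=40)
            o = rng.normal(loc=0.3, size=40)
            assert paired_wilcoxon(f, o) == pytest.approx(
                stats.wilcoxon(f, o, method="approx", correction=True).pvalue,
                rel=1e-9,
            )


class TestBHAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.04, 0.03, 0.002]) == pytest.approx(
            [0.02, 0.04, 0.04, 0.008]
        )

    def test_single_test_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_ones_fixed_point(self):
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_input_and_order_preserving(self, p):
        q = bh_adjust(p)
        assert all(qi >= pi for qi, pi in zip(q, p))
        order = np.argsort(p, kind="stable")
        assert all(
            q[order[i]] <= q[order[i + 1]] + 1e-12 for i in range(len(p) - 1)
        )


class TestBrayCurtis:
    def test_identity_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([2, 1], [1, 1]) == pytest.approx(0.2)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedTestError):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100), min_size=1, max_size=10),
        st.integers(0, 2**31 - 1),
    )
    def test_symmetry_and_range(self, a, seed):
        b = np.random.default_rng(seed).uniform(0, 100, size=len(a))
        a = np.asarray(a)
        if a.sum() == 0 and b.sum() == 0:
            return
        d1, d2 = bray_curtis(a, b), bray_curtis(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0


class TestCompareNicheAbundances:
    def _origin_for(self, fecal_val, oral_val):
        table = _paired_table([(1, 1)] * 15, fecal_val=fecal_val, oral_val=oral_val)
        pairs = build_sample_pairs(table, "saliva")
        (res,) = compare_niche_abundances(table, pairs, ["SpX"])
        return res

    def test_oral_origin_when_oral_dominates(self):
        res = self._origin_for(fecal_val=0.01, oral_val=1.2)
        assert res.significant and res.inferred_origin == "oral"
        assert res.q_value >= res.p_value

    def test_fecal_origin_when_fecal_dominates(self):
        res = self._origin_for(fecal_val=20.0, oral_val=0.05)
        assert res.significant and res.inferred_origin == "fecal"

    def test_indeterminate_when_not_significant(self):
        table = _paired_table(
            [(1, 1)] * 6, fecal_val=1.0, oral_val=1.0
        )
        # perturb one pair so the test is defined but far from significant
        table.data.loc[
            (table.data["sample_id"] == "or0") & (table.data["species"] == "SpX"),
            "relative_abundance",
        ] = 1.5
        pairs = build_sample_pairs(table, "saliva")
        (res,) = compare_niche_abundances(table, pairs, ["SpX"])
        assert not res.significant
        assert res.inferred_origin == "indeterminate"

    def test_degenerate_species_flagged_not_significant(self):
        table = _paired_table([(1, 1)] * 5, fecal_val=1.0, oral_val=1.0)
        pairs = build_sample_pairs(table, "saliva")
        (res,) = compare_niche_abundances(table, pairs, ["SpX"])
        assert res.degenerate_test and not res.significant


class TestSummaries:
    def test_whiskers_exclude_outliers(self):
        s = box_summary([1, 2, 3, 4, 100])
        assert (s.q1, s.q3) == (2, 4)
        assert s.whisker_high == 4
        assert s.whisker_low == 1

    def test_log_transform_uses_smallest_nonzero_pseudocount(self):
        table = _paired_table([(0, 1)], oral_val=0.1)
        mat = table.matrix()  # SpX absent from stool -> exact zero entry
        logged = log_transform(mat)
        assert logged.min().min() == pytest.approx(np.log10(0.0 + 0.1))
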