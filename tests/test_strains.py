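"""Marker presence/absence patterns and strain-consistency calls."""

import pandas as pd
import pytest

from oralgut import (
    MarkerPattern,
    StrainCall,
    binarize_pattern,
    call_shared_strains,
    count_consistent_individuals,
    eligible_samples,
    pattern_match,
)

from conftest import make_markers


def _map(species, n):
    return {f"{species}_m{i:02d}": species for i in range(n)}


class TestBinarize:
    def test_nine_of_ten_coverage(self):
        markers = make_markers(
            _map("SpA", 10), [("S1", f"SpA_m{i:02d}", 1.0) for i in range(9)]
        )
        pat = binarize_pattern(markers, "S1", "SpA")
        assert pat.coverage == pytest.approx(0.9)
        assert sum(pat.presence) == 9

    def test_no_entries_all_absent(self):
        markers = make_markers(_map("SpA", 5), [("S2", "SpA_m00", 1.0)])
        pat = binarize_pattern(markers, "S1", "SpA")
        assert pat.coverage == 0.0
        assert set(pat.presence) == {0}

    def test_presence_strictly_above_threshold(self):
        markers = make_markers(
            _map("SpA", 3),
            [("S1", "SpA_m00", 0.5), ("S1", "SpA_m01", 1.0), ("S1", "SpA_m02", 2.0)],
        )
        pat = binarize_pattern(markers, "S1", "SpA", marker_presence_threshold=1.0)
        assert pat.presence == (0, 0, 1)
        assert pat.coverage == pytest.approx(1 / 3)

    def test_unknown_species_rejected(self):
        markers = make_markers(_map("SpA", 3), [("S1", "SpA_m00", 1.0)])
        with pytest.raises(ValueError, match="SpB"):
            binarize_pattern(markers, "S1", "SpB")


class TestEligibility:
    def _markers(self, n_present, n_total=20):
        return make_markers(
            _map("SpA", n_total),
            [("S1", f"SpA_m{i:02d}", 1.0) for i in range(n_present)],
        )

    def test_boundary_090_inclusive(self):
        markers = self._markers(18, 20)  # coverage exactly 0.9
        assert len(eligible_samples(markers, ["S1"], "SpA", 0.9)) == 1

    def test_below_boundary_excluded(self):
        markers = self._markers(17, 20)  # coverage 0.85
        assert eligible_samples(markers, ["S1"], "SpA", 0.9) == []

    def test_lower_cutoff_gives_superset(self):
        markers = make_markers(
            _map("SpA", 20),
            [("S1", f"SpA_m{i:02d}", 1.0) for i in range(18)]
            + [("S2", f"SpA_m{i:02d}", 1.0) for i in range(17)],
        )
        strict = {p.sample_id for p in eligible_samples(markers, ["S1", "S2"], "SpA", 0.9)}
        loose = {p.sample_id for p in eligible_samples(markers, ["S1", "S2"], "SpA", 0.8)}
        assert strict <= loose
        assert loose == {"S1", "S2"}


class TestPatternMatch:
    def _pat(self, presence, species="SpA", sid="S1"):
        cov = sum(presence) / len(presence)
        return MarkerPattern(sid, species, tuple(presence), cov)

    def test_identity_and_reflexivity(self):
        a = self._pat([1, 0, 1])
        assert pattern_match(a, a)
        assert pattern_match(a, self._pat([1, 0, 1], sid="S2"))

    def test_single_position_difference(self):
        assert not pattern_match(self._pat([1, 0, 1]), self._pat([1, 1, 1], sid="S2"))

    def test_symmetric(self):
        a, b = self._pat([1, 1, 0]), self._pat([1, 0, 0], sid="S2")
        assert pattern_match(a, b) == pattern_match(b, a)

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different species"):
            pattern_match(self._pat([1]), self._pat([1], species="SpB"))


def _meta(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "subject_id", "body_site"])
    return df.set_index("sample_id")


class TestCallSharedStrains:
    def _cohort_markers(self):
        """u1: stool==tongue; u2: stool==tongue==buccal; u3: oral coverage 0.85."""
        mm = _map("SpA", 20)
        full = [f"SpA_m{i:02d}" for i in range(20)]
        minus_last = full[:19]
        entries = []
        entries += [("u1_st", m, 1.0) for m in minus_last]
        entries += [("u1_td", m, 1.0) for m in minus_last]
        entries += [("u2_st", m, 1.0) for m in full]
        entries += [("u2_td", m, 1.0) for m in full]
        entries += [("u2_bm", m, 1.0) for m in full]
        entries += [("u3_st", m, 1.0) for m in full]
        entries += [("u3_td", m, 1.0) for m in full[:17]]  # coverage 0.85
        meta = _meta(
            [
                ("u1_st", "u1", "stool"), ("u1_td", "u1", "tongue_dorsum"),
                ("u2_st", "u2", "stool"), ("u2_td", "u2", "tongue_dorsum"),
                ("u2_bm", "u2", "buccal_mucosa"),
                ("u3_st", "u3", "stool"), ("u3_td", "u3", "tongue_dorsum"),
            ]
        )
        return make_markers(mm, entries), meta

    def test_single_site_match(self):
        markers, meta = self._cohort_markers()
        calls = {c.subject_id: c for c in call_shared_strains(markers, meta, ["SpA"])}
        assert calls["u1"].matched_oral_sites == frozenset({"tongue_dorsum"})
        assert calls["u1"].is_consistent

    def test_multi_site_match(self):
        markers, meta = self._cohort_markers()
        calls = {c.subject_id: c for c in call_shared_strains(markers, meta, ["SpA"])}
        assert calls["u2"].matched_oral_sites == frozenset(
            {"tongue_dorsum", "buccal_mucosa"}
        )

    def test_low_coverage_oral_subject_omitted(self):
        markers, meta = self._cohort_markers()
        calls = call_shared_strains(markers, meta, ["SpA"])
        assert "u3" not in {c.subject_id for c in calls}

    def test_lowering_coverage_min_never_removes_consistency(self):
        markers, meta = self._cohort_markers()
        strict = {
            c.subject_id
            for c in call_shared_strains(markers, meta, ["SpA"], coverage_min=0.9)
            if c.is_consistent
        }
        loose = {
            c.subject_id
            for c in call_shared_strains(markers, meta, ["SpA"], coverage_min=0.8)
            if c.is_consistent
        }
        assert strict <= loose


class TestCountConsistent:
    def _call(self, subj, sp, sites):
        return StrainCall(subj, sp, frozenset(sites), f"{subj}_st")

    def test_paper_style_arithmetic_sums_individuals(self):
        # 1 + 3 + 1 + 2 matches across four species, all subjects distinct
        calls = [
            self._call("s1", "SpA", {"tongue_dorsum"}),
            self._call("s2", "SpB", {"saliva"}),
            self._call("s3", "SpB", {"tongue_dorsum", "buccal_mucosa"}),
            self._call("s4", "SpB", {"tongue_dorsum", "buccal_mucosa", "supragingival_plaque"}),
            self._call("s5", "SpC", {"supragingival_plaque"}),
            self._call("s6", "SpD", {"saliva"}),
            self._call("s7", "SpD", {"tongue_dorsum", "buccal_mucosa"}),
        ]
        assert count_consistent_individuals(calls) == 7

    def test_subject_matching_two_species_counts_once(self):
        calls = [
            self._call("s1", "SpA", {"saliva"}),
            self._call("s1", "SpB", {"tongue_dorsum"}),
        ]
        assert count_consistent_individuals(calls) == 1

    def test_inconsistent_and_empty(self):
        assert count_consistent_individuals([]) == 0
        calls = [self._call("s1", "SpA", set())]
        assert count_consistent_individuals(calls) == 0
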