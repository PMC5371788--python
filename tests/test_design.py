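import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stitchkit as sk
from stitchkit.complementarity import ScoreCutoffs
from stitchkit.design import best_candidate, candidate_count
from stitchkit.errors import DesignFailureError, ParameterError


def loose_params(**kw):
    """Parameters with every filter effectively disabled."""
    base = dict(
        gc_min=0, gc_max=100, tm_min=-100, tm_max=200,
        exclude_repeats=False, hairpin_max=10**6,
        cutoffs=ScoreCutoffs(
            self_max=1e9, three_prime_max=1e9, overhang_max=1e9, dimer_max=1e9
        ),
    )
    base.update(kw)
    return sk.DesignParameters(**base)


class TestEnumeration:
    @pytest.mark.parametrize(
        "area, size, inc, expected",
        [(30, 18, 2, 7), (20, 18, 1, 3), (18, 18, 2, 1)],
    )
    def test_window_count_closed_form(self, fixture_record, area, size, inc, expected):
        params = loose_params(
            search_area_5p=area, fwd_size=size, increment_fwd=inc
        )
        cands = sk.enumerate_candidates(fixture_record, params, "forward")
        assert len(cands) == expected == candidate_count(area, size, inc)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        area=st.integers(8, 200),
        size=st.integers(8, 40),
        inc=st.integers(1, 10),
    )
    def test_count_formula_property(self, fixture_record, area, size, inc):
        if area < size:
            with pytest.raises(ParameterError):
                candidate_count(area, size, inc)
            return
        params = loose_params(
            search_area_5p=area, search_area_3p=area,
            fwd_size=size, rev_size=size,
            increment_fwd=inc, increment_rev=inc,
        )
        for strand in ("forward", "reverse"):
            cands = sk.enumerate_candidates(
                fixture_record, params, strand, annotate=False
            )
            assert len(cands) == (area - size) // inc + 1

    def test_forward_cores_are_verbatim_slices(self, fixture_record):
        params = loose_params(search_area_5p=60, fwd_size=20)
        for c in sk.enumerate_candidates(fixture_record, params, "forward"):
            assert fixture_record.seq[c.start - 1:c.end] == c.core_seq
            assert c.end - c.start + 1 == len(c.core_seq)

    def test_reverse_cores_relocate_by_reverse_complement(self, fixture_record):
        params = loose_params(search_area_3p=60, rev_size=20)
        for c in sk.enumerate_candidates(fixture_record, params, "reverse"):
            slice_ = fixture_record.seq[c.start - 1:c.end]
            assert sk.reverse_complement(c.core_seq) == slice_
        # first reverse candidate abuts the 3' end
        assert max(c.end for c in sk.enumerate_candidates(
            fixture_record, params, "reverse")) == fixture_record.length

    def test_area_smaller_than_size_rejected(self, fixture_record):
        params = loose_params(search_area_5p=10, fwd_size=18)
        with pytest.raises(ParameterError):
            sk.enumerate_candidates(fixture_record, params, "forward")

    def test_all_pass_when_filters_disabled(self, fixture_record):
        params = loose_params()
        cands = sk.enumerate_candidates(fixture_record, params, "forward")
        assert cands and all(c.passes for c in cands)


class TestRepetitive:
    @pytest.mark.parametrize(
        "seq, flagged",
        [
            ("ACGCGCGCGT", True),   # 4 CG units in a row
            ("ATTTTA", True),       # homopolymer run of 4
            ("ACCCCA", True),
            ("ACGTACGA", False),
            ("ACGCGCGT", False),    # only 3 dinucleotide units
            ("ATGTGTGTGA", True),   # 4 TG units
            ("AATTAATT", False),
        ],
    )
    def test_repeat_definitions(self, seq, flagged):
        assert sk.is_repetitive(seq) is flagged


class TestFilters:
    def _candidate(self, rec, start, size, params):
        return sk.score_pinned_primer(rec, start, start + size - 1, "forward", params)

    def test_gc_clamp_rule(self, fixture_record):
        params = loose_params(gc_clamp_fwd=True)
        cands = sk.enumerate_candidates(fixture_record, params, "forward")
        for c in cands:
            if c.core_seq[-1] not in "GC":
                assert "gc_clamp" in c.fail_reasons
            else:
                assert "gc_clamp" not in c.fail_reasons

    def test_repetitive_fail_reason(self):
        rec = sk.generate_fixture(seed=5, length=200, repeat_insert="TTTTTT")
        params = loose_params(exclude_repeats=True, search_area_5p=200, fwd_size=20,
                              increment_fwd=1)
        cands = sk.enumerate_candidates(rec, params, "forward")
        flagged = [c for c in cands if "repetitive" in c.fail_reasons]
        assert flagged
        for c in flagged:
            assert sk.is_repetitive(c.core_seq)

    def test_gc_range_fail_reason(self, fixture_record):
        params = loose_params(gc_min=0, gc_max=10)
        cands = sk.enumerate_candidates(fixture_record, params, "forward")
        assert all("gc_range" in c.fail_reasons for c in cands
                   if c.gc_percent > 10)

    def test_filters_annotate_rather_than_drop(self, fixture_record):
        strict = loose_params(gc_min=49.9, gc_max=50.1)
        loose = loose_params()
        assert len(sk.enumerate_candidates(fixture_record, strict, "forward")) == len(
            sk.enumerate_candidates(fixture_record, loose, "forward")
        )


class TestMutantMode:
    def test_reverse_oligo_is_reverse_complement(self, fixture_record):
        fwd, rev, mutant_rev = sk.design_mutant_pair(
            fixture_record, "GATTACA", loose_params()
        )
        assert mutant_rev == "TGTAATC"
        assert fwd.strand == "forward" and rev.strand == "reverse"
        assert fwd.passes and rev.passes

    def test_palindromic_oligo(self, fixture_record):
        _, _, mutant_rev = sk.design_mutant_pair(
            fixture_record, "GAATTC", loose_params()
        )
        assert mutant_rev == "GAATTC"

    def test_empty_oligo_rejected(self, fixture_record):
        with pytest.raises(ParameterError):
            sk.design_mutant_pair(fixture_record, "", loose_params())

    def test_design_failure_reports_near_miss(self, fixture_record):
        params = loose_params(gc_min=99, gc_max=100)
        with pytest.raises(DesignFailureError) as err:
            sk.design_mutant_pair(fixture_record, "GATTACA", params)
        assert "near-miss" in str(err.value)

    def test_best_candidate_ranking_is_deterministic(self, fixture_record):
        params = loose_params()
        cands = sk.enumerate_candidates(fixture_record, params, "forward")
        assert best_candidate(cands, params) == best_candidate(
            list(reversed(cands)), params
        )
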