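"""Superposition forward model, heterozygote detection and base subtraction."""

import pytest
from hypothesis import given, settings, strategies as st

from amplityper.phasing import (MixedTrace, PhasingError, SuperpositionModel,
                                detect_heterozygote, iupac_union,
                                phase_individual, realign_recovered,
                                subtract_reference, superimpose)
from amplityper.synth import SimulationSpec, generate_trace_pair

SPEC = SimulationSpec()


class TestSuperimpose:
    def test_identity_superposition_is_clean(self):
        trace = superimpose("ACGTACGT", "ACGTACGT")
        assert trace.read == "ACGTACGT"
        assert trace.ambiguous_positions == ()

    def test_snp_becomes_union_code(self):
        assert superimpose("ACGT", "AGGT").read == "ASGT"
        assert iupac_union("C", "G") == "S"

    def test_insertion_shifts_tail_into_ambiguity(self):
        r1, r2, trace, truth = generate_trace_pair(SPEC, seed=11,
                                                   force_snps=0,
                                                   force_indel=True)
        p = truth["insertion_point"]
        assert trace.read[: p - 1] == r1[: p - 1]
        tail = trace.read[p - 1:]
        ambiguous = sum(ch not in "ACGT" for ch in tail)
        # expected mismatch rate of a sequence against itself shifted by 6
        assert 0.4 < ambiguous / len(tail) < 0.95

    def test_gap_characters_rejected(self):
        with pytest.raises(ValueError):
            superimpose("AC-T", "ACGT")

    def test_skewed_mix_surfaces_minor_sparsely(self):
        r1 = "ACGT" * 200
        r2 = "AGGT" * 200  # minor copy differs at every 2nd-of-4 position
        trace = superimpose(r1, r2, mixing="skewed", seed=5)
        surfaced = sum(ch not in "ACGT" for ch in trace.read)
        assert 0 < surfaced < 60  # rate 0.1 of 200 differing sites, not all


class TestDetectHeterozygote:
    def test_clean_read_not_heterozygous(self):
        het = detect_heterozygote(MixedTrace(read="ACGT" * 30))
        assert not het.is_heterozygous and het.breakpoint is None

    def test_single_additive_site_not_heterozygous(self):
        read = "ACGT" * 10 + "R" + "ACGT" * 10
        het = detect_heterozygote(MixedTrace(read=read))
        assert not het.is_heterozygous
        assert het.additive_sites == (41,)

    def test_breakpoint_near_insertion_point(self):
        _, _, trace, truth = generate_trace_pair(SPEC, seed=3, force_indel=True)
        het = detect_heterozygote(trace)
        assert het.is_heterozygous
        assert abs(het.breakpoint - truth["insertion_point"]) <= 6

    def test_window_smaller_than_min_run_rejected(self):
        with pytest.raises(ValueError):
            detect_heterozygote(MixedTrace(read="ACGT"), window=3, min_run=4)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.data())
    def test_adding_ambiguities_never_unflags(self, seed, data):
        # monotonicity: extra ambiguities can only strengthen a het call
        _, _, trace, _ = generate_trace_pair(SPEC, seed=seed, force_indel=True)
        het_before = detect_heterozygote(trace).is_heterozygous
        pos = data.draw(st.integers(0, len(trace.read) - 1))
        read = trace.read[:pos] + "N" + trace.read[pos + 1:]
        het_after = detect_heterozygote(MixedTrace(read=read)).is_heterozygous
        assert het_after or not het_before


class TestSubtractReference:
    def test_snp_only_pair_recovered_full_length(self):
        r1, r2, trace, _ = generate_trace_pair(SPEC, seed=21, force_snps=3,
                                               force_indel=False)
        res = subtract_reference(trace, r1)
        assert res.mode == "both_recovered"
        assert res.ribotype_2 == r2
        assert res.resolved_through == len(trace.read)

    def test_insertion_pair_recovered_over_resolvable_window(self):
        r1, r2, trace, _ = generate_trace_pair(SPEC, seed=22, force_indel=True)
        res = subtract_reference(trace, r1)
        assert res.ribotype_2 == r2[: len(trace.read)]

    def test_reference_choice_is_symmetric(self):
        r1, r2, trace, _ = generate_trace_pair(SPEC, seed=23, force_indel=True)
        res = subtract_reference(trace, r2)
        assert res.ribotype_2 == r1[: len(trace.read)]

    def test_skewed_trace_yields_dominant_only(self):
        r1, r2, trace, _ = generate_trace_pair(SPEC, seed=24, mixing="skewed")
        res = subtract_reference(trace, r1)
        assert res.mode == "dominant_only" and res.ribotype_2 is None

    def test_short_reference_rejected(self):
        _, _, trace, _ = generate_trace_pair(SPEC, seed=25)
        with pytest.raises(ValueError):
            subtract_reference(trace, "ACGT")

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_identity_property(self, seed):
        """superimpose(reference, subtracted) reproduces the read exactly."""
        r1, r2, trace, _ = generate_trace_pair(SPEC, seed=seed)
        res = subtract_reference(trace, r1)
        redone = superimpose(r1[: len(res.ribotype_2)], res.ribotype_2)
        assert redone.read == trace.read


class TestPhaseIndividual:
    def test_correct_neighbour_found_among_candidates(self):
        r1, r2, trace, _ = generate_trace_pair(SPEC, seed=31, force_snps=2,
                                               force_indel=True)
        wrong1 = "A" * len(r1)
        wrong2 = r1[:100] + "G" * (len(r1) - 100)
        ref_id, res = phase_individual(
            trace, [("far", wrong1, 9.0), ("near", wrong2, 1.0),
                    ("right", r1, 2.0)])
        assert ref_id == "right"
        assert res.ribotype_2 == r2[: len(trace.read)]

    def test_zero_candidates_rejected(self):
        _, _, trace, _ = generate_trace_pair(SPEC, seed=32)
        with pytest.raises(PhasingError):
            phase_individual(trace, [])

    def test_equal_distance_tie_resolved_by_id_order(self):
        r1, r2, trace, _ = generate_trace_pair(SPEC, seed=33, force_snps=1,
                                               force_indel=False)
        ref_id, _ = phase_individual(
            trace, [("b", r1, 1.0), ("a", r1, 1.0)])
        assert ref_id == "a"

    def test_all_inconsistent_candidates_raise(self):
        _, _, trace, _ = generate_trace_pair(SPEC, seed=34, force_snps=3)
        with pytest.raises(PhasingError, match="inconsistent"):
            phase_individual(trace, [("x", "A" * len(trace.read), 0.0)])


def test_realign_recovered_reinserts_gaps():
    aligned = "AC--GT"
    assert realign_recovered("ACGT", aligned) == "AC--GT"
    with pytest.raises(ValueError):
        realign_recovered("ACG", aligned)
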