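import pytest

from mtvntr.seqio import revcomp
from mtvntr.type1_model import (
    ElongationEvent,
    F_UNIT,
    NotType1Error,
    R_UNIT,
    decompose,
    elongate_once,
    initial_vntr,
    innermost_unit,
    sample_events,
    simulate_elongation,
)

E = ElongationEvent


class TestConstants:
    def test_units_are_mutual_revcomps(self):
        assert revcomp(F_UNIT) == R_UNIT
        assert len(F_UNIT) == len(R_UNIT) == 11

    def test_initial_vntr(self):
        assert initial_vntr("F") == "TCCCTTTAGGG"
        assert initial_vntr("R") == "CCCTAAAGGGA"
        with pytest.raises(ValueError):
            initial_vntr("X")


class TestElongateOnce:
    def test_r_incorporation_into_f(self):
        # spacer G + R unit replace the central TT of the F unit
        assert elongate_once("TCCCTTTAGGG", E("R", "G")) == "TCCCTGCCCTAAAGGGAAGGG"

    def test_f_incorporation_into_compound(self):
        out = elongate_once("TCCCTGCCCTAAAGGGAAGGG", E("F"))
        assert out == "TCCCTGCCCTATCCCTTTAGGGTGGGAAGGG"
        assert len(out) == 31

    def test_incompatible_center_rejected(self):
        with pytest.raises(ValueError, match="AA center"):
            elongate_once("TCCCTTTAGGG", E("F"))

    def test_event_validation(self):
        with pytest.raises(ValueError):
            E("R")  # missing spacer
        with pytest.raises(ValueError):
            E("F", "G")  # spurious spacer
        with pytest.raises(ValueError):
            E("R", "A")  # spacer must be G or C


class TestSimulate:
    def test_length_law(self):
        for k in range(0, 9):
            events = [E("R", "G") if i % 2 == 0 else E("F") for i in range(k)]
            assert len(simulate_elongation("F", events)) == 11 + 10 * k

    def test_empty_events_identity(self):
        assert simulate_elongation("F", []) == F_UNIT

    def test_alternation_enforced(self):
        with pytest.raises(ValueError, match="event 1"):
            simulate_elongation("F", [E("R", "G"), E("R", "G")])

    def test_first_event_compatibility(self):
        with pytest.raises(ValueError, match="event 0"):
            simulate_elongation("F", [E("F")])


class TestSampleEvents:
    def test_degenerate_probability(self):
        evs = sample_events(4, "F", spacer_prob_G=1.0, seed=123)
        assert [e.kind for e in evs] == ["R", "F", "R", "F"]
        assert all(e.spacer == "G" for e in evs if e.kind == "R")

    def test_zero_events(self):
        assert sample_events(0, "F", 0.5, seed=7) == []

    def test_deterministic_given_seed(self):
        assert sample_events(8, "R", 0.5, seed=11) == sample_events(8, "R", 0.5, seed=11)

    def test_sampled_lists_are_valid(self):
        for seed in range(5):
            evs = sample_events(7, "F", 0.3, seed=seed)
            simulate_elongation("F", evs)  # must not raise


class TestDecompose:
    def test_worked_nine_unit_allele(self):
        # alternating growth from F: 8 events -> 91 nt -> 5 F + 4 R
        allele = simulate_elongation("F", [E("R", "G"), E("F")] * 4)
        assert len(allele) == 91
        comp = decompose(allele)
        assert (comp.n_f, comp.n_r, comp.center) == (5, 4, "TT")

    def test_one_more_r_event_gives_five_five(self):
        allele = simulate_elongation("F", [E("R", "G"), E("F")] * 4 + [E("R", "G")])
        assert len(allele) == 101
        comp = decompose(allele)
        assert (comp.n_f, comp.n_r, comp.center) == (5, 5, "AA")

    def test_single_f_unit(self):
        comp = decompose("TCCCTTTAGGG")
        assert (comp.n_f, comp.n_r, comp.center) == (1, 0, "TT")
        assert comp.snps == []
        assert innermost_unit(comp) == "F"

    def test_spacer_observation_recorded(self):
        # spacer G mutated to C in the second left motif: counts unchanged,
        # the observation lands on motif 2 of the left side
        mut = "TCCCT" + "C" + "CCCTAAAGGGAAGGG"
        comp = decompose(mut)
        assert (comp.n_f, comp.n_r) == (1, 1)
        assert comp.mismatch_count == 0
        spacer_obs = [s for s in comp.snps if s.ref == "S"]
        assert len(spacer_obs) == 1
        assert (spacer_obs[0].side, spacer_obs[0].index, spacer_obs[0].obs) == ("L", 2, "C")

    def test_substitution_recorded_and_tolerated(self):
        allele = simulate_elongation("F", [E("R", "G"), E("F")] * 2)
        mutated = allele[:2] + "A" + allele[3:]  # TCCCT -> TCACT at motif 1
        comp = decompose(mutated)
        assert (comp.n_f, comp.n_r) == (3, 2)
        assert comp.mismatch_count == 1
        subs = [s for s in comp.snps if s.ref != "S"]
        assert subs == [type(subs[0])(1, "C", "A", 2, "L")]

    def test_not_type1_error(self):
        with pytest.raises(NotType1Error):
            decompose("ACGTACGTACGTACGTACGT")
        with pytest.raises(NotType1Error):
            decompose("ACGT")  # too short

    def test_indel_fallback_parses_tcct_variant(self):
        # a 1-nt deletion in one left motif (TCCCT -> TCCT) still parses,
        # flagged as an indel fallback
        allele = simulate_elongation("F", [E("R", "G"), E("F")] * 2)
        assert allele.startswith("TCCCTGCCCTA")
        deleted = allele[:1] + allele[2:]  # TCCCT -> TCCT outermost
        comp = decompose(deleted)
        assert comp.indel_fallback
        assert (comp.n_f, comp.n_r) == (3, 2)


class TestRoundTrip:
    def test_exhaustive_roundtrip(self, event_universe):
        """decompose inverts simulate_elongation for every alternating event
        list up to 8 events, both start units and all spacer choices."""
        for start, events in event_universe:
            allele = simulate_elongation(start, events)
            exp_f = (start == "F") + sum(1 for e in events if e.kind == "F")
            exp_r = (start == "R") + sum(1 for e in events if e.kind == "R")
            last = events[-1].kind if events else start
            comp = decompose(allele)
            assert len(allele) == 11 + 10 * len(events)
            assert (comp.n_f, comp.n_r) == (exp_f, exp_r)
            assert comp.center == ("TT" if last == "F" else "AA")
            assert innermost_unit(comp) == last
            assert comp.balanced and comp.mismatch_count == 0
            assert comp.strand == "+"
            assert len(allele) == 11 + 10 * (comp.n_f + comp.n_r - 1)

    def test_strand_duality(self, event_universe):
        """The reverse complement of any model allele parses with F/R counts
        swapped and the center dinucleotide complemented."""
        for start, events in event_universe:
            allele = simulate_elongation(start, events)
            fwd = decompose(allele)
            rev = decompose(revcomp(allele))
            assert (rev.n_f, rev.n_r) == (fwd.n_r, fwd.n_f)
            assert rev.center == ("AA" if fwd.center == "TT" else "TT")

    def test_one_event_extension_changes_one_motif_per_side(self):
        """A single incorporation adds exactly one left and one right
        half-motif to the parse (the half-repeat growth seen in mate
        alleles)."""
        allele = simulate_elongation("F", [E("R", "C"), E("F")] * 3)
        comp = decompose(allele)
        ext = elongate_once(allele, E("R", "C"))
        comp2 = decompose(ext)
        assert len(comp2.left_motifs) == len(comp.left_motifs) + 1
        assert len(comp2.right_motifs) == len(comp.right_motifs) + 1
        assert comp2.n_r == comp.n_r + 1
        assert comp2.n_f == comp.n_f
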