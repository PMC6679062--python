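import numpy as np
import pytest

from mtvntr.genotype import count_repeats, in_silico_pcr
from mtvntr.inheritance import MON, call_trio, donated_nucleus
from mtvntr.seqio import SeqRecord
from mtvntr.synthetic_data import (
    SimConfig,
    generate_genome,
    generate_panel,
    generate_trio,
    monokaryotic_offspring,
)
from mtvntr.type1_model import decompose
from mtvntr.vntr_detect import (
    TYPE_I,
    TYPE_II,
    classify_loci,
    detect_tandem_arrays,
    find_inverted_partners,
)

SMALL = dict(genome_length=3000, n_type1=1, n_type2=1, flank_length=60)


class TestConfig:
    def test_copy_range_validated(self):
        with pytest.raises(ValueError):
            SimConfig(copy_range=(1, 5))
        with pytest.raises(ValueError):
            SimConfig(copy_range=(2, 30))

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            SimConfig(snp_rate_per_unit=1.5)


class TestGenome:
    def test_deterministic(self):
        r1, t1 = generate_genome(SimConfig(seed=42, **SMALL))
        r2, t2 = generate_genome(SimConfig(seed=42, **SMALL))
        assert r1.sequence == r2.sequence
        assert [(l.start, l.end) for l in t1] == [(l.start, l.end) for l in t2]

    def test_planted_type2_found_by_detector(self):
        cfg = SimConfig(seed=0, genome_length=2000, n_type1=0, n_type2=1,
                        type2_units=("GCTCCGC",), flank_length=60)
        rec, truth = generate_genome(cfg)
        assert len(truth) == 1 and truth[0].vntr_type == TYPE_II
        found = detect_tandem_arrays(rec)
        assert [(a.start, a.end, a.copy_number) for a in found] == [
            (t.start, t.end, t.arrays[0].copy_number) for t in truth
        ]

    def test_planted_type1_decomposable(self):
        cfg = SimConfig(seed=1, **SMALL)
        rec, truth = generate_genome(cfg)
        t1 = [l for l in truth if l.vntr_type == TYPE_I and "partner_of" not in l.meta]
        assert t1
        for locus in t1:
            vs, ve = locus.meta["vntr_span"]
            comp = decompose(rec.sequence[vs:ve])
            assert (comp.n_f, comp.n_r) == (locus.meta["n_f"], locus.meta["n_r"])

    def test_partner_is_reverse_complement_family(self):
        rec, truth = generate_genome(SimConfig(seed=2, **SMALL))
        loci = find_inverted_partners(classify_loci(detect_tandem_arrays(rec)))
        t1 = [l for l in loci if l.vntr_type == TYPE_I]
        assert len(t1) == 2
        assert t1[0].partner_locus_id == t1[1].locus_id
        assert t1[1].partner_locus_id == t1[0].locus_id

    def test_amplicons_unique_and_match_truth(self):
        rec, truth = generate_genome(SimConfig(seed=3, **SMALL))
        for locus in truth:
            s, e = locus.meta["amplicon_span"]
            assert in_silico_pcr(rec, locus.meta["primers"]) == rec.sequence[s:e]

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(SimConfig(seed=0, genome_length=500))

    def test_circular_flag_set(self):
        rec, _ = generate_genome(SimConfig(seed=4, **SMALL))
        assert rec.circular


class TestPanel:
    def test_copy_numbers_within_range(self):
        cfg = SimConfig(seed=5, n_strains=10, snp_rate_per_unit=0.0, flank_length=60)
        profiles, truth = generate_panel(cfg)
        assert len(profiles) == 10
        lo, hi = cfg.copy_range
        for p in profiles:
            for allele in p.alleles.values():
                assert allele.repeat_count >= 2
        t2 = truth[truth["kind"] == TYPE_II]
        assert t2["copies"].between(lo, hi).all()

    def test_snp_rate_zero_gives_clean_type2(self):
        cfg = SimConfig(seed=6, n_strains=5, n_type1=0, n_type2=2,
                        snp_rate_per_unit=0.0, flank_length=60)
        profiles, _ = generate_panel(cfg)
        for p in profiles:
            for allele in p.alleles.values():
                assert allele.unit_snps == []

    def test_counts_match_planted_truth(self):
        cfg = SimConfig(seed=7, n_strains=8, snp_rate_per_unit=0.0, flank_length=60)
        profiles, truth = generate_panel(cfg)
        for p in profiles:
            for lid, allele in p.alleles.items():
                row = truth[
                    (truth.strain_id == p.strain_id) & (truth.locus_id == lid)
                ].iloc[0]
                expected = (
                    row["copies"] if row["kind"] == TYPE_II
                    else row["n_f"] + row["n_r"]
                )
                assert allele.repeat_count == expected

    def test_deterministic(self):
        cfg = SimConfig(seed=8, n_strains=3, flank_length=60)
        p1, _ = generate_panel(cfg)
        p2, _ = generate_panel(cfg)
        for a, b in zip(p1, p2):
            assert {k: v.sequence for k, v in a.alleles.items()} == {
                k: v.sequence for k, v in b.alleles.items()
            }

    def test_offspring_inherit_parent_mitochondria(self):
        cfg = SimConfig(seed=9, n_strains=2, flank_length=60)
        profiles, _ = generate_panel(cfg)
        parent = profiles[0]
        child = monokaryotic_offspring(parent, sorted(parent.nuclear_types)[0])
        assert len(child.nuclear_types) == 1
        assert {k: v.sequence for k, v in child.alleles.items()} == {
            k: v.sequence for k, v in parent.alleles.items()
        }
        with pytest.raises(ValueError):
            monokaryotic_offspring(parent, "A999")


class TestTrio:
    CFG = dict(n_type1=1, n_type2=2, flank_length=60, snp_rate_per_unit=0.0)

    def test_no_elongation_gives_identical_mate_profile(self):
        cfg = SimConfig(seed=10, p_elongation_per_mate=0.0, **self.CFG)
        trio, truth = generate_trio(cfg, rng=np.random.default_rng(10))
        for lid in trio.mon.alleles:
            assert trio.mate.alleles[lid].sequence == trio.mon.alleles[lid].sequence
        assert not any(truth["elongated"].values())
        assert call_trio(trio).overall == MON

    def test_forced_elongation_lengthens_and_flags(self):
        cfg = SimConfig(seed=11, p_elongation_per_mate=1.0, **self.CFG)
        trio, truth = generate_trio(cfg, rng=np.random.default_rng(11))
        oc = call_trio(trio)
        for lid, elong in truth["elongated"].items():
            assert elong
            assert (
                trio.mate.alleles[lid].amplicon_length
                > trio.mon.alleles[lid].amplicon_length
            )
        # markers called UP must carry the elongation flag
        for lid, call in oc.per_marker.items():
            if call == "UP":
                assert oc.elongation_flags[lid]

    def test_donor_round_trip(self):
        rng = np.random.default_rng(12)
        cfg = SimConfig(seed=12, **self.CFG)
        for _ in range(10):
            trio, truth = generate_trio(cfg, rng=rng)
            assert donated_nucleus(trio) == truth["donor"]

    def test_only_mon_origin_supported(self):
        cfg = SimConfig(seed=13, **self.CFG)
        with pytest.raises(ValueError):
            generate_trio(cfg, truth_origin="DI")


class TestFullPipeline:
    def test_detect_classify_decompose_genotype_on_one_genome(self):
        """End-to-end: genome-wide detection, classification, partnering,
        decomposition and repeat counting all reproduce the planted truth."""
        cfg = SimConfig(seed=21, genome_length=8000, n_type1=1, n_type2=2,
                        flank_length=80)
        rec, truth = generate_genome(cfg)
        loci = find_inverted_partners(classify_loci(detect_tandem_arrays(rec)))
        t = sorted((l.vntr_type, tuple((a.start, a.end) for a in l.arrays)) for l in truth)
        f = sorted((l.vntr_type, tuple((a.start, a.end) for a in l.arrays)) for l in loci)
        assert t == f
        for locus in truth:
            vs, ve = locus.meta["vntr_span"]
            segment = rec.sequence[vs:ve]
            if locus.vntr_type == TYPE_II:
                count, snps = count_repeats(
                    in_silico_pcr(rec, locus.meta["primers"]), locus.meta["unit"]
                )
                assert count == locus.meta["copies"]
                assert snps == []
            else:
                comp = decompose(segment)
                assert (comp.n_f, comp.n_r) == (
                    locus.meta["n_f"], locus.meta["n_r"]
                )
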