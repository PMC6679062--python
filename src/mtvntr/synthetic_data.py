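"""Synthetic mitochondrial genomes, strain panels and mating trios.

The generator emulates the observable structure of *L. edodes* mtDNA VNTR
data so every pipeline stage can be tested against known ground truth:

* circular ~120 kb genomes carrying implanted Type I loci (grown with the
  F/R elongation model, each with a reverse-complement partner locus
  elsewhere on the molecule) and Type II loci (simple tandem arrays of the
  7- and 17-nt units), every locus flanked by unique 20-nt primer sites;
* strain panels whose Type II copy numbers span the observed 2-11 range,
  with optional within-unit SNPs;
* Di-Mon mating trios with strictly uniparental (monokaryon) mitochondrial
  inheritance and occasional repeat-unit addition in the mate.

Background sequence is uniform over ACGT but *screened*: while streaming
bases, any base that would complete a two-copy tandem window with a
primitive unit of >= 5 nt (the detector's reporting floor) is resampled,
and the junctions of planted loci are re-rolled until no array crosses
them.  This keeps the planting record an exact oracle for the detector.
All randomness flows from the single seed in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genotype import PrimerPair, StrainProfile, VntrAllele, count_repeats
from .seqio import SeqRecord, revcomp
from .type1_model import (
    ElongationEvent,
    decompose,
    elongate_once,
    sample_events,
    simulate_elongation,
)
from .vntr_detect import (
    TYPE_I,
    TYPE_II,
    TandemArray,
    VntrLocus,
    detect_tandem_arrays,
    _primitive_period,
)

__all__ = [
    "SimConfig",
    "TYPE2_UNITS",
    "generate_genome",
    "generate_panel",
    "generate_trio",
    "monokaryotic_offspring",
]

#: The three simple tandem-repeat units observed in *L. edodes* mtDNA.
TYPE2_UNITS = ("GCTCCGC", "GCGTAGC", "TACTAATCCTCCTCCCT")

_MIN_D, _MAX_D = 5, 30
_PRIMER_LEN = 20
_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the observed system: a ~120 kb circular molecule,
    Type II copy numbers between 2 and 11, Type I loci of 4-9 incorporation
    events (5-10 units), six markers per strain panel and a small
    per-marker elongation probability in mating (6 elongated markers were
    seen across 22 mates x 6 markers, i.e. about 0.05).
    """

    seed: int = 0
    genome_length: int = 120_000
    n_type1: int = 2
    n_type2: int = 3
    type2_units: tuple[str, ...] = TYPE2_UNITS
    copy_range: tuple[int, int] = (2, 11)
    type1_events_range: tuple[int, int] = (4, 9)
    snp_rate_per_unit: float = 0.02
    n_strains: int = 25
    p_elongation_per_mate: float = 0.05
    flank_length: int = 110

    def __post_init__(self) -> None:
        lo, hi = self.copy_range
        if not (2 <= lo <= hi <= 20):
            raise ValueError("copy_range must lie within [2, 20]")
        for p in (self.snp_rate_per_unit, self.p_elongation_per_mate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# Screened background stream
# ---------------------------------------------------------------------------


def _completes_array(seq: list[str], t: int, lo: int = 0) -> bool:
    """True if a 2-copy window of primitive period in [5, 30] ends at ``t``
    and starts at or after ``lo``."""
    for d in range(_MIN_D, _MAX_D + 1):
        a = t - 2 * d + 1
        if a < lo:
            return False  # larger d would start even earlier
        if seq[a : a + d] == seq[a + d : t + 1]:
            if _primitive_period("".join(seq[a : a + d])) >= _MIN_D:
                return True
    return False


def _extends_array(seq: list[str], t: int) -> bool:
    """True if the base at ``t`` continues, in phase, a 2-copy tandem
    window ending at ``t - 1`` (a fractional array extension)."""
    for d in range(_MIN_D, _MAX_D + 1):
        a = t - 2 * d
        if a < 0:
            return False
        if (
            seq[t] == seq[t - d]
            and seq[a : a + d] == seq[a + d : t]
            and _primitive_period("".join(seq[a + d : t])) >= _MIN_D
        ):
            return True
    return False


def _crosses_junction(seq: list[str], t: int, boundary: int) -> bool:
    """True if a 2-copy window ending at ``t`` starts before ``boundary``."""
    for d in range(_MIN_D, _MAX_D + 1):
        a = t - 2 * d + 1
        if a < 0:
            return False
        if a >= boundary:
            continue
        if seq[a : a + d] == seq[a + d : t + 1]:
            if _primitive_period("".join(seq[a : a + d])) >= _MIN_D:
                return True
    return False


def _push_screened(rng: np.random.Generator, seq: list[str], n: int) -> None:
    """Append ``n`` background bases, none completing a reportable array."""
    for _ in range(n):
        choices = rng.permutation(4)
        for b in choices:
            seq.append(_BASES[int(b)])
            t = len(seq) - 1
            if not _completes_array(seq, t) and not _extends_array(seq, t):
                break
            seq.pop()
        else:  # pragma: no cover - probability ~0 (needs 4 blocked bases)
            seq.append(_BASES[int(choices[0])])


def _push_fixed(
    rng: np.random.Generator, seq: list[str], fixed: str, frozen: int
) -> int:
    """Append a fixed segment, re-rolling preceding background until no
    tandem window crosses the left junction.  Returns the new frozen
    watermark (end of the fixed segment)."""
    for _ in range(100):
        base_len = len(seq)
        seq.extend(fixed)
        bad = any(
            _crosses_junction(seq, t, base_len)
            for t in range(base_len, len(seq))
        )
        # the last background base must not extend, in phase, an array
        # sitting at the start of the fixed segment (leftward fraction)
        if not bad and base_len > 0:
            b = base_len
            for d in range(_MIN_D, _MAX_D + 1):
                if b + 2 * d > len(seq):
                    break
                if (
                    seq[b - 1] == seq[b + d - 1]
                    and seq[b : b + d] == seq[b + d : b + 2 * d]
                    and _primitive_period("".join(seq[b : b + d])) >= _MIN_D
                ):
                    bad = True
                    break
        if not bad:
            return len(seq)
        del seq[base_len:]
        k = min(2 * _MAX_D, base_len - frozen)
        if k <= 0:  # nothing to re-roll; accept as-is
            seq.extend(fixed)
            return len(seq)
        del seq[base_len - k :]
        _push_screened(rng, seq, k)
    raise RuntimeError("could not place fixed segment without junction array")


def _random_primer(rng: np.random.Generator) -> str:
    while True:
        s = "".join(_BASES[int(b)] for b in rng.integers(0, 4, _PRIMER_LEN))
        # a primer must not itself contain a seedable repeat
        probe = list(s)
        if not any(_completes_array(probe, t) for t in range(len(probe))):
            return s


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def _draw_type1(cfg: SimConfig, rng: np.random.Generator):
    """One Type I allele: alternating events with a per-locus spacer."""
    k = int(rng.integers(cfg.type1_events_range[0], cfg.type1_events_range[1] + 1))
    spacer = "G" if rng.random() < 0.5 else "C"
    start_unit = "F" if rng.random() < 0.5 else "R"
    first = "R" if start_unit == "F" else "F"
    events = []
    kind = first
    for _ in range(k):
        events.append(
            ElongationEvent(kind, spacer) if kind == "R" else ElongationEvent(kind)
        )
        kind = "F" if kind == "R" else "R"
    allele = simulate_elongation(start_unit, events)
    comp = decompose(allele)
    return allele, {
        "start_unit": start_unit,
        "spacer": spacer,
        "n_events": k,
        "n_f": comp.n_f,
        "n_r": comp.n_r,
    }


def generate_genome(cfg: SimConfig) -> tuple[SeqRecord, list[VntrLocus]]:
    """A circular genome with implanted VNTR loci and its truth record.

    Each Type I locus is planted together with a reverse-complement partner
    locus elsewhere on the molecule; Type II loci are perfect ``unit^n``
    arrays.  Every locus is flanked by unique 20-nt primer sites placed
    ``cfg.flank_length`` nt away.  Truth loci carry exact array coordinates
    (locally re-derived for Type I, analytic for Type II) and generator
    metadata in ``meta`` (planted composition, primers, amplicon span).
    """
    rng = np.random.default_rng(cfg.seed)

    # build the cassette plan: (kind, vntr_seq, meta)
    cassettes = []
    for i in range(cfg.n_type1):
        allele, meta = _draw_type1(cfg, rng)
        meta = dict(meta)
        cassettes.append([TYPE_I, allele, meta, f"t1_{i}"])
        cassettes.append(
            [TYPE_I, revcomp(allele), {**meta, "partner_of": f"t1_{i}"}, f"t1_{i}p"]
        )
    for i in range(cfg.n_type2):
        unit = cfg.type2_units[i % len(cfg.type2_units)]
        copies = int(rng.integers(cfg.copy_range[0], cfg.copy_range[1] + 1))
        cassettes.append([TYPE_II, unit * copies, {"unit": unit, "copies": copies}, f"t2_{i}"])
    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[int(i)] for i in order]

    cassette_len = lambda c: 2 * _PRIMER_LEN + 2 * cfg.flank_length + len(c[1])
    total = sum(cassette_len(c) for c in cassettes)
    n_gaps = len(cassettes) + 1
    spare = cfg.genome_length - total - 200 * n_gaps
    if spare < 0:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for "
            f"{len(cassettes)} marker cassettes"
        )
    props = rng.dirichlet(np.ones(n_gaps))
    gaps = [200 + int(spare * p) for p in props]
    gaps[-1] += cfg.genome_length - total - sum(gaps)

    seq: list[str] = []
    frozen = 0
    placements = []
    for gap, cassette in zip(gaps, cassettes):
        _push_screened(rng, seq, gap)
        fwd_site = _random_primer(rng)
        frozen = _push_fixed(rng, seq, fwd_site, frozen)
        amp_start = frozen - _PRIMER_LEN
        _push_screened(rng, seq, cfg.flank_length)
        vntr_start = len(seq)
        frozen = _push_fixed(rng, seq, cassette[1], frozen)
        vntr_end = frozen
        _push_screened(rng, seq, cfg.flank_length)
        rev_site = _random_primer(rng)
        frozen = _push_fixed(rng, seq, rev_site, frozen)
        placements.append(
            (cassette, amp_start, vntr_start, vntr_end, frozen, fwd_site, rev_site)
        )
    _push_screened(rng, seq, gaps[-1])
    # the molecule is circular: re-roll tail background until no tandem
    # window spans the origin junction
    for _ in range(100):
        ext = seq + seq[: 2 * _MAX_D]
        wrap_bad = any(
            _completes_array(ext, t) or _extends_array(ext, t)
            for t in range(len(seq), len(ext))
        )
        if not wrap_bad:
            break
        k = min(2 * _MAX_D, gaps[-1])
        del seq[len(seq) - k :]
        _push_screened(rng, seq, k)
    else:  # pragma: no cover
        raise RuntimeError("could not close the circular junction cleanly")
    genome = "".join(seq)
    assert len(genome) == cfg.genome_length

    record = SeqRecord(
        id=f"synthetic_mtDNA_seed{cfg.seed}", sequence=genome, circular=True
    )

    for site in {p[5] for p in placements} | {p[6] for p in placements}:
        if genome.count(site) != 1:  # pragma: no cover - p ~ L/4^20
            raise RuntimeError("primer site collision; use a different seed")

    truth: list[VntrLocus] = []
    for idx, (cassette, amp_start, vs, ve, amp_end, fwd_site, rev_site) in enumerate(
        placements, start=1
    ):
        kind, vntr_seq, meta, tag = cassette
        meta = {
            **meta,
            "tag": tag,
            "amplicon_span": (amp_start, amp_end),
            "primers": PrimerPair(
                name=f"locus{idx}", fwd=fwd_site, rev=revcomp(rev_site)
            ),
            "vntr_span": (vs, ve),
        }
        if kind == TYPE_II:
            arrays = [
                TandemArray(
                    seq_id=record.id,
                    start=vs,
                    end=ve,
                    unit=meta["unit"],
                    copy_number=float(meta["copies"]),
                    purity=1.0,
                )
            ]
        else:
            # Type I arrays are derived by isolated detection in their real
            # flank context: the two half-motif arrays carry a phase break
            # at the nucleating unit, so their exact maximal span (including
            # any in-phase fractional base at the boundary) is defined by
            # the same maximality rule the genome-wide scan applies.
            margin = 40
            lo = max(0, vs - margin)
            local = detect_tandem_arrays(
                SeqRecord("local", record.sequence[lo : ve + margin])
            )
            arrays = [
                TandemArray(
                    seq_id=record.id,
                    start=lo + a.start,
                    end=lo + a.end,
                    unit=a.unit,
                    copy_number=a.copy_number,
                    purity=a.purity,
                )
                for a in local
                if lo + a.end > vs and lo + a.start < ve
            ]
        truth.append(
            VntrLocus(
                locus_id=f"locus{idx}", vntr_type=kind, arrays=arrays, meta=meta
            )
        )
    # partner ids by tag
    by_tag = {l.meta["tag"]: l for l in truth}
    for locus in truth:
        partner_tag = locus.meta.get("partner_of")
        if partner_tag and partner_tag in by_tag:
            locus.partner_locus_id = by_tag[partner_tag].locus_id
            by_tag[partner_tag].partner_locus_id = locus.locus_id
    return record, truth


# ---------------------------------------------------------------------------
# Marker sets, panels and trios
# ---------------------------------------------------------------------------


def _guarded_flanks(rng: np.random.Generator, n: int, unit_hint: str):
    """Random flanks whose repeat-adjacent ends cannot extend a planted run.

    For a tandem unit ``unit_hint`` the last ``len(unit)`` bases of the left
    flank and the first ``len(unit)`` of the right flank are re-rolled until
    they are at least two substitutions away from the unit (so no extra full
    copy can anchor there), and the base right of the repeat differs from
    the unit's first base (so no fractional trailing copy accrues).
    """

    def draw(k: int) -> list[str]:
        return [_BASES[int(b)] for b in rng.integers(0, 4, k)]

    left, right = draw(n), draw(n)
    d = len(unit_hint)
    if d:
        while sum(1 for a, b in zip(left[-d:], unit_hint) if a != b) < 2:
            left[-d:] = draw(d)
        while (
            sum(1 for a, b in zip(right[:d], unit_hint) if a != b) < 2
            or right[0] == unit_hint[0]
        ):
            right[:d] = draw(d)
    return "".join(left), "".join(right)


@dataclass
class _Marker:
    locus_id: str
    kind: str  # TYPE_I or TYPE_II
    unit: str  # Type II tandem unit ("" for Type I)
    fwd_site: str
    rev_site: str
    flank_left: str
    flank_right: str

    @property
    def primers(self) -> PrimerPair:
        return PrimerPair(
            name=self.locus_id, fwd=self.fwd_site, rev=revcomp(self.rev_site)
        )

    def amplicon(self, vntr_seq: str) -> str:
        return (
            self.fwd_site
            + self.flank_left
            + vntr_seq
            + self.flank_right
            + self.rev_site
        )


def _make_marker_set(cfg: SimConfig, rng: np.random.Generator) -> list[_Marker]:
    markers = []
    for i in range(cfg.n_type1):
        markers.append(
            _Marker(f"VNTRsim{i + 1}", TYPE_I, "", _random_primer(rng),
                    _random_primer(rng), "", "")
        )
    for i in range(cfg.n_type2):
        unit = cfg.type2_units[i % len(cfg.type2_units)]
        markers.append(
            _Marker(f"VNTRsim{cfg.n_type1 + i + 1}", TYPE_II, unit,
                    _random_primer(rng), _random_primer(rng), "", "")
        )
    for m in markers:
        hint = m.unit if m.kind == TYPE_II else "TCCCT"
        m.flank_left, m.flank_right = _guarded_flanks(rng, cfg.flank_length, hint)
    return markers


def _mutate_type2(
    vntr: str, unit: str, rng: np.random.Generator, rate: float
) -> str:
    """Inject at most one substitution per unit copy with probability ``rate``."""
    d = len(unit)
    out = list(vntr)
    for c in range(len(vntr) // d):
        if rng.random() < rate:
            k = int(rng.integers(0, d))
            old = out[c * d + k]
            out[c * d + k] = rng.choice([b for b in _BASES if b != old])
    return "".join(out)


def _strain_allele(
    cfg: SimConfig, rng: np.random.Generator, marker: _Marker, strain_id: str
) -> tuple[VntrAllele, dict]:
    """Draw one strain's allele at one marker, with construction truth."""
    if marker.kind == TYPE_II:
        copies = int(rng.integers(cfg.copy_range[0], cfg.copy_range[1] + 1))
        vntr = _mutate_type2(
            marker.unit * copies, marker.unit, rng, cfg.snp_rate_per_unit
        )
        amplicon = marker.amplicon(vntr)
        count, snps = count_repeats(amplicon, marker.unit)
        allele = VntrAllele(
            strain_id=strain_id,
            locus_id=marker.locus_id,
            sequence=amplicon,
            repeat_count=count,
            unit_snps=snps,
        )
        truth = {"kind": TYPE_II, "copies": copies, "vntr": vntr}
    else:
        vntr, meta = _draw_type1(cfg, rng)
        comp = decompose(vntr)
        amplicon = marker.amplicon(vntr)
        allele = VntrAllele(
            strain_id=strain_id,
            locus_id=marker.locus_id,
            sequence=amplicon,
            repeat_count=float(comp.n_f + comp.n_r),
            unit_snps=comp.snps,
        )
        truth = {"kind": TYPE_I, **meta, "vntr": vntr}
    return allele, truth


def generate_panel(
    cfg: SimConfig, markers: list[_Marker] | None = None
):
    """A strain panel typed over a shared marker set.

    Returns ``(profiles, truth)`` where ``truth`` is a pandas DataFrame of
    the planted copy numbers / unit compositions per strain and marker.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    if markers is None:
        markers = _make_marker_set(cfg, rng)
    pool = [f"A{k}" for k in rng.permutation(np.arange(2, 100))]
    profiles = []
    rows = []
    for s in range(cfg.n_strains):
        strain_id = f"S{s + 1}"
        types = {pool.pop(), pool.pop()}
        profile = StrainProfile(strain_id=strain_id, nuclear_types=types)
        for m in markers:
            allele, truth = _strain_allele(cfg, rng, m, strain_id)
            profile.alleles[m.locus_id] = allele
            rows.append(
                {
                    "strain_id": strain_id,
                    "locus_id": m.locus_id,
                    **{
                        k: v
                        for k, v in truth.items()
                        if k in ("kind", "copies", "n_f", "n_r", "spacer")
                    },
                }
            )
        profiles.append(profile)
    return profiles, pd.DataFrame(rows)


def monokaryotic_offspring(
    parent: StrainProfile, nuclear_type: str
) -> StrainProfile:
    """A basidiospore-derived monokaryon: one parental nucleus, the
    parent's mitochondria (identical VNTR profile)."""
    if nuclear_type not in parent.nuclear_types:
        raise ValueError(f"{nuclear_type} is not a nucleus of {parent.strain_id}")
    return StrainProfile(
        strain_id=f"{parent.strain_id}-{nuclear_type}",
        alleles=dict(parent.alleles),
        nuclear_types={nuclear_type},
    )


def _elongate_allele(
    allele: VntrAllele,
    marker: _Marker,
    truth: dict,
    rng: np.random.Generator,
) -> tuple[VntrAllele, dict]:
    """Add one repeat unit to a mate allele (Type I: one incorporation
    event; Type II: one extra unit copy)."""
    vntr = truth["vntr"]
    if marker.kind == TYPE_I:
        comp = decompose(vntr)
        if comp.center == "TT":
            spacer = "G" if rng.random() < 0.5 else "C"
            event = ElongationEvent("R", spacer)
        else:
            event = ElongationEvent("F")
        new_vntr = elongate_once(vntr, event)
        new_comp = decompose(new_vntr)
        new_allele = VntrAllele(
            strain_id=allele.strain_id,
            locus_id=allele.locus_id,
            sequence=marker.amplicon(new_vntr),
            repeat_count=float(new_comp.n_f + new_comp.n_r),
            unit_snps=new_comp.snps,
        )
        new_truth = {**truth, "vntr": new_vntr, "n_f": new_comp.n_f,
                     "n_r": new_comp.n_r}
    else:
        new_vntr = vntr + marker.unit
        amplicon = marker.amplicon(new_vntr)
        count, snps = count_repeats(amplicon, marker.unit)
        new_allele = VntrAllele(
            strain_id=allele.strain_id,
            locus_id=allele.locus_id,
            sequence=amplicon,
            repeat_count=count,
            unit_snps=snps,
        )
        new_truth = {**truth, "vntr": new_vntr, "copies": truth["copies"] + 1}
    return new_allele, new_truth


def generate_trio(
    cfg: SimConfig,
    truth_origin: str = "MON",
    rng: np.random.Generator | None = None,
):
    """One Di-Mon mating trio with ground-truth labels.

    The mate's mitochondrial profile is copied from the monokaryon
    (uniparental inheritance); with probability ``cfg.p_elongation_per_mate``
    per marker one repeat unit is added.  One dikaryotic nucleus is drawn
    as the donor.  Returns ``(trio, truth)`` with truth keys ``origin``,
    ``donor``, ``elongated`` and ``identical_parents`` per marker.
    """
    if truth_origin != "MON":
        raise ValueError("only monokaryon-origin trios are modelled")
    from .inheritance import MatingTrio

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    markers = _make_marker_set(cfg, rng)

    di_types = sorted({f"A{int(t)}" for t in rng.choice(
        np.arange(2, 100), size=2, replace=False)})
    di = StrainProfile("Di1", nuclear_types=set(di_types))
    mon = StrainProfile("E13", nuclear_types={"A1"})
    mate = StrainProfile("Di1xE13")

    truth: dict = {
        "origin": "MON",
        "elongated": {},
        "identical_parents": {},
    }
    for m in markers:
        di_allele, _ = _strain_allele(cfg, rng, m, di.strain_id)
        mon_allele, mon_truth = _strain_allele(cfg, rng, m, mon.strain_id)
        di.alleles[m.locus_id] = di_allele
        mon.alleles[m.locus_id] = mon_allele
        mate_allele = VntrAllele(
            strain_id=mate.strain_id,
            locus_id=m.locus_id,
            sequence=mon_allele.sequence,
            repeat_count=mon_allele.repeat_count,
            unit_snps=list(mon_allele.unit_snps),
        )
        elongated = rng.random() < cfg.p_elongation_per_mate
        if elongated:
            mate_allele, mate_truth = _elongate_allele(mate_allele, m, mon_truth, rng)
            # A length-only marker cannot resolve an elongated allele that
            # collides exactly with the dikaryon allele; the study's flagged
            # elongations all stayed assignable (via SNPs or by exceeding
            # both parents), so grow past any accidental collision.
            while mate_allele.sequence == di_allele.sequence:
                mate_allele, mate_truth = _elongate_allele(
                    mate_allele, m, mate_truth, rng
                )
        mate.alleles[m.locus_id] = mate_allele
        truth["elongated"][m.locus_id] = elongated
        truth["identical_parents"][m.locus_id] = (
            di_allele.sequence == mon_allele.sequence
        )

    donor = str(rng.choice(di_types))
    mate.nuclear_types = frozenset({"A1", donor})
    truth["donor"] = donor
    trio = MatingTrio(di=di, mon=mon, mate=mate)
    return trio, truth
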