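"""Mitochondrial-origin and nuclear-donation calling for Di-Mon mating trios.

In a dikaryon-monokaryon (Di-Mon, "Buller") mating one nucleus of the donor
dikaryon migrates into the monokaryon's cytoplasm, so the new dikaryon keeps
the monokaryon's mitochondria.  This module decides, per VNTR marker and
overall, where a mate's mitochondria came from, and which dikaryotic nucleus
was donated.

Per-marker calls:

* ``ND``  — parents not differentiable at the marker (or the observation is
  uninterpretable); uninformative.
* ``MON`` / ``DI`` — the mate allele matches exactly one parent.
* ``UP``  — the mate allele is longer than both parents ("unexpectedly
  bigger"): one or more repeat units were added during mtDNA replication.
  When the parents differ at diagnostic SNP positions the elongated allele
  can still be assigned to a parent (SNP rescue); otherwise the parental
  origin of an UP marker stays unknown.

A mate whose allele matches one parent's *length* but the other parent's
SNP fingerprint is called for the SNP-matching parent with an elongation
flag (the allele grew by exactly enough units to collide in length).

The overall call is the consensus of informative markers: MON or DI when
unanimous, MIXED when both occur, UNDETERMINED when nothing is informative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .genotype import StrainProfile, VntrAllele

__all__ = [
    "MON",
    "DI",
    "ND",
    "UP",
    "MIXED",
    "UNDETERMINED",
    "UNKNOWN",
    "MarkerCall",
    "OriginCall",
    "MatingTrio",
    "call_marker_origin",
    "call_overall",
    "call_trio",
    "donated_nucleus",
    "donation_consistency",
    "load_mate_panel",
    "replay_mate_panel",
]

MON = "MON"
DI = "DI"
ND = "ND"
UP = "UP"
MIXED = "MIXED"
UNDETERMINED = "UNDETERMINED"
UNKNOWN = "UNKNOWN"


@dataclass
class MatingTrio:
    """Donor dikaryon, recipient monokaryon and the resulting Di-Mon mate.

    The mate's nuclear types must be the monokaryon's type plus one of the
    dikaryon's two types (checked by :func:`donated_nucleus`).
    """

    di: StrainProfile
    mon: StrainProfile
    mate: StrainProfile

    def __post_init__(self) -> None:
        if len(self.mon.nuclear_types) != 1:
            raise ValueError("monokaryon must carry exactly one nuclear type")
        if len(self.di.nuclear_types) != 2:
            raise ValueError("dikaryon must carry exactly two nuclear types")


@dataclass(frozen=True)
class MarkerCall:
    call: str  # MON / DI / ND / UP
    elongation_flag: bool = False
    inferred_parent: str = UNKNOWN  # MON / DI / UNKNOWN


@dataclass
class OriginCall:
    """Per-marker and overall mitochondrial origin of one Di-Mon mate."""

    per_marker: dict[str, str] = field(default_factory=dict)
    elongation_flags: dict[str, bool] = field(default_factory=dict)
    inferred_up_parent: dict[str, str] = field(default_factory=dict)
    overall: str = UNDETERMINED


def _alleles_equal(a: VntrAllele, b: VntrAllele) -> bool:
    return a.amplicon_length == b.amplicon_length and a.sequence == b.sequence


def _snp_map(allele: VntrAllele) -> dict[tuple, tuple[str, str]]:
    """Position -> (ref, obs) for every recorded SNP/spacer observation."""
    return {
        (s.side, s.index, s.offset): (s.ref, s.obs) for s in allele.unit_snps
    }


def _fingerprint_positions(
    di: VntrAllele, mon: VntrAllele
) -> list[tuple[tuple, str, str]]:
    """Positions where the two parents carry different bases.

    A position absent from one parent's SNP list is taken to carry the
    reference (canonical-motif) base there — but only when that parent's
    allele actually contains the motif (its unit/motif count reaches the
    position's index); a motif present in only the longer allele says
    nothing about parentage.  Only parent-discriminating positions enter
    the fingerprint.
    """

    def covers(allele: VntrAllele, index: int) -> bool:
        return not allele.repeat_count or index <= int(allele.repeat_count)

    di_map = _snp_map(di)
    mon_map = _snp_map(mon)
    out = []
    for pos in sorted(set(di_map) | set(mon_map), key=repr):
        _, index, _ = pos
        if pos not in di_map and not covers(di, index):
            continue
        if pos not in mon_map and not covers(mon, index):
            continue
        ref = (di_map.get(pos) or mon_map.get(pos))[0]
        di_base = di_map.get(pos, (ref, ref))[1]
        mon_base = mon_map.get(pos, (ref, ref))[1]
        if di_base != mon_base:
            out.append((pos, ref, di_base, mon_base))
    return out


def _fingerprint_match(
    mate: VntrAllele, positions: list[tuple[tuple, str, str, str]]
) -> str:
    """Which parent the mate's bases match at all discriminating positions."""
    if not positions:
        return UNKNOWN
    mate_map = _snp_map(mate)
    matches_di = matches_mon = True
    for pos, ref, di_base, mon_base in positions:
        # absent from the mate's record means it carries the canonical base
        mate_base = mate_map.get(pos, (ref, ref))[1]
        if mate_base != di_base:
            matches_di = False
        if mate_base != mon_base:
            matches_mon = False
    if matches_di and not matches_mon:
        return DI
    if matches_mon and not matches_di:
        return MON
    return UNKNOWN


def call_marker_origin(
    di_allele: VntrAllele, mon_allele: VntrAllele, mate_allele: VntrAllele
) -> MarkerCall:
    """Mitochondrial origin of one marker in a Di-Mon mate.

    Decision ladder:

    1. parents identical (length and sequence) -> ``ND``;
    2. mate identical to exactly one parent -> that parent;
    3. mate matching neither parent:
       longer than both -> ``UP`` (new repeat units), with the parent
       inferred by SNP fingerprint when the parents differ at diagnostic
       positions; same length as one parent but fingerprint of the other ->
       the fingerprint parent with an elongation flag; anything else ->
       uninterpretable, reported ``ND``.
    """
    if not (di_allele.locus_id == mon_allele.locus_id == mate_allele.locus_id):
        raise ValueError(
            f"locus mismatch: {di_allele.locus_id}/{mon_allele.locus_id}/"
            f"{mate_allele.locus_id}"
        )
    if _alleles_equal(di_allele, mon_allele):
        return MarkerCall(ND)
    eq_mon = _alleles_equal(mate_allele, mon_allele)
    eq_di = _alleles_equal(mate_allele, di_allele)
    if eq_mon and not eq_di:
        return MarkerCall(MON)
    if eq_di and not eq_mon:
        return MarkerCall(DI)

    positions = _fingerprint_positions(di_allele, mon_allele)
    fp = _fingerprint_match(mate_allele, positions)
    longer_than_both = mate_allele.amplicon_length > max(
        di_allele.amplicon_length, mon_allele.amplicon_length
    )
    if longer_than_both:
        return MarkerCall(UP, elongation_flag=True, inferred_parent=fp)
    if (
        mate_allele.amplicon_length == di_allele.amplicon_length
        and fp == MON
    ):
        return MarkerCall(MON, elongation_flag=True, inferred_parent=MON)
    if (
        mate_allele.amplicon_length == mon_allele.amplicon_length
        and fp == DI
    ):
        return MarkerCall(DI, elongation_flag=True, inferred_parent=DI)
    return MarkerCall(ND)


def call_overall(calls: dict[str, MarkerCall] | list[MarkerCall]) -> str:
    """Consensus origin over markers.

    ND markers are ignored; UP markers contribute through their inferred
    parent (UNKNOWN stays uninformative).  MON/DI when unanimous among
    informative markers, MIXED when both occur, UNDETERMINED when no marker
    is informative.  Raises on empty input.
    """
    if isinstance(calls, dict):
        calls = list(calls.values())
    if not calls:
        raise ValueError("no marker calls")
    votes = []
    for c in calls:
        if c.call in (MON, DI):
            votes.append(c.call)
        elif c.call == UP and c.inferred_parent in (MON, DI):
            votes.append(c.inferred_parent)
    if not votes:
        return UNDETERMINED
    kinds = set(votes)
    if kinds == {MON}:
        return MON
    if kinds == {DI}:
        return DI
    return MIXED


def call_trio(trio: MatingTrio, loci: list[str] | None = None) -> OriginCall:
    """Per-marker plus overall origin call for one trio."""
    if loci is None:
        loci = sorted(
            set(trio.di.alleles) & set(trio.mon.alleles) & set(trio.mate.alleles)
        )
    result = OriginCall()
    marker_calls: dict[str, MarkerCall] = {}
    for locus in loci:
        mc = call_marker_origin(
            trio.di.alleles[locus], trio.mon.alleles[locus], trio.mate.alleles[locus]
        )
        marker_calls[locus] = mc
        result.per_marker[locus] = mc.call
        result.elongation_flags[locus] = mc.elongation_flag
        result.inferred_up_parent[locus] = mc.inferred_parent
    result.overall = call_overall(marker_calls)
    return result


def donated_nucleus(trio: MatingTrio) -> str:
    """The dikaryotic nucleus present in the mate (the donated one).

    Raises ``ValueError`` when the mate's nuclear types cannot be written
    as {monokaryon type} plus one dikaryon type.
    """
    (mon_type,) = trio.mon.nuclear_types
    mate_types = set(trio.mate.nuclear_types)
    di_types = set(trio.di.nuclear_types)
    if mon_type not in mate_types:
        raise ValueError(
            f"mate lacks the monokaryotic nucleus {mon_type}: {sorted(mate_types)}"
        )
    donated = mate_types - {mon_type}
    if len(mate_types) == 1:
        # mate typed with a single label: only consistent if the dikaryon
        # shares the monokaryon's type (donated nucleus == mon type)
        if mon_type in di_types:
            return mon_type
        raise ValueError("mate carries only the monokaryotic nucleus")
    if len(donated) != 1 or not donated <= di_types:
        raise ValueError(
            f"mate types {sorted(mate_types)} not expressible as "
            f"{{{mon_type}}} + one of {sorted(di_types)}"
        )
    return next(iter(donated))


def donation_consistency(
    replicate_mates: list[StrainProfile], di: StrainProfile, mon: StrainProfile
) -> tuple[int, Counter]:
    """Tally of donated nuclei across replicate mates of one Di-Mon pairing."""
    if not replicate_mates:
        raise ValueError("no replicate mates")
    counts: Counter = Counter()
    for mate in replicate_mates:
        counts[donated_nucleus(MatingTrio(di=di, mon=mon, mate=mate))] += 1
    return len(replicate_mates), counts


# ---------------------------------------------------------------------------
# Curated Di-Mon mate panel (22 L. edodes dikaryons mated to monokaryon E13)
# ---------------------------------------------------------------------------

#: Markers scored in the curated panel.
PANEL_MARKERS = ["VNTR7", "VNTR13", "VNTR18", "VNTR20", "VNTR23", "VNTR25"]


def load_mate_panel() -> pd.DataFrame:
    """The bundled 22-trio Di-Mon mate panel.

    Each row is one dikaryon x E13 mating with its nuclear types and the
    per-marker mitochondrial call tokens: ``Mon``, ``ND``, ``UP`` (allele
    bigger than both parents) or ``Mon*`` (same length as the dikaryon but
    carrying the monokaryon's SNPs, i.e. an SNP-rescued elongated allele).
    """
    with resources.files("mtvntr.data").joinpath("dimon_mates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _token_to_call(token: str) -> MarkerCall:
    token = token.strip()
    if token == "Mon":
        return MarkerCall(MON)
    if token == "Mon*":
        return MarkerCall(MON, elongation_flag=True, inferred_parent=MON)
    if token == "ND":
        return MarkerCall(ND)
    if token == "UP":
        return MarkerCall(UP, elongation_flag=True, inferred_parent=UNKNOWN)
    raise ValueError(f"unknown marker token {token!r}")


def replay_mate_panel(panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute overall origin calls and nuclear donations for the panel.

    Returns one row per trio with the overall mitochondrial call, the number
    of elongation-flagged markers and the donated nucleus.
    """
    if panel is None:
        panel = load_mate_panel()
    rows = []
    for _, row in panel.iterrows():
        calls = {m: _token_to_call(row[m]) for m in PANEL_MARKERS if m in row}
        overall = call_overall(calls)
        di_types = set(row["di_types"].split("/"))
        mon_types = {row["mon_types"]}
        mate_types = set(row["mate_types"].split("/"))
        (mon_type,) = mon_types
        donated = next(iter(mate_types - mon_types), mon_type)
        rows.append(
            {
                "strain": row["strain"],
                "overall": overall,
                "n_elongated": sum(c.elongation_flag for c in calls.values()),
                "donated_nucleus": donated,
                **{m: row[m] for m in PANEL_MARKERS if m in row},
            }
        )
    return pd.DataFrame(rows)
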