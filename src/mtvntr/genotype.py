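"""VNTR genotyping of strain panels.

Turns locus sequences into genotype tables: in-silico PCR amplicon lengths,
tandem-repeat copy counts and within-unit SNPs, and a strain-by-strain
discrimination matrix.  Amplicon length polymorphism plus within-unit SNPs
are what make mitochondrial VNTRs usable as strain markers: two mtDNAs are
distinguishable as soon as one shared marker differs in product length or
in sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqio import SeqRecord, revcomp
from .type1_model import UnitSnp

__all__ = [
    "PrimerPair",
    "VntrAllele",
    "StrainProfile",
    "PcrError",
    "NoProductError",
    "MultipleProductsError",
    "in_silico_pcr",
    "count_repeats",
    "discrimination_matrix",
    "DiscriminationResult",
    "profiles_to_tsv",
]


class PcrError(ValueError):
    """Base class for in-silico PCR failures."""


class NoProductError(PcrError):
    """Neither primer orientation yields a product."""


class MultipleProductsError(PcrError):
    """The primer pair amplifies more than one region."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; ``rev`` is given 5'->3' on the opposite strand."""

    name: str
    fwd: str
    rev: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if len(self.fwd) < 15 or len(self.rev) < 15:
            raise ValueError("primers must be at least 15 nt")


@dataclass
class VntrAllele:
    """One strain's allele at one VNTR marker.

    ``amplicon_length`` equals ``len(sequence)`` when the allele was derived
    by in-silico PCR.  ``unit_snps`` records within-unit deviations (and
    spacer observations for Type I alleles) as :class:`UnitSnp` tuples.
    """

    strain_id: str
    locus_id: str
    sequence: str
    amplicon_length: int = 0
    repeat_count: float = 0.0
    unit_snps: list[UnitSnp] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.amplicon_length == 0:
            self.amplicon_length = len(self.sequence)


@dataclass
class StrainProfile:
    """Per-strain genotype across VNTR markers plus nuclear type(s).

    ``nuclear_types`` holds the A-mating-type labels of the nuclei: one for
    a monokaryon, two for a dikaryon.
    """

    strain_id: str
    alleles: dict[str, VntrAllele] = field(default_factory=dict)
    nuclear_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.nuclear_types = frozenset(self.nuclear_types)
        if self.nuclear_types and len(self.nuclear_types) not in (1, 2):
            raise ValueError("nuclear_types must have size 1 or 2")


def _site_matches(seq: str, pos: int, probe: str, max_mm: int, exact_at: int) -> bool:
    """Substitution-only probe match at ``pos`` with an exact base at index
    ``exact_at`` (the primer's 3'-terminal position)."""
    window = seq[pos : pos + len(probe)]
    if len(window) != len(probe):
        return False
    if window[exact_at] != probe[exact_at]:
        return False
    return sum(1 for a, b in zip(window, probe) if a != b) <= max_mm


def in_silico_pcr(record: SeqRecord, primers: PrimerPair, max_len: int = 2000) -> str:
    """The unique amplicon (both primer sites included) of ``primers``.

    The forward primer must match the forward strand and the reverse
    primer's reverse complement a downstream site, each with at most
    ``primers.max_mismatch`` substitutions and an exact 3'-terminal base.
    Raises :class:`NoProductError` / :class:`MultipleProductsError` when the
    product is not unique.
    """
    seq = record.sequence
    L = len(seq)
    scan = seq + seq if record.circular else seq
    fwd = primers.fwd.upper()
    rev_rc = revcomp(primers.rev.upper())
    mm = primers.max_mismatch

    fwd_sites = [
        i
        for i in range(len(scan) - len(fwd) + 1)
        if _site_matches(scan, i, fwd, mm, len(fwd) - 1)
    ]
    # the 3' end of the reverse primer maps to the first base of its
    # reverse-complemented site on the forward strand
    rev_sites = [
        j
        for j in range(len(scan) - len(rev_rc) + 1)
        if _site_matches(scan, j, rev_rc, mm, 0)
    ]

    products: dict[tuple[int, int], str] = {}
    for i in fwd_sites:
        if i >= L:
            continue  # doubled-scan duplicate
        for j in rev_sites:
            if j < i + len(fwd) - len(rev_rc):
                continue
            length = j + len(rev_rc) - i
            if length > max_len or length > L:
                continue
            products[(i % L, length)] = scan[i : j + len(rev_rc)]

    if not products:
        raise NoProductError(f"{primers.name}: no amplification product")
    if len(products) > 1:
        raise MultipleProductsError(
            f"{primers.name}: {len(products)} products "
            f"(sites {sorted(products)})"
        )
    return next(iter(products.values()))


def count_repeats(
    allele_seq: str,
    unit: str,
    max_mismatch_per_unit: int = 1,
    min_copies: int = 2,
) -> tuple[float, list[UnitSnp]]:
    """Best tandem run of ``unit`` copies within ``allele_seq``.

    Scans every anchor position; a run is consecutive full copies each
    within ``max_mismatch_per_unit`` substitutions of ``unit``, plus an
    exactly-matching fractional trailing copy (counted to 0.1).  The
    highest full-copy count wins; ties break to the 5'-most run.  Returns
    ``(0.0, [])`` when no run of at least ``min_copies`` exists.

    SNPs are recorded per copy as ``UnitSnp(copy_index_1based, ref, obs,
    offset_0based)``.
    """
    if len(unit) < 5:
        raise ValueError("unit must be at least 5 nt")
    allele_seq = allele_seq.upper()
    unit = unit.upper()
    d = len(unit)
    best: tuple[int, float, list[UnitSnp]] | None = None

    for s0 in range(len(allele_seq) - 2 * d + 1):
        p = s0
        n = 0
        snps: list[UnitSnp] = []
        while p + d <= len(allele_seq):
            window = allele_seq[p : p + d]
            diffs = [
                (k, unit[k], window[k]) for k in range(d) if window[k] != unit[k]
            ]
            if len(diffs) > max_mismatch_per_unit:
                break
            n += 1
            snps.extend(UnitSnp(n, r, o, k) for k, r, o in diffs)
            p += d
        if n < min_copies:
            continue
        t = 0
        while p + t < len(allele_seq) and allele_seq[p + t] == unit[t]:
            t += 1
        count = n + round(t / d, 1)
        if best is None or n > best[0]:
            best = (n, count, snps)

    if best is None:
        return 0.0, []
    return best[1], best[2]


@dataclass
class DiscriminationResult:
    """Pairwise strain distinguishability with the discriminating loci."""

    matrix: pd.DataFrame
    discriminators: dict[tuple[str, str], list[str]]


def discrimination_matrix(
    profiles: list[StrainProfile], loci: list[str]
) -> DiscriminationResult:
    """Pairwise strain discrimination over a marker set.

    Two strains are distinguishable iff at least one locus typed in both
    differs in amplicon length or in sequence (within-unit SNPs therefore
    count).  Loci missing from either profile are ignored for that pair.
    """
    ids = [p.strain_id for p in profiles]
    by_id = {p.strain_id: p for p in profiles}
    matrix = pd.DataFrame(False, index=ids, columns=ids)
    discriminators: dict[tuple[str, str], list[str]] = {}
    for i, s1 in enumerate(ids):
        for s2 in ids[i + 1 :]:
            diffs = []
            for locus in loci:
                a1 = by_id[s1].alleles.get(locus)
                a2 = by_id[s2].alleles.get(locus)
                if a1 is None or a2 is None:
                    continue
                if (
                    a1.amplicon_length != a2.amplicon_length
                    or a1.sequence != a2.sequence
                ):
                    diffs.append(locus)
            discriminators[(s1, s2)] = diffs
            discriminators[(s2, s1)] = diffs
            matrix.loc[s1, s2] = matrix.loc[s2, s1] = bool(diffs)
    return DiscriminationResult(matrix=matrix, discriminators=discriminators)


def profiles_to_tsv(profiles: list[StrainProfile], path) -> None:
    """Write a long-format genotype table (strain, locus, length, copies, SNPs)."""
    rows = []
    for p in profiles:
        for locus_id, allele in sorted(p.alleles.items()):
            rows.append(
                {
                    "strain_id": p.strain_id,
                    "locus_id": locus_id,
                    "amplicon_length": allele.amplicon_length,
                    "repeat_count": allele.repeat_count,
                    "snps": ";".join(
                        f"{s.side or ''}{s.index}:{s.ref}>{s.obs}@{s.offset}"
                        for s in allele.unit_snps
                    ),
                    "nuclear_types": "/".join(sorted(p.nuclear_types)),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "locus_id",
            "amplicon_length",
            "repeat_count",
            "snps",
            "nuclear_types",
        ],
    ).to_csv(path, sep="\t", index=False)
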