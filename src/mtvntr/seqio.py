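"""Sequence records, FASTA I/O and exact nucleotide utilities.

Everything downstream (detection, decomposition, genotyping) works on plain
uppercase DNA strings over the IUPAC nucleotide alphabet.  Coordinates are
0-based, half-open, on the forward strand throughout the package; conversion
to 1-based inclusive happens only at report boundaries (GFF3 output).

Circularity of a molecule (mitochondrial genomes are circular) is an explicit
flag on the record, carried through FASTA round trips via a ``circular=true``
token on the description line — FASTA itself has no standard topology field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SeqRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "iupac_match",
    "canonical_rotation",
    "IUPAC_SETS",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; names the offending line."""


def _validate_alphabet(s: str, context: str = "sequence") -> None:
    for i, ch in enumerate(s):
        if ch not in IUPAC_SETS:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {i} in {context}"
            )


@dataclass
class SeqRecord:
    """A named DNA sequence with an explicit topology flag.

    The sequence is normalised to uppercase at construction and restricted to
    IUPAC nucleotide codes; it must be non-empty.
    """

    id: str
    sequence: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        _validate_alphabet(self.sequence, context=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Sequences are uppercased on read.  Topology is taken from a
    ``circular=true`` token (case-insensitive) anywhere on the description
    line; records default to linear.  An empty file yields an empty list.
    """
    # Light structural pre-check so malformed input fails with a line number
    # (Bio.SeqIO silently yields nothing for headerless text).
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header "
                    f"starting with '>', got {line.strip()[:40]!r}"
                )
            break

    records: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        circular = any(t.lower() == "circular=true" for t in tokens)
        records.append(
            SeqRecord(
                id=rec.id,
                sequence=str(rec.seq),
                circular=circular,
                description=rec.description,
            )
        )
    return records


def write_fasta(records: list[SeqRecord], path, width: int = 70) -> None:
    """Write records to FASTA, preserving the circularity flag as a token."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.circular:
                header += " circular=true"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def revcomp(s: str) -> str:
    """IUPAC-aware reverse complement (S<->S, W<->W, R<->Y, ...)."""
    _validate_alphabet(s)
    return str(Seq(s).reverse_complement())


def iupac_match(a: str, b: str) -> bool:
    """True iff at every position the IUPAC base sets of ``a`` and ``b``
    intersect (e.g. S matches C, G, S, N but not A).

    Raises ``ValueError`` on length mismatch or non-IUPAC characters.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    _validate_alphabet(a)
    _validate_alphabet(b)
    return all(IUPAC_SETS[x] & IUPAC_SETS[y] for x, y in zip(a, b))


def canonical_rotation(unit: str) -> str:
    """Lexicographically minimal rotation of a repeat unit.

    Tandem-repeat units are only defined up to cyclic rotation; the canonical
    form makes units comparable across loci regardless of the phase in which
    an array was first encountered.
    """
    return min(unit[i:] + unit[:i] for i in range(len(unit)))
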