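"""Elongation model for Type I mitochondrial VNTRs.

Type I VNTRs in *Lentinula edodes* mtDNA are built from two 11-nt basic
units that are reverse complements of each other:

* F unit: ``5'-TCCCTTTAGGG-3'``
* R unit: ``5'-CCCTAAAGGGA-3'``

Both fold into hairpins around a central dinucleotide (TT in F, AA in R).
The locus grows from a single unit by reciprocal incorporation at the
center:

* **F incorporation** — the central ``AA`` of the current array is excised
  and replaced by an F unit carrying an extra ``T`` at its 3' end
  (``TCCCTTTAGGGT``).  The new center is the F unit's ``TT``.
* **R incorporation** — the central ``TT`` is excised and replaced by an R
  unit carrying an extra spacer base (``G`` or ``C``) at its 5' end
  (``SCCCTAAAGGGA``).  The new center is the R unit's ``AA``.

Each incorporation adds exactly 10 nt, so an allele produced by *k* events
is ``11 + 10*k`` nt long.  Because F incorporation leaves a TT center and R
incorporation leaves an AA center, event kinds strictly alternate.

Reading an allele outward-in, the left flank is an alternating string of
``TCCCT`` (F half) and ``SCCCTA`` (R half, S = G or C) motifs and the right
flank of ``AGGGT`` (F half) and ``GGGA`` (R half) motifs; the nucleating
unit contributes boundary variants (``AGGG`` without the trailing T for a
starting F, ``CCCTA`` without the leading spacer for a starting R) because
the +T / +S additions happen only on incorporation.  :func:`decompose`
inverts this grammar: it parses an observed allele into its F/R composition,
tolerating point substitutions and recording them as SNPs.  The motif next
to the center is the most recently incorporated unit.
"""

from __future__ import annotations

import itertools
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .seqio import revcomp

__all__ = [
    "F_UNIT",
    "R_UNIT",
    "F_LEFT",
    "F_RIGHT",
    "F_RIGHT_INITIAL",
    "R_LEFT",
    "R_LEFT_INITIAL",
    "R_RIGHT",
    "ElongationEvent",
    "UnitSnp",
    "Type1Composition",
    "NotType1Error",
    "initial_vntr",
    "elongate_once",
    "simulate_elongation",
    "sample_events",
    "decompose",
    "innermost_unit",
]

F_UNIT = "TCCCTTTAGGG"
R_UNIT = "CCCTAAAGGGA"

F_LEFT = "TCCCT"  # left half-motif contributed by every F unit
F_RIGHT = "AGGGT"  # right half-motif of an incorporated F (+T at 3')
F_RIGHT_INITIAL = "AGGG"  # right half-motif of the nucleating F
R_LEFT = "SCCCTA"  # left half-motif of an incorporated R (+S at 5', S=G/C)
R_LEFT_INITIAL = "CCCTA"  # left half-motif of the nucleating R
R_RIGHT = "GGGA"  # right half-motif of every R unit

_F_INSERT = "TCCCTTTAGGGT"  # replaces the central AA
_R_INSERT = "CCCTAAAGGGA"  # spacer + this replaces the central TT

assert revcomp(F_UNIT) == R_UNIT
assert F_UNIT == F_LEFT + "TT" + F_RIGHT_INITIAL
assert R_UNIT == R_LEFT_INITIAL + "AA" + R_RIGHT


class NotType1Error(ValueError):
    """The allele has no valid parse under the F/R half-motif grammar."""


@dataclass(frozen=True)
class ElongationEvent:
    """One incorporation step.

    ``kind`` is ``"F"`` (F unit into an AA center) or ``"R"`` (R unit into a
    TT center).  ``spacer`` is the extra 5' base of an incorporated R unit
    and must be G or C; it is present iff ``kind == "R"``.
    """

    kind: Literal["F", "R"]
    spacer: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("F", "R"):
            raise ValueError(f"event kind must be 'F' or 'R', got {self.kind!r}")
        if self.kind == "R":
            if self.spacer not in ("G", "C"):
                raise ValueError("R incorporation requires spacer 'G' or 'C'")
        elif self.spacer is not None:
            raise ValueError("F incorporation takes no spacer")


#: A recorded deviation from (or observation at) a canonical half-motif.
#: ``index`` is the 1-based motif index counted from the outermost motif of
#: its side (``side`` is "L" or "R"; None for simple tandem-unit SNPs),
#: ``offset`` the 0-based position within the motif.  Observations at the
#: polymorphic spacer position (ref "S") are always recorded, even when the
#: observed base is a legal G or C, because the concrete spacer base is the
#: strain-diagnostic signal used in inheritance fingerprinting.
UnitSnp = namedtuple("UnitSnp", ["index", "ref", "obs", "offset", "side"], defaults=[None])


@dataclass
class Type1Composition:
    """Parse of a Type I allele into F/R half-motifs.

    ``left_motifs`` / ``right_motifs`` list ``(unit_class, canonical_motif)``
    pairs ordered outermost-first.  ``center_pos`` is the 0-based position of
    the central dinucleotide on the strand that parsed (``strand`` is "-"
    when only the reverse complement fits the grammar; counts and center are
    already reported in the swapped, forward-equivalent convention).
    """

    n_f: int
    n_r: int
    center: Literal["TT", "AA"]
    center_pos: int
    left_motifs: list[tuple[str, str]]
    right_motifs: list[tuple[str, str]]
    snps: list[UnitSnp]
    mismatch_count: int
    strand: Literal["+", "-"] = "+"
    balanced: bool = True
    indel_fallback: bool = False
    allele_length: int = 0

    @property
    def total_units(self) -> int:
        return self.n_f + self.n_r


def initial_vntr(start_unit: Literal["F", "R"]) -> str:
    """The nucleating single-unit allele (11 nt)."""
    if start_unit == "F":
        return F_UNIT
    if start_unit == "R":
        return R_UNIT
    raise ValueError(f"start unit must be 'F' or 'R', got {start_unit!r}")


def _find_center(vntr: str) -> tuple[int, str]:
    """Locate the unique central dinucleotide via a strict (0-mismatch) parse."""
    comp = _best_composition(vntr, max_mismatch_per_motif=0, allow_deletion=False)
    if comp is None or comp.strand != "+":
        raise NotType1Error(
            f"cannot locate a parseable TT/AA center in {vntr[:30]!r}..."
        )
    return comp.center_pos, comp.center


def elongate_once(vntr: str, event: ElongationEvent) -> str:
    """Apply one incorporation event; returns an allele 10 nt longer.

    Raises ``ValueError`` if the current center is incompatible with the
    event kind (the mechanism enforces strict F/R alternation: an F unit can
    only enter an AA center, an R unit only a TT center).
    """
    pos, center = _find_center(vntr)
    if event.kind == "F":
        if center != "AA":
            raise ValueError(
                f"F incorporation requires an AA center, found {center}"
            )
        insert = _F_INSERT
    else:
        if center != "TT":
            raise ValueError(
                f"R incorporation requires a TT center, found {center}"
            )
        insert = event.spacer + _R_INSERT
    out = vntr[:pos] + insert + vntr[pos + 2 :]
    assert len(out) == len(vntr) + 10
    return out


def simulate_elongation(
    start_unit: Literal["F", "R"], events: Sequence[ElongationEvent]
) -> str:
    """Fold :func:`elongate_once` over an event list.

    The first event must be compatible with the nucleating unit's center
    (start F -> first event R, start R -> first event F) and kinds must
    alternate; violations raise ``ValueError`` at the offending event.
    """
    vntr = initial_vntr(start_unit)
    for i, ev in enumerate(events):
        try:
            vntr = elongate_once(vntr, ev)
        except ValueError as exc:
            raise ValueError(f"event {i} ({ev.kind}): {exc}") from exc
    return vntr


def sample_events(
    n_events: int,
    start_unit: Literal["F", "R"],
    spacer_prob_G: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> list[ElongationEvent]:
    """Draw a valid alternating event list of length ``n_events``.

    Spacers of R incorporations are i.i.d. with ``P(G) = spacer_prob_G``
    from a generator seeded by ``seed``; the same seed reproduces the same
    list.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not 0.0 <= spacer_prob_G <= 1.0:
        raise ValueError("spacer_prob_G must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    first = "R" if start_unit == "F" else "F"
    events: list[ElongationEvent] = []
    kind = first
    for _ in range(n_events):
        if kind == "R":
            spacer = "G" if rng.random() < spacer_prob_G else "C"
            events.append(ElongationEvent("R", spacer))
        else:
            events.append(ElongationEvent("F"))
        kind = "F" if kind == "R" else "R"
    return events


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

_LEFT_STD = (("F", F_LEFT), ("R", R_LEFT))
_LEFT_INITIAL = (("R", R_LEFT_INITIAL),)  # outermost position only
_RIGHT_STD = (("F", F_RIGHT), ("R", R_RIGHT))
_RIGHT_INITIAL = (("F", F_RIGHT_INITIAL),)  # outermost position only


def _match_motif(obs: str, ref: str, max_mm: int):
    """Compare an observed slice to a canonical motif of equal length.

    Returns ``(mismatches, records)`` or None if over budget.  Positions
    with ref "S" accept G/C for free but are always recorded (the spacer
    base is informative); any other deviation is a counted mismatch.
    """
    mm = 0
    records: list[tuple[int, str, str]] = []
    for k, (r, o) in enumerate(zip(ref, obs)):
        if r == "S":
            if o in "GC":
                records.append((k, "S", o))
            else:
                mm += 1
                records.append((k, "S", o))
        elif o != r:
            mm += 1
            records.append((k, r, o))
        if mm > max_mm:
            return None
    return mm, records


def _match_motif_del(obs: str, ref: str, max_mm: int):
    """Best match of ``obs`` against ``ref`` with exactly one base deleted.

    Used only in the indel-fallback parse (field alleles sometimes carry a
    4-nt TCCT in place of TCCCT).  Returns (mismatches, records) or None.
    """
    best = None
    for di in range(len(ref)):
        variant = ref[:di] + ref[di + 1 :]
        res = _match_motif(obs, variant, max_mm)
        if res is not None and (best is None or res[0] < best[0]):
            best = res
    return best


_Token = namedtuple("_Token", ["cls", "ref", "length", "mm", "records", "deleted"])


def _parse_left(flank: str, max_mm: int, allow_deletion: bool):
    """Parse a left flank outermost-first; returns list of token lists?

    Returns the best (max tokens, then min mismatches) full tokenisation of
    ``flank`` or None.  The initial-R variant CCCTA is admitted only for the
    first (outermost) token.
    """
    n = len(flank)
    memo: dict[int, Optional[tuple[int, int, tuple]]] = {}

    def candidates(p: int):
        cands = list(_LEFT_STD)
        if p == 0:
            cands += list(_LEFT_INITIAL)
        return cands

    def go(p: int):
        if p == n:
            return (0, 0, ())
        if p in memo:
            return memo[p]
        best = None
        for cls, ref in candidates(p):
            lengths = [(len(ref), False)]
            if allow_deletion:
                lengths.append((len(ref) - 1, True))
            for length, deleted in lengths:
                if p + length > n:
                    continue
                obs = flank[p : p + length]
                res = (
                    _match_motif_del(obs, ref, max_mm)
                    if deleted
                    else _match_motif(obs, ref, max_mm)
                )
                if res is None:
                    continue
                rest = go(p + length)
                if rest is None:
                    continue
                mm, records = res
                tok = _Token(cls, ref, length, mm, tuple(records), deleted)
                cand = (1 + rest[0], mm + rest[1], (tok,) + rest[2])
                if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
        memo[p] = best
        return best

    return go(0)


def _parse_right(flank: str, max_mm: int, allow_deletion: bool):
    """Parse a right flank innermost-first (tokens returned innermost-first).

    The initial-F variant AGGG is admitted only as the final (outermost)
    token, i.e. when it exactly consumes the remaining suffix.
    """
    n = len(flank)
    memo: dict[int, Optional[tuple[int, int, tuple]]] = {}

    def go(p: int):
        if p == n:
            return (0, 0, ())
        if p in memo:
            return memo[p]
        best = None
        cands = list(_RIGHT_STD)
        for cls, ref in _RIGHT_INITIAL:
            lengths = [len(ref)] + ([len(ref) - 1] if allow_deletion else [])
            if n - p in lengths:
                cands.append((cls, ref))
        for cls, ref in cands:
            lengths = [(len(ref), False)]
            if allow_deletion:
                lengths.append((len(ref) - 1, True))
            for length, deleted in lengths:
                if p + length > n:
                    continue
                if ref == F_RIGHT_INITIAL and p + length != n:
                    continue  # initial variant must be outermost
                obs = flank[p : p + length]
                res = (
                    _match_motif_del(obs, ref, max_mm)
                    if deleted
                    else _match_motif(obs, ref, max_mm)
                )
                if res is None:
                    continue
                rest = go(p + length)
                if rest is None:
                    continue
                mm, records = res
                tok = _Token(cls, ref, length, mm, tuple(records), deleted)
                cand = (1 + rest[0], mm + rest[1], (tok,) + rest[2])
                if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
        memo[p] = best
        return best

    return go(0)


def _compose(allele: str, max_mm: int, allow_deletion: bool):
    """Best forward-strand composition of ``allele`` or None.

    Tries every TT/AA dinucleotide as the center; ranks candidate parses by
    (total motifs desc, total mismatches asc, center position asc).
    """
    best = None
    for c in range(len(allele) - 1):
        center = allele[c : c + 2]
        if center not in ("TT", "AA"):
            continue
        left = _parse_left(allele[:c], max_mm, allow_deletion)
        if left is None:
            continue
        right = _parse_right(allele[c + 2 :], max_mm, allow_deletion)
        if right is None:
            continue
        n_motifs = left[0] + right[0]
        mm = left[1] + right[1]
        key = (n_motifs, -mm, -c)
        if best is None or key > best[0]:
            best = (key, c, center, left, right)
    if best is None:
        return None

    _, c, center, left, right = best
    left_tokens = list(left[2])  # outermost-first already
    right_tokens = list(right[2])[::-1]  # reorder outermost-first
    n_f = sum(1 for t in left_tokens if t.cls == "F")
    n_r = sum(1 for t in left_tokens if t.cls == "R")
    n_f_right = sum(1 for t in right_tokens if t.cls == "F")

    snps: list[UnitSnp] = []
    for side, tokens in (("L", left_tokens), ("R", right_tokens)):
        for i, tok in enumerate(tokens, start=1):
            for offset, ref_b, obs_b in tok.records:
                snps.append(UnitSnp(i, ref_b, obs_b, offset, side))

    return Type1Composition(
        n_f=n_f,
        n_r=n_r,
        center=center,  # type: ignore[arg-type]
        center_pos=c,
        left_motifs=[(t.cls, t.ref) for t in left_tokens],
        right_motifs=[(t.cls, t.ref) for t in right_tokens],
        snps=snps,
        mismatch_count=left[1] + right[1],
        balanced=(n_f == n_f_right),
        indel_fallback=any(t.deleted for t in left_tokens + right_tokens),
        allele_length=len(allele),
    )


def _best_composition(allele: str, max_mismatch_per_motif: int, allow_deletion: bool):
    """Best composition over both strands.

    The half-motif grammar is strand-specific; the reverse complement of a
    Type I allele is itself a Type I allele of the partner family.  When
    only (or better) parseable on the minus strand, counts are reported in
    the swapped convention: n_f/n_r exchanged, center complemented.
    """
    fwd = _compose(allele, max_mismatch_per_motif, allow_deletion)
    rev_raw = _compose(revcomp(allele), max_mismatch_per_motif, allow_deletion)
    rev = None
    if rev_raw is not None:
        rev = Type1Composition(
            n_f=rev_raw.n_r,
            n_r=rev_raw.n_f,
            center="AA" if rev_raw.center == "TT" else "TT",
            center_pos=len(allele) - rev_raw.center_pos - 2,
            left_motifs=rev_raw.left_motifs,
            right_motifs=rev_raw.right_motifs,
            snps=rev_raw.snps,
            mismatch_count=rev_raw.mismatch_count,
            strand="-",
            balanced=rev_raw.balanced,
            indel_fallback=rev_raw.indel_fallback,
            allele_length=len(allele),
        )
    if fwd is None:
        return rev
    if rev is None:
        return fwd
    fwd_key = (fwd.total_units + len(fwd.right_motifs) - 0, -fwd.mismatch_count, 1)
    rev_key = (rev.total_units + len(rev.right_motifs) - 0, -rev.mismatch_count, 0)
    return fwd if fwd_key >= rev_key else rev


def decompose(allele: str, max_mismatch_per_motif: int = 1) -> Type1Composition:
    """Parse an observed Type I allele into its F/R composition.

    Finds a TT or AA center such that the left flank tokenises into
    {TCCCT, SCCCTA (+ outermost CCCTA)} and the right flank into
    {AGGGT, GGGA (+ outermost AGGG)} half-motifs, each motif carrying at
    most ``max_mismatch_per_motif`` substitutions.  Among valid parses the
    one with the most motifs wins, then fewest mismatches, then the leftmost
    center.  If no substitution-only parse exists on either strand, a
    fallback allowing one single-base deletion per motif is attempted and
    flagged via ``indel_fallback`` (field alleles print a 4-nt TCCT variant
    of the TCCCT half-motif).

    Raises :class:`NotType1Error` when no parse exists at all.
    """
    if len(allele) < 11:
        raise NotType1Error(f"allele too short ({len(allele)} nt) for a Type I unit")
    allele = allele.upper()
    comp = _best_composition(allele, max_mismatch_per_motif, allow_deletion=False)
    if comp is None:
        comp = _best_composition(allele, max_mismatch_per_motif, allow_deletion=True)
    if comp is None:
        raise NotType1Error(
            "allele is not a Type I VNTR: no valid F/R half-motif parse"
        )
    return comp


def innermost_unit(comp: Type1Composition) -> str:
    """Class ("F" or "R") of the motif adjacent to the center.

    The unit closest to the central TT/AA is the most recently incorporated
    one, so this identifies the last elongation event.
    """
    if not comp.left_motifs:
        raise ValueError("empty composition: no motifs adjacent to the center")
    return comp.left_motifs[-1][0]
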