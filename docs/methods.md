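# Methods

## The Type I elongation model

Type I mitochondrial VNTRs are modelled as products of reciprocal
incorporation of two 11-nt units, F = `TCCCTTTAGGG` and its reverse
complement R = `CCCTAAAGGGA`. Both fold into hairpins around a central
dinucleotide (TT in F, AA in R). One elongation event excises the current
center and inserts a unit carrying one extra base:

* **F incorporation** (into an AA center): `AA → TCCCTTTAGGGT` (+T at 3').
* **R incorporation** (into a TT center): `TT → S + CCCTAAAGGGA` (+spacer
  S ∈ {G, C} at 5').

Each event adds exactly 10 nt and flips the center, so event kinds strictly
alternate and an allele built from *k* events is `11 + 10k` nt long. The
alternation is a consequence of the mechanism, not an extra assumption; the
simulator enforces it as a precondition and fails loudly on violations.

The nucleating unit contributes boundary variants: a starting F ends in
`AGGG` (no trailing T) and a starting R begins with `CCCTA` (no spacer),
because the +T/+S additions happen only on incorporation. This makes the
11 + 10k arithmetic exact and the grammar below unambiguous on clean
alleles.

### Decomposition grammar

An allele is parsed as

```
left flank            center   right flank
{TCCCT | SCCCTA}*     TT|AA    {AGGGT | GGGA}*
(outermost CCCTA      (innermost first;
 allowed once)         outermost AGGG allowed once)
```

Every TT/AA dinucleotide is tried as a center; each half-motif may carry at
most `max_mismatch_per_motif` substitutions (default 1). Among valid
parses the ranking is: most motifs, then fewest mismatches, then the
leftmost center. `n_f` counts F-class left motifs, `n_r` R-class left
motifs; a flag records when left and right counts disagree (they cannot on
model-generated alleles).

Three deliberate choices:

* **Spacer observations are always recorded.** The spacer position (ref
  written `S`) legally carries G or C, so a G↔C difference is not a
  mismatch — but it is precisely the strain-diagnostic signal used in
  inheritance fingerprinting, so the observed base is always emitted in the
  SNP list with reference `S`.
* **Strand auto-orientation.** The grammar is strand-specific: the reverse
  complement of a Type I allele belongs to the partner motif family
  (left units of the `TSCCTSCCCTA`/`GGGAAGGGT` kind) and does not parse
  under the forward grammar. The decomposer therefore parses both the
  allele and its reverse complement, keeps the better parse (ties prefer
  the forward strand), and reports minus-strand parses in the swapped
  convention (n_f ↔ n_r, center complemented), so F/R counts are
  strand-consistent.
* **Indel fallback.** Field alleles sometimes show a 4-nt `TCCT` variant of
  the `TCCCT` half-motif. When no substitution-only parse exists on either
  strand, a second pass allows one single-base deletion per motif and the
  result is flagged `indel_fallback`. The clean model stays primary.

An exhaustive round trip (both start units, all spacer choices, all event
lists up to 8 events — 107 alleles) recovers unit counts, center and the
innermost (most recent) unit with zero failures.

## Tandem-array detection

Third-party repeat finders score alignments probabilistically; this package
instead uses a deterministic, auditable k-mer-seeded exact-extension scan.
For each candidate unit length d in `[min_unit, max_unit]`, a seed is two
adjacent identical d-mers with a primitive (non-self-periodic) unit. Seeds
extend outward whole-unit-at-a-time while (a) the stepped unit carries at
most `max(1, ceil((1−min_purity)·d))` substitutions and (b) global purity —
fraction of positions matching a perfect repetition of the unit phased at
the array start — stays ≥ `min_purity`; then base-by-base for exact
fractional copies (reported to 0.1, as repeat finders conventionally do).

Competing descriptions of one region (phase-shifted seeds that trade a
flank base for an internal mismatch; short periodicities embedded in longer
arrays, such as the AAGGG×2 window at a Type I center) are resolved by a
conflict pass: arrays overlapping by more than one unit of the shorter
compete, and the one with the most matched positions wins.

Circular molecules are scanned as a doubled sequence; arrays wholly inside
the second copy, and arrays whose footprint (mod L) is covered by a longer
array, are dropped, so an origin-spanning array is reported exactly once
with `start ∈ [0, L)` and `end` possibly beyond L.

Defaults: `min_unit 5`, `max_unit 30`, `min_copies 2`, `min_purity 0.9`,
chosen for the 7–17-nt units of this system with one-SNP-per-unit
tolerance. Units are reported in the phase first encountered; a canonical
(lexicographically minimal) rotation is stored for cross-locus comparison.

**Classification:** adjacent arrays with distinct, non-reverse-complementary
units separated by ≤ `max_gap` (default 50 nt) merge into a Type I locus;
everything else is Type II. **Partner pairing:** loci are cross-complementary
partners when every unit of one is the IUPAC-aware, rotation-tolerant
reverse complement of a unit of the other, in both directions; the first
match wins.

## Genotyping

In-silico PCR requires a substitution-only match of the forward primer and
of the reverse primer's reverse complement (≤ `max_mismatch` each, exact
3'-terminal base) and a unique product ≤ `max_len`; zero or multiple
products raise distinct errors. Repeat counting anchors the best-scoring
run of unit copies (each ≤ `max_mismatch_per_unit` substitutions from the
unit), ties broken 5'-most, with an exactly-matching fractional trailing
copy; SNPs are recorded as (copy index 1-based, ref, obs, offset 0-based).
Two strains are distinguishable when at least one marker typed in both
differs in amplicon length or sequence.

## Inheritance calling

Per marker, with alleles compared on length and full sequence:

1. parents identical → **ND** (not differentiable);
2. mate identical to exactly one parent → that parent;
3. otherwise: mate longer than both parents → **UP** (new repeat units),
   with the parent inferred by SNP fingerprint where possible; mate equal
   in length to one parent but fingerprinting as the other → the
   fingerprint parent with an elongation flag; anything else is
   uninterpretable and reported ND.

The fingerprint uses only positions where the two parents differ — matching
anywhere else says nothing about parentage. A position absent from an
allele's SNP list is taken as the canonical base *only when the allele
actually contains that motif* (its unit count reaches the index); a motif
present only in the longer parent is excluded, since the shorter allele has
no base there at all.

The overall call ignores ND markers, resolves UP through its inferred
parent, and returns MON/DI when unanimous, MIXED when both parental origins
appear (defined for totality; never observed), UNDETERMINED when nothing is
informative. Internally the package distinguishes "parents identical" from
"uninterpretable", but table-style output prints ND for both.

The bundled 22-trio Di–Mon mate panel (six markers per trio, tokens Mon /
ND / UP / Mon*) replays to 22/22 monokaryon-origin calls with six
elongation-flagged markers (four UP + two SNP-rescued collisions).

## Synthetic data

The generator emulates the observable structure of the system: a circular
120 kb molecule (tests and the acceptance script use 3–12 kb for speed; the
conditions are otherwise identical), Type II copy numbers uniform on
[2, 11], Type I loci of 4–9 events with a per-locus spacer, each Type I
locus accompanied by a reverse-complement partner elsewhere, unique 20-nt
primer sites ±110 nt around every locus (amplicons land in the 200–500 bp
range), 25-strain panels, per-unit SNP probability 0.02 by default, and a
per-marker elongation probability of 0.05 in mating (≈ 6 events per 22
trios × 6 markers, matching the observed rate).

Background sequence is uniform ACGT but screened so the planting record is
an exact detector oracle: every appended base is resampled if it would
complete a two-copy tandem window with a primitive unit ≥ 5 nt (the
detector's reporting floor) or continue, in phase, an array ending just
before it; planted-segment junctions and the circular origin junction are
re-rolled until no array crosses them. Type II truth spans are analytic;
Type I truth arrays are derived by isolated detection in their real flank
context, because the phase break at the nucleating unit makes the exact
maximal span (including in-phase fractional bases) awkward to state in
closed form.

Trio generation copies the monokaryon's mitochondrial profile into the
mate, optionally adds repeat units, and draws a donor nucleus. When an
elongated mate allele collides *exactly* (length and sequence) with the
dikaryon allele it is grown one more unit: such a collision is unresolvable
by construction for a length-only marker, and the study conditions modelled
here had every elongated allele still assignable. What passing tests on
this generator do **not** show: robustness to sequencing error, indel
variation inside units, mtDNA recombination, or non-uniform base
composition — none of which the generator emulates.

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open on the forward strand; GFF3 output
converts to 1-based inclusive. Copy numbers are rounded to 0.1. Degenerate
inputs fail explicitly: empty sequences, non-IUPAC characters, unit length
< 5, `min_unit > max_unit`, non-alternating event lists, mates whose
nuclear types are inconsistent with their parents. Tie-breaks are
deterministic everywhere (leftmost center, 5'-most run, first partner
match), so every pipeline stage is reproducible given a seed.

## Known limitations

* The detector targets units of 5–30 nt at ≥ 90 % purity; diverged or
  indel-riddled arrays are out of scope.
* The elongation model describes growth only; repeat loss is not modelled,
  and nothing is claimed about which unit (F or R) nucleates a real locus —
  both are supported.
* The decomposer's indel fallback handles single-base deletions per motif
  only.
* Inheritance calls assume exactly one candidate donor dikaryon and
  monokaryon; mixed or recombinant mitochondrial genomes are not modelled.
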