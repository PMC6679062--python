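# mtvntr

Mitochondrial VNTR analysis for the shiitake mushroom *Lentinula edodes*:
tandem-repeat detection in circular mtDNA, Type I / Type II locus
classification, a mechanistic elongation model for Type I repeats, VNTR
genotyping of strain panels, and mitochondrial/nuclear origin calling in
dikaryon–monokaryon (Di–Mon) matings.

## The problem

*L. edodes* mtDNA carries dozens of variable number tandem repeats (VNTRs)
that make excellent strain markers: a short PCR product spanning a VNTR
differs in length between strains whenever the repeat count differs, and
within-unit SNPs discriminate even same-length alleles. Two architectures
occur:

* **Type II** — simple tandem arrays of a single unit (GCTCCGC, GCGTAGC or
  TACTAATCCTCCTCCCT; 7 or 17 nt), with copy numbers from 2 to 11 across
  strains.
* **Type I** — two distinct repeat units juxtaposed symmetrically around a
  central TT or AA dinucleotide, with reverse-complementary partner loci
  elsewhere on the molecule.

Type I loci grow by reciprocal incorporation of two 11-nt basic units,

```
F = 5'-TCCCTTTAGGG-3'        R = revcomp(F) = 5'-CCCTAAAGGGA-3'
```

at the center of the array: an F unit (plus a 3' T) replaces the central
AA, an R unit (plus a 5' G or C "spacer") replaces the central TT. Each
event adds 10 nt, events strictly alternate, and an allele produced by *k*
events is `11 + 10k` nt. Reading outward-in, the left flank is an
alternating string of `TCCCT` and `SCCCTA` half-motifs and the right flank
of `AGGGT` and `GGGA` half-motifs; the decomposer inverts this grammar and
reports an allele as, e.g., 5F+4R with its SNPs.

In Di–Mon ("Buller") mating, one nucleus of a donor dikaryon migrates into
a monokaryon's cytoplasm. Scoring VNTR markers in the dikaryon ("Di"), the
monokaryon ("Mon") and the mate tells whose mitochondria the new dikaryon
carries; A-mating-type labels identify the donated nucleus. Occasionally a
mate allele is *longer* than both parents — a repeat unit was added during
mtDNA replication — and diagnostic SNPs can still assign its parent.

## Worked example

Grow a Type I allele from an F unit by eight alternating events and parse
it back:

```
$ mtvntr simulate --start F --events RFRFRFRF --spacer G
TCCCTGCCCTATCCCTGCCCTATCCCTGCCCTATCCCTGCCCTATCCCTTTAGGGTGGGAAGGGTGGGAAGGGTGGGAAGGGTGGGAAGGG

$ mtvntr simulate --start F --events RFRFRFRF --spacer G > /tmp/a.txt
$ printf '>allele\n%s\n' "$(cat /tmp/a.txt)" > /tmp/a.fa
$ mtvntr decompose /tmp/a.fa
[
  {
    "id": "allele",
    "n_f": 5,
    "n_r": 4,
    "center": "TT",
    ...
  }
]
```

The 91-nt allele parses as five F and four R units around a TT center; one
more R event produces a 101-nt 5F+5R allele — exactly the half-unit growth
seen in elongated mate alleles.

Replay the bundled 22-trio Di–Mon mate panel:

```
$ mtvntr inherit | head -3
strain   overall  n_elongated  donated_nucleus  VNTR7  VNTR13  VNTR18  VNTR20  VNTR23  VNTR25
IUM3182  MON      1            A11              Mon    Mon     Mon     Mon*    Mon     Mon
IUM3179  MON      0            A19              Mon    Mon     Mon     Mon     Mon     Mon
```

All 22 matings resolve to monokaryon-derived mitochondria; six markers
across the panel carry newly added repeat units (four "UP" alleles longer
than both parents plus two SNP-rescued length collisions).

Other subcommands: `detect` (tandem arrays), `classify` (loci + inverted
partners, GFF3/TSV out), `genotype` (unit counting over allele FASTA) and
`simulate-data` (synthetic genomes and panels with ground truth).

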