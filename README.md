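# satkit

Characterization of satellite DNA repeats in plant genomes: tandem
periodicity and monomer extraction, higher-order repeat (HOR) decomposition,
monomer diversity and species specificity, satellite capture by transposable
elements (TEs), chromosome-scale annotation, and read-based copy-number
estimation.

## The problem

Satellite DNA consists of non-coding monomers (here 36–240 bp, strongly
AT-rich) repeated head-to-tail in long arrays. Characterizing a satellite
family from clones and assemblies involves a recurring set of desk analyses:

- **Periodicity and monomers.** The monomer length is the lag *p* maximizing
  the autocorrelation support `s(p) = (1/(L−p)) Σᵢ 1[xᵢ = xᵢ₊ₚ]`; arrays and
  multimeric clones are cut into monomers against a consensus by iterated
  local alignment.
- **Consensus and identity.** Monomers are multiply aligned; the consensus
  is the per-column majority base. Pairwise identity is matches divided by
  *all* alignment columns (gaps count against identity).
- **HOR structure.** Many monomers carry an internal duplication — a leading
  subunit S1 whose diverged echo begins the second subunit (S1 + S2), or two
  diverged variant subunits ahead of an unrelated remainder
  (S1‑1 + S1‑2 + S2). Detection is an anchored prefix-duplication test: the
  match count between `cons[0:l]` and `cons[l:2l]` is referred to an exact
  binomial null with the composition-derived per-site match probability
  `p₀ = Σ_b f_b²` (AT-rich sequences agree at ~⅓ of sites by chance, so an
  uncorrected identity threshold is meaningless).
- **Diversity.** Neighbor-joining dendrograms from `d = 1 − identity`
  matrices; a family is species-specific when mean within-species identity
  exceeds mean between-species identity by ≥ 5 percentage points *and* at
  least one species forms a monophyletic tip cluster.
- **TE association.** Satellite-like units are found genome-wide by
  seed-and-extend local alignment (11-mer seeds, Smith–Waterman extension),
  clustered by the 75 % identity / 75 % length single-linkage rule, and
  classified as tandem-within-TE, dispersed-within-TE, or standalone array.
  The target-site duplication (TSD) — the short exact direct repeat flanking
  an insertion — is read directly off the element boundaries.
- **Distribution.** Monomers are annotated along pseudochromosomes at an
  80 % identity / 80 % coverage floor and each family's placement is
  classified as central, multisite, dispersed, or absent.
- **Copy number.** `copies = ⌊genome_size × genome_proportion / monomer_length⌋`,
  where the genome proportion comes from read clustering. Outward-facing
  primers on a tandem array produce the diagnostic amplicon ladder
  `band(n) = (monomer_length − forward_start) + reverse_end + (n−1) × monomer_length`.

Every stage is validated against a built-in, seeded synthetic genome
generator that plants arrays, HOR structures, TE insertions with TSDs, and
PCR-multimer clones with machine-readable ground truth.

## Worked example

`examples/characterize_clones.py` simulates the clone-based workflow for a
37 bp family with a 10 bp duplicated leading subunit:

```
simulated 6 clones, insert sizes: [55, 92, 129, 166, 203, 240]
extracted 27 monomers from the clone set
15 of 27 monomers are full length
consensus length: 37 bp
pairwise monomer identity: 0.95-1.00
HOR model: S1(10 bp) + S2(27 bp)
internal boundaries (bp): [10]
```

The insert sizes follow the ladder law (first band 55 bp, increments of one
37 bp monomer); extraction recovers the monomers at ~95 % mutual identity
(5 % divergence was planted), and the HOR decomposition recovers the planted
10 bp subunit boundary exactly. The other examples cover copy numbers and
ladders (`copy_number_and_ladder.py`), TE capture with TSD detection
(`te_association.py`), chromosome annotation and distribution classes
(`annotate_genome.py`), and NJ dendrograms with the specificity score
(`diversity_tree.py`).

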