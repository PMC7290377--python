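# Methods

This note documents the models, statistics, and numerical choices behind
satkit, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates, alphabet, alignment

All coordinates are 0-based half-open internally; GFF3 output converts to
1-based inclusive at the boundary, BED stays half-open. The alphabet is
`{A, C, G, T, N}`; other IUPAC ambiguity codes are folded to `N` on input
with a warning, and `N` never matches anything (including another `N`).

Pairwise alignment is Needleman–Wunsch (global) and Smith–Waterman (local)
with linear gap costs. Defaults are match +2, mismatch −3, gap −5 —
tandem-repeat-finder-style weights (light match reward, heavy mismatch and
indel penalties suit highly similar repeat copies); all callers can override
them. Traceback ties break diagonal-first, then up, then left, and the local
traceback starts from the first (row-major) maximum cell, so every alignment
string is deterministic. **Identity** is matches divided by *total alignment
columns*: gap columns count against identity. Published repeat-identity
values rarely state their denominator; this is the strictest reproducible
choice, so identities computed here can sit slightly below values produced
by tools that ignore gap columns.

## Dotplots

`wordmatch_segments` reports every maximal diagonal run in which each
k-window (default k = 10–12) holds at most S mismatches (S = 2–3), on both
strands if requested — the word-match dotplot style used for repeat
structure. `windowed_dotplot` marks every diagonal point covered by some
full window (default 14) scoring at least the threshold (default 27) under
+5/−4 DNA scoring; with that matrix the threshold means "≥ 7 matches of
14". Both kernels are property-tested for exact agreement with brute-force
window enumeration.

## Periodicity and monomer extraction

`estimate_period` maximizes the autocorrelation support (fraction of
positions matching the base one lag away); sub-multiples are resolved by
preferring the smallest lag within 0.05 of the maximum, and no period is
called below a support of 0.60 (random sequence supports sit near the
composition background, ≈ 0.25–0.35). The phase is the offset maximizing
mean identity between consecutive slices.

`extract_monomers` cuts either at `phase + n × period` (period mode) or at
successive best local alignments of a reference consensus with masking
(consensus mode). Local alignment trims mismatching monomer edges, so each
hit is extended to the uncovered reference span before masking; at 5 %
planted divergence ≥ 95 % of recovered boundaries fall within ±2 bp of
truth. Full-period (or reference-scale) slices are monomers; any incomplete
terminal remainder is returned as a partial, and in consensus mode a
matched region shorter than half the reference is a partial. Degenerate
input (no monomer-scale alignment at ≥ 50 % identity) is an error rather
than an empty result.

Consensus building is progressive-MSA + per-column majority with ties broken
in fixed A<C<G<T order; majority-gap columns are dropped. Identity matrices
optionally exclude mask intervals (e.g. primer regions) mapped through the
MSA from both numerator and denominator.

## HOR decomposition

The field identifies higher-order structure by eye from self-dotplots; this
package fixes an explicit, reproducible rule. Detection runs on the
consensus monomer (majority vote removes most inter-monomer noise) and
tests, for each lag `l` from 10 to L/2, the *anchored prefix duplication*:
the number of matches between `cons[0:l]` and `cons[l:2l]`.

- The null is an exact binomial with per-site match probability
  `p₀ = Σ_b f_b(f_b·N−1)/(N−1)` pooled over the monomer set and clipped at
  0.38. The clip matters: for 36–50 bp monomers the plug-in estimate is
  dominated by sampling noise, and beyond ~62/38 AT skew it stops being
  information about the null.
- Lags ≤ 12 bp carry too few sites for a per-template null and use a fixed
  80 % identity floor (≤ 2 mismatches in 10) instead, a ≈ 0.5–1.3 % per-lag
  false-positive rate across the satellite composition range.
- Longer lags get explicit per-lag false-positive budgets: 10⁻³ for
  13–32 bp (the range where satellite subunits are observed) and 10⁻⁴
  beyond. The budgets are deliberately uneven: short duplications carry few
  informative bits, so they receive the larger share; long lags have sites
  to spare, so strictness there is free sensitivity elsewhere.

The smallest qualifying lag is called and refined (±2 bp) to the most
identical copy pair. Model shape: no tail → the two copies are the two
subunits; lag ≤ 20 bp → compact S1 plus composite S2 still containing the
echo (the presentation used for 10–20 bp subunits); longer lag with a tail
→ diverged variant subunits S1‑1 + S1‑2 ahead of S2. Subunit variants are
classed by average-linkage clustering on pairwise identity, cutting where
the within-minus-between identity gap is maximal (capped at 3 classes,
minimum gap 0.05).

An identifiability limit is worth stating plainly: for 27 bp subunit copies
at ≲ 60 % mutual identity, the match-count distributions of a real
duplication and of the best chance pairing in an AT-rich monomer overlap
substantially — no detector can simultaneously deliver ≥ 90 % recovery
there and ≥ 95 % specificity on elementary monomers. The synthetic
benchmark therefore plants variant subunits at 30 % divergence (≈ 70 %
identity, the detectable upper end of the 41–67 % identity range reported
for such variants in the motivating system), and the generator applies
variant divergence as an exact substitution count so that each replicate's
planted structure realizes its nominal divergence. More diverged
duplications degrade gracefully into single-subunit verdicts; they are not
claimed to be recoverable.

## Diversity and species specificity

The progressive MSA uses an average-linkage guide tree on shared-5-mer
distances and sum-of-pairs profile–profile DP under the seq-level scoring;
a two-sequence input reduces exactly to the pairwise global alignment.
Dendrograms use canonical neighbor joining — deterministic (Q-ties break
toward the lexicographically smallest tip pair), exactly testable, and
provably exact on additive matrices — rather than approximate
maximum-likelihood, since the trees serve qualitative clustering only.
Negative branch-length estimates are clamped to zero and flagged.

The species-specificity score is mean within-species identity minus mean
between-species identity in percentage points; the verdict requires ≥ 5
points *and* a monophyletic species in the NJ tree. The 5-point threshold
is this package's operationalization of qualitative "species-specific"
calls and is configurable; singleton species are excluded from the within
mean and reported.

## TE association

`scan_similarity` nominates candidate loci from exact 11-mer seed matches
(both strands), groups seed-derived start estimates, and extends each
candidate by local alignment of the full query against a padded window.
Grouping is density-aware: estimate bins (8 bp) carried by a single seed
are discarded — isolated chance seeds otherwise chain adjacent tandem
copies into one candidate — and chains wider than 0.6 query lengths are
split at their largest internal gap. Hits pass at ≥ 80 % identity and ≥
80 % query coverage by default; same-strand hits overlapping more than half
of the shorter are merged keeping the best identity (literal any-overlap
merging would fuse abutting tandem-array hits).

`detect_tsd` reports the longest exact, boundary-anchored direct repeat
(2–12 bp) flanking an element. The anchored ≥ 2 bp rule has a 1/16
false-positive probability per boundary pairing on random flanks, and a
planted t-bp TSD is extended to t+k only by a ~4⁻⁽ᵗ⁺¹⁾-probability
coincidence — the dominant (≈ 1 %) failure mode of the archetype benchmark.

`classify_association`: tandem-within-TE needs ≥ 2 inside hits with every
inter-hit gap ≤ 25 % of the query length; any other inside hit is
dispersed-within-TE; ≥ 2 adjacent hits with no element form a standalone
array. The gap tolerance approximates "adjacent units" and is configurable.

## Chromosome annotation and distribution

Annotation is `scan_similarity` per chromosome at identity ≥ 0.80 and
coverage ≥ 0.80 (both knobs exposed; the 80 % level is the similarity floor
used for chromosome-scale satellite annotation in highly diverged,
TE-associated families). A *run* is a maximal chain of records with
inter-record gaps ≤ 100 kb (configurable). Per chromosome:

- **absent** — no records;
- **central** — ≥ 80 % of records inside the middle third, ≤ 2 runs (the
  middle-third proxy reflects metacentric/submetacentric chromosomes);
- **dispersed** — records span ≥ 80 % of the chromosome, no run holds
  > 30 % of records, and the median run holds ≤ 2 records;
- **multisite** — ≥ 3 runs, and the fallback for anything else.

Evaluated in that order. The median-run-size guard in *dispersed* is what
separates isolated TE-borne monomers from several genuine arrays that
happen to span a chromosome — without it the two regimes' predicates
overlap and no evaluation order classifies both correctly. The family-level
pattern is the modal per-chromosome pattern among chromosomes carrying the
family (ties resolve alphabetically).

## Copy number and ladders

`copy_number` floors (never rounds) `genome_size × proportion /
monomer_length`: truncation is the only rule that reproduces the canonical
integer table from its fractional intermediates (e.g. 2326.7 → 2326,
1438.77 → 1438). For the 36–38 bp family the midpoint length 37 is used.
Two families' printed copy numbers are *not* reproducible from their printed
proportions and lengths under any rounding rule; they are excluded from the
exact benchmark and flagged in the preset notes. Ladder prediction applies
the outward-facing-primer law exactly and enumerates cross-products of
secondary primer sites as off-ladder bands when primer sequences are given.

## The synthetic generator

`satkit.synth` emulates: i.i.d. backbones at a chosen GC (default 38 %,
a typical plant genome-wide value); per-site independent substitutions and
single-base indels applied independently per copy from a shared template
(star phylogeny, matching how divergence-from-consensus is reported);
family presets mirroring the motivating system (monomer lengths 37–238 bp,
GC 17–41 %, genome proportions 0.015–1 %); LTR- and TIR-bounded elements
carrying satellite units; TSDs created mechanistically by duplicating the
insertion-site k-mer; and PCR multimers cut between outward-facing primer
sites. Determinism is strict: identical seeds give byte-identical sequences
and truth.

What the generator does **not** model — and hence what passing benchmarks do
not show about real data: sequencing error profiles, unequal
crossing-over/array homogenization dynamics, chimeric PCR artifacts, nested
or fragmented TE insertions, assembly collapse of long arrays, and
compositional heterogeneity along real chromosomes. Benchmark sizes (100
archetype seeds, 50 HOR replicates per family, a 12 × 1.1 Mb annotation
genome) were chosen as the smallest sets that make the reported rates
stable to within a few percent across seed blocks.

## Known limitations

- HOR detection tests duplications anchored at the monomer start; an echo
  internal to an arbitrary monomer phase requires re-phasing the monomer
  frame first (extraction from arrays yields a consistent phase, so this
  binds mainly for externally supplied monomers).
- Affine gaps are not implemented; at satellite scales linear gaps with the
  default weights behave nearly identically for ≤ 10 % divergence.
- `scan_similarity` is exact-seeded: sensitivity drops steeply beyond ~25 %
  query divergence (by design — the annotation floor is 20 %).
- The NJ tree is unrooted and unsupported (no bootstrap); monophyly is
  evaluated as a split of the unrooted topology.
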