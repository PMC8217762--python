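# Methods

`famevo` re-implements a genome-wide gene-family expansion analysis of the
kind applied to the mouse Wnt (PF00110) and DIX (PF00778) families as a
reusable, tested pipeline.  This note records the models, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Family identification and physicochemistry

Membership is decided on HMMER3 `domtblout` hits filtered at
`E-value <= 1e-5` and `bit score >= 0`, both comparisons inclusive.  The
full-sequence E-value is filtered by default; a flag switches to the
per-domain independent E-value, since search protocols differ on which one
they threshold.  Redundant isoforms collapse to one representative per
gene: the longest isoform, ties broken by the lexicographically smallest
protein id — a deterministic reading of the usual "redundant sequences
were removed" step.

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water (18.0153 Da), the convention of the ExPASy Compute pI/Mw
tool.  `X` contributes the mean of the 20 canonical masses and carries no
charge.  The isoelectric point is the root of the Henderson–Hasselbalch
net charge over the two termini plus D, E, C, Y (acidic) and H, K, R
(basic), found by bisection on [0, 14] to a default tolerance of 1e-3 pH
units.  The pK set is the Bjellqvist/ExPASy table (N-term 7.5, C-term
3.55, D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0), passed as
an argument so other tables can be swapped in.  Charge is strictly
decreasing in pH, so the root is unique; tests verify both quantities
against an independent brute-force oracle (direct mass summation; a
1e-4-step pH grid search).

Cross-species family sizes are compared with classical one-way ANOVA plus
Dunnett many-to-one comparisons against a designated control group, via
`scipy.stats.dunnett` (exact multivariate-t quantiles).  An earlier plan
to approximate the Dunnett adjustment by seeded Monte Carlo was dropped
once the exact implementation was available — it is both faster and free
of simulation error.

`orf_length_bp` encodes the CDS arithmetic `3 * (n_residues + 1)` (three
bases per codon plus a stop), e.g. a 349-aa protein ↔ a 1,050 bp ORF.

## Tandem duplication

A tandem group is a maximal run of ≥ 2 same-family genes with no
intervening annotated gene of any kind.  "No spacer genes" is interpreted
through the gene-order index over *all* annotated genes on a chromosome
(ranked by start, ties by end), not through a base-pair cutoff — the rule
as stated names adjacency, not distance.  A bp-threshold mode exists but
is off by default.  Runs of three or more chain transitively into one
group.  Strand is ignored.  Two genes with identical coordinates on one
chromosome are rejected: their order, and hence adjacency, would be
undefined.

## Phylogenetics

Distances come from a consumed multiple alignment (the aligner itself,
e.g. ClustalW, is out of scope) under pairwise gap deletion: p-distance,
or the Poisson correction `d = -ln(1 - p)` — the default for proteins,
matching the common default of desktop phylogenetics suites.  Complete
deletion was not chosen because it discards whole columns for a single
gapped row; a flagged alternative was considered unnecessary given
pairwise deletion dominates in practice.

Trees are Saitou–Nei neighbor joining.  Ties in the Q criterion break on
the lowest (row, column) pair for determinism; negative branch lengths
are clamped to zero (with the raw value logged), the convention of
MEGA-style implementations.  On additive matrices the algorithm recovers
the generating topology and path lengths exactly (tested on 500 random
additive matrices of 4–10 taxa, plus a brute-force four-point oracle over
all three quartet topologies); on noisy matrices it agrees with
scikit-bio's independent NJ implementation.

Bootstrap support of an internal edge is the fraction of
column-resampled replicate trees containing the same bipartition,
deterministic under a seed.  One numerical wrinkle: a resampled replicate
can saturate a pair (p = 1), where the Poisson distance is undefined.
Replicate distances therefore cap p at `1 - 1/(2L)` (L = alignment
columns); the tree from the full alignment is built uncapped, and a
saturated pair there is an error, surfaced to the caller.

Phylogenetic cluster proportions (e.g. "cluster VII holds 23 of 118
proteins, 19.5%") are computed from an explicit assignment map, not from
an automatic tree cut: published groupings of this kind are manual.

## Phylostratigraphy

Each gene carries presence flags for orthologs in zebrafish, sea urchin,
nematode, and yeast — four successively deeper divergences from mouse.
The stratum label is set by the deepest species with an ortholog:
`++++` (yeast; origin with eukaryotes), `+++-` (nematode), `++--`
(sea urchin), `+---` (zebrafish), `----` (none; origin after the
invertebrate–vertebrate split).  The five symbols assume nested presence;
a gapped pattern (e.g. present in nematode, absent in sea urchin) is
labelled by its deepest present species and flagged `non_nested` so it is
never silently mislabelled.  Family-vs-genome background comparisons
report the per-stratum proportion ratio, plus a two-sided Fisher exact
p-value from the 2×2 table — added because a ratio without any test is
uninterpretable at small family sizes; the ratio remains the primary
output.  Family-size co-expansion across species is a standard Pearson
correlation with the t-distribution p-value.

## Mirror-tree co-evolution

The score for one A-member against one B-member is the Pearson
correlation of their inter-species distance matrices, restricted to
shared species (canonical sorted order, making the score symmetric and
order-invariant) and compared over the strict upper triangles.  Distances
are Poisson-corrected from each member's ortholog alignment; the original
server-side settings behind published mirror-tree values are not
recoverable, so exact reproduction of real-data means is not attempted.
Pairs with fewer than 4 shared species (configurable) return a missing
value with a reason — below that, n(n-1)/2 ≤ 3 points cannot support a
correlation.  Missing pairs are excluded from the family mean and
counted.  Background-signal correction (partial-correlation mirror-tree
variants) is a documented non-goal.

## Expression classification

The differential-expression stage substitutes a fully specified
classifier for a moderated-statistics (limma-style) fit, which is out of
scope: log2 fold change = case mean − control mean; *up* when
`log2fc >= lfc_min` (default 1.0) — and, in `welch` mode, Welch t-test
p < alpha (default 0.05) — *down* symmetrically, else *unchanged*.
`fc_only` is the default mode because it needs no replication assumption;
`welch` is recommended whenever each group has ≥ 2 samples.  Swapping
case and control exactly exchanges up and down calls.  Published
proportions (e.g. 7/3/9 of 19 → 36.84/15.79/47.37%) are reproduced as
proportion arithmetic from the printed counts; gene-level reproduction of
the original microarray calls would require the external GEO data and is
not attempted.

## Synthetic data

Generators draw from named substreams of one master seed
(`SeedSequence([seed, crc32(name)])`), so adding a generator never
perturbs existing outputs, and identical specs reproduce identical files
bitwise.

* **Trees**: Yule (pure-birth) topologies — a uniformly chosen leaf
  splits until n leaves — with Exponential branch lengths (default mean
  0.1 expected substitutions/site, a realistic protein-family scale that
  keeps pairwise distances well away from saturation).
* **Sequences**: 20-state equal-rates model, chosen over empirical
  matrices (WAG/LG) because it is sufficient for recovery tests and has
  an analytically tractable saturation limit.  Along a branch of length
  t a site keeps its state with probability `exp(-t)` and is otherwise
  redrawn uniformly over all 20 states, so divergence from the parent is
  `(19/20)(1 - exp(-t))`, saturating at 19/20.
* **Co-evolving families**: all members evolve on one shared tree; each
  member's per-edge log rate multiplier mixes a shared normal profile
  with a member-specific one as `sigma * (sqrt(rho)*shared +
  sqrt(1-rho)*own)` (sigma = 0.75, mean-corrected log-normal), giving
  log-rate correlation rho between any two members.  rho = 1 yields
  identical rate profiles; rho = 0, independent ones.
* **Genomes**: family genes placed as blocks (planted tandem groups plus
  singletons) on random chromosomes with at least one spacer gene between
  consecutive blocks, so detection must recover exactly the planted
  groups.
* **Ortholog tables and expression matrices**: exact planted stratum
  counts; Gaussian log2 matrices with a ±effect mean shift in the case
  group for planted genes.  The default design mirrors the study system:
  19 genes, 3 up / 7 down, effect 3 log2 units, unit noise, 5 samples per
  group.

What the generators do *not* emulate: indels and alignment error,
rate-across-site heterogeneity, empirical amino-acid exchangeabilities,
gene-length and intergenic-distance distributions of a real genome, and
array-specific noise structure.  Passing recovery tests therefore
demonstrate algorithmic correctness under the stated models, not
performance on real downloads.

## Problem sizes and tolerances in the test suite

The suite runs in well under a minute on one CPU: tandem recovery over
1,000 random layouts; NJ additivity over 500 random matrices (atol 1e-9
on path lengths); co-evolution monotonicity over rho ∈ {0, 0.3, 0.6,
0.9} with 50 replicates each (10 taxa, 2×2 members, 300 sites — sizes at
which the rho = 0.9 vs rho = 0 comparison was observed to separate in
200/200 replicates during design); DE recovery over 100 seeds (mean
per-gene accuracy ≥ 0.90, observed ≈ 0.97); pI/Mw oracle agreement on
100 random sequences.  Bootstrap tests use 50–200 replicates; the
production default stays 1,000.

## Known limitations

* NJ is O(n³) with a pure-Python pair search; fine for family-scale trees
  (tens to a few hundred taxa), not for thousands.
* The stratum classifier presumes the four fixed reference species; other
  ladders require changing `SPECIES_ORDER`.
* Fisher tests per stratum are not multiplicity-adjusted (five strata;
  callers can Bonferroni-adjust trivially).
* The expression classifier is intentionally simpler than an
  empirical-Bayes fit and will be conservative at very small n.
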