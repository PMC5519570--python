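# Methods

`microems` re-implements, as a tested pipeline over synthetic data with known
ground truth, the metacommunity analysis used for host-associated skin
microbiomes: OTU-table preprocessing, Elements of Metacommunity Structure
(EMS) inference with permutation nulls, and phylogenetic/compositional
beta-diversity tests. This note documents the models, the statistical
conventions, and the design choices that were genuinely open.

## The EMS procedure

An incidence matrix (hosts × OTUs, presence/absence) is ordinated by
reciprocal averaging (correspondence analysis, CA): rows and columns are
reordered by their scores on the first non-trivial CA axis. We compute the
axis by singular decomposition of the chi-square standardized matrix
`(P − r cᵀ) / √(r cᵀ)` rather than by iterated averaging — the two are
mathematically equivalent at the fixed point, and the SVD route is
deterministic. Sign convention: the axis is oriented so the first input
row's score is non-negative (first row with a nonzero score if that one is
zero); ordering ties break by original index. Matrices with no non-trivial
axis (e.g. all rows proportional) are rejected.

Three statistics are evaluated on the ordered matrix:

- **Coherence** — embedded absences: zeros lying strictly inside the first-
  to-last-presence span of each OTU column, plus (by default) the same count
  over host rows; a columns-only switch is provided. Fewer absences than the
  null indicates coherent ranges along a latent gradient; significantly more
  indicates a checkerboard.
- **Turnover** — each column's range is filled (embedded absences set to 1)
  and replacements are summed over unordered OTU pairs as
  (#sites with i only) × (#sites with j only). More replacements than the
  null indicates Gleasonian/Clementsian turnover; fewer indicates
  nestedness.
- **Boundary clumping** — Morisita's index
  `I_M = T · Σ nᵢ(nᵢ−1) / (N(N−1))` over per-site tallies of range
  boundaries (each occupied OTU contributes its first and last ordered site;
  both at the same site for a single-site range).

### The fixed-proportional (r1) null

Null matrices preserve each host's observed richness exactly; within a host,
OTUs are drawn without replacement with probability proportional to their
observed column totals. Sampling uses exponential-key (Efraimidis–Spirakis)
weighted reservoir selection, which is identical in distribution to
sequential weighted draws and O(S) per row; the 2×3 margin case is verified
against exact enumeration in the tests. The default is 99 permutations with
empty columns permitted, matching common practice on large OTU matrices.
Null matrices are re-ordinated before counting (switchable); empty columns
are dropped first, because an unplaceable all-zero column inserted into the
ordering would create spurious gaps in host rows while contributing no
range of its own.

### Significance conventions

For coherence and turnover we report the observed count, null mean and SD,
the z-score with its two-tailed normal p, and a two-tailed empirical rank p
`min(1, 2·(min(#null ≤ obs, #null ≥ obs)+1)/(n+1))`. The *classification*
decision tree thresholds the empirical p by default: permutation nulls of
these counts are visibly heavy-tailed, and the rank test has exact level
under exchangeability while the normal approximation is anticonservative.

For boundary clumping we report Morisita's index with the classical
dispersion chi-square `I_M(N−1) + T − N` (df = sites−1 by default; a
species−1 convention is switchable, matching reports that print
species-based df). The chi-square test, however, is strongly
anticonservative on CA-ordered matrices: the arch effect compresses site
scores near the gradient ends, and every range reaching a compressed region
piles its boundary on whichever site lands at the ordering's edge. Measured
on matrices built with randomly placed ranges (the very null hypothesis of
the clumping test), CA ordering inflates I_M from ≈1.0 to 1.5–3. The
classification therefore uses a Monte Carlo test against the literal
random-placement null: each null matrix keeps the observed filled range
lengths, draws uniform range starts, and is pushed through the same
ordination-and-counting pipeline, so ordination artefacts cancel by
construction. An r1-referenced I_M null was evaluated and rejected: the r1
null of a strongly compartmented matrix inherits its bimodal marginals and
reproduces the clumping (z ≈ 0), destroying sensitivity.

### Classification

With α = 0.05 (two-tailed, configurable): significantly *more* absences →
checkerboard; non-significant coherence → random; otherwise positive
coherence branches on turnover sign — fewer replacements → nested; more →
Clementsian if I_M > 1 and Monte-Carlo-significant, evenly spaced if
I_M < 1 and significant, Gleasonian otherwise. With `quasi` enabled a
non-significant turnover yields the "quasi-" variant of its sign-based
label; it is off by default. Degenerate nulls (SD = 0) propagate an
"indeterminate" label.

### Compartments

`split_compartments` cuts the ordered matrix at a row boundary — either
given, or proposed automatically as the split maximizing mean between-group
minus mean within-group Jaccard distance over ordered host pairs — drops
per-child empty columns, and re-runs the full EMS analysis on each child
with at least 4 hosts.

## Beta diversity

Jaccard (on presence sets), unweighted and weighted-normalized UniFrac
(via scikit-bio; verified in tests against an explicit per-branch
summation oracle), PCoA by Gower double-centering (negative-eigenvalue axes
reported and dropped from coordinates by default), ANOSIM and one-factor
PERMANOVA (Adonis; R² derived from the pseudo-F partition and cross-checked
against a Euclidean centroid oracle), and Mantel tests correlating
community dissimilarity with population-level Fst (expanded to sample
pairs; zero within populations) and great-circle geographic distance. All
permutation p-values use the (count+1)/(n+1) estimator; Mantel defaults to
10,000 permutations and the one-sided "greater" alternative, the group
tests to 999 permutations.

## The synthetic study

The generator emulates the field design the pipeline targets: 8 river
populations split 3 + 5 into two genetic demes, 43 animal and 8 water
samples (per-population animal counts 5,5,7,5,3,5,8,5 — the published
per-population counts sum to one more than the stated total, so one
population was reduced by one), environmental covariates (latitude,
elevation, % forest cover) drifting linearly along the latent gradient with
per-sample noise, pseudo-coordinates on a longitude transect, and an Fst
matrix with higher between-deme than within-deme divergence.

Canonical incidence structures on a 1-D gradient (sites generated sorted,
then shuffled; the true order is kept in the `truth` payload):

- *Clementsian*: species span exactly their compartment's site block —
  coincident boundaries, no inter-compartment overlap.
- *Gleasonian*: contiguous ranges with independently uniform endpoints.
- *Nested*: species occupy all sites up to a threshold; thresholds are
  stratified evenly over the gradient (iid thresholds make the observed
  replacement count vary wildly between replicates).
- *Evenly spaced*: equal-length ranges with maximally staggered starts.
- *Checkerboard*: mutually exclusive complementary pairs whose balanced
  site sets have their site-by-site co-occurrence flattened by greedy
  swaps. This matters: with random bipartitions the matrix is
  statistically indistinguishable from the r1 null after re-ordination,
  and with periodic stripes CA compacts the few distinct patterns into
  pseudo-compartments. Decorrelated exclusion is what makes a checkerboard
  a checkerboard — no ordering can compact the ranges, so embedded
  absences exceed the re-ordinated null.
- *Random*: a Bernoulli template at the target fill (default 0.5) sets the
  margins and the returned matrix is one fixed-proportional draw at those
  margins — i.e. the calibration case is drawn from the null process the
  tests assume, as is standard for null-model calibration. (Embedded-absence
  counts are concave in column totals, so r1 nulls of a plain iid Bernoulli
  matrix are biased low by ~0.5–1 SD.)

Abundance overlay: per-sample read depth is gamma-Poisson (negative
binomial; mean 20,000, shape 20); reads are allocated to present species by
multinomial sampling over iid lognormal weights (σ = 2.0). Species present
in ≥80 % of sites take the largest weights in prevalence order — this keeps
the always-present "core" OTUs dominant enough to survive rarefaction, like
the handful of taxa that dominate real skin communities — while all other
species receive the remaining weights in random order so narrow-ranged
species are not starved. The single most prevalent OTU's weight is then
calibrated so its expected within-sample relative abundance is
`dominant_fraction` (default 0.465).

The emulated study dataset adds, on top of a 4-compartment Clementsian
scenario (2 compartments per deme, so the deme boundary is the major split
with finer groupings inside, and compartment children re-classify as
Clementsian), three dataset-level layers: 9 core OTUs present on every
animal; ~5 % broad-ranged "bridge" OTUs whose contiguous ranges straddle
compartment edges — strictly disjoint compartments carry no information
about their own order along the gradient, and without bridges CA arranges
the blocks arbitrarily, destroying covariate correlations; and one water
sample per population sharing a fixed-size subset of the population's
animal OTUs (targets 0.29 in deme 1, 0.16 in deme 2) plus water-exclusive
OTUs, with the core OTUs always present in water. The phylogeny is a
random sequential coalescent with Exp(1) branch lengths over all OTUs —
any rooted binary tree with positive lengths suffices for testing
phylogenetic distances.

### What the generator does and does not emulate

It reproduces the study's design shape (sample layout, demes, covariate
gradients), the dominance structure (a ~46.5 % top OTU, 9 core OTUs, a long
rare tail), the compartmented incidence structure, and genetic/geographic
distance structure. It does not simulate reads, sequencing error, chimeras,
or 16S copy-number effects; OTU identity is abstract. Two quantitative
emulation limits: the rare tail reaches ~62 % of OTUs under 100 reads
(versus ~77.5 % in the study — pushing the lognormal σ high enough to match
thins the incidence until structure recovery fails), and rarefaction shifts
realized animal–water shared proportions upward of the generator targets
(the surviving OTUs in both sample types are the abundant, more widely
shared ones). Passing tests therefore show the pipeline recovers known
structure under realistic sparsity and dominance, not that real skin data
have any particular structure.

## Preprocessing conventions

The abundance filter removes OTUs whose total count is below
`min_fraction` × the grand total *of the input table* (default 0.005 %);
the pipeline order is fixed — filter, then rarefy. Rarefaction subsamples
each sample without replacement to exactly 8,800 reads by default via the
multivariate hypergeometric distribution; samples below depth are dropped
with a warning, never padded. The core microbiome uses ≥ on the exact
prevalence fraction (41/51 ≈ 0.804 is in at the 80 % threshold; 40/51 is
out), over all samples by default (configurable to animals only). Shannon
diversity uses natural log by default. The shared-OTU proportion divides by
animal richness by default; a union denominator is switchable.

## Problem sizes and determinism

Default analysis conditions: 99-permutation r1 nulls (both for the
coherence/turnover stream and the clumping Monte Carlo), 999-permutation
group tests, 10,000-permutation Mantel. The structure-recovery evaluation
uses 60 sites × 150 species at 2 % cell-flip noise, 20 replicates per
scenario; permutation-test calibration uses 1,000 null simulations at 199
permutations; the end-to-end demo runs the full 51-sample study shape in
well under a minute. One master seed drives everything: per-stage child
seeds are derived by hashing, so any stage can be re-run in isolation and
identical configuration + seed yields an identical report (timestamps and
runtimes aside).

## Known limitations

- Single-axis ordination only; no detrending. The arch effect is handled in
  the clumping test's null, not removed from the ordination itself.
- One-factor PERMANOVA only; no nested/multi-factor designs or partial
  Mantel.
- Geographic distance is great-circle; river-network distance is not
  modelled, though the hosts disperse along rivers.
- The clumping Monte Carlo conditions on observed filled range lengths;
  species whose observed range is fragmented by sampling noise contribute
  longer filled ranges to the null than their true ranges.
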