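# Methods

## Model and procedure

The package tests whether the between-group difference observed in one
microbiome count dataset (`ds1`) reappears in a second, independent dataset
(`ds2`). Sequencing counts are treated as compositional: only relative
information is meaningful, so all geometry is Aitchison geometry.

**Zero treatment and point estimation.** Each sample's relative abundances
are estimated as the mean of `n_draws` = 1000 Monte Carlo draws from
Dirichlet(counts + 0.5). The uniform 0.5 offset is the only zero treatment
anywhere in the pipeline; no pseudocounts are added elsewhere. The Monte
Carlo mean has the closed form (cᵢ + 0.5)/Σ(cⱼ + 0.5), available via
`exact=True`; the Monte Carlo mode is the default and the closed form serves
as its oracle in the tests. Draws use one RNG substream per sample, keyed by
(table seed, CRC32 of the sample id) rather than by column position, so the
estimate is deterministic *and* invariant to sample order — a property the
rest of the pipeline inherits and the tests assert.

**Log-ratio coordinates.** Compositions are mapped by the isometric
log-ratio transform, `coords = CLR(x) · B`, with `B` the D×(D−1)
Helmert-type contrast matrix (`scipy.linalg.helmert`), orthonormal and
orthogonal to the all-ones vector. The ILR basis is a free choice: any two
valid bases differ by a (D−1)×(D−1) orthogonal factor, so distances, PCA
eigenvalues, pseudo-F values, P values, and cosθ are all basis-invariant.
The tests verify full-output invariance under a randomly rotated alternative
basis; the deterministic Helmert basis in taxon sort order is therefore an
implementation convenience, not a modeling decision.

**Projection.** PCA is fitted on ds1's ILR coordinates alone (centered,
unscaled; eigenvalues with the n−1 divisor; components trimmed at a 1e−10
relative eigenvalue tolerance, keeping ds1's total variance to 1e−6). ds2 is
passed through the identical affine map — ds1's center and rotation. Because
every downstream statistic is translation-invariant, centering ds2 with
ds1's mean cannot change any P value or cosθ. By default all retained axes
are used by the tests ("all PCA axes"); `n_axes` restricts to the first k
for users who want the leading-axes variant.

**Component tests.** All use 10,000 permutations or bootstraps by default.

1. *ds1 segregation*: one-way PERMANOVA of ds1's groups on its PC scores.
   The pseudo-F on Euclidean coordinates is the classical between/within
   ratio F = [SS_B/(a−1)]/[SS_W/(n−a)] (centroid identity). Sampled-mode
   P values count the observed assignment, p = (1 + #{F* ≥ F})/(n_perm + 1),
   so p ≥ 1/(n_perm+1); when the number of distinct label assignments is
   ≤ n_perm the test switches to exhaustive enumeration (every distinct
   assignment exactly once, exact fraction reported). Ties count as ≥, with
   a 1e−9 relative tolerance on the comparison so that floating-point
   jitter (e.g. after a change of basis) cannot flip a tie.
2. *ds2 segregation*: the same PERMANOVA on ds2's projected scores, plus a
   second null in which the assignment of ds2's taxon profiles to the union
   taxon rows is randomly permuted, the permuted composition re-ILR'd and
   re-projected through the unchanged model, and the ds2 pseudo-F
   recomputed. The reported p2 is the larger of the two P values. The
   taxon null's statistic is the pseudo-F rather than a nested permutation
   P value; since CLR commutes with taxon permutation, each draw reduces to
   one matrix product. p2_taxon asks whether the *specific* matching — not
   generic multivariate structure — aligns ds2's segregation with ds1's
   axes.
3. *Direction*: the group-difference direction is the centroid difference
   (second group minus first) in PC-score space, computed per dataset with
   the caller's fixed group orientation. cosθ between the two directions is
   bootstrapped: replicates resample samples with replacement within each
   group of each dataset and the PCA model is refit on each resampled ds1
   (propagating axis-estimation uncertainty); a `fast` mode holds the model
   fixed. p3 = 2·min(Pr(cosθ* ≤ 0), Pr(cosθ* ≥ 0)), capped at 1 — a
   two-sided sign-crossing estimate of Pr(cosθ = 0). Replicates reuse each
   sample's deterministic Dirichlet point estimate; resampling whole samples
   already propagates the sampling variability that dominates at 1000
   draws. A zero-length direction makes cosθ undefined; it is reported as
   missing and p3 set to 1.

**Omnibus.** The three rejection regions are intersected
(intersection-union test): omnibus P = max(p1, p2, p3), always and exactly.
The IUT is level-α and typically conservative, which the measured type-I
error (≈ 0.03 at the 0.05 call) reflects. The 0.05 "similar" call is a
reporting convention, not package logic; results carry unrounded P values
and all seeds/settings for exact replay.

## Simulation framework

The generator emulates the structure of real 16S surveys without requiring
any external dataset:

- **Template**: log-normal rank abundance (σ = 2.0) over D = 200 species —
  a few dominant species and a long rare tail — with per-sample sequencing
  depths log-normal (median 3×10⁴, σ = 0.6) truncated to [10³, 10⁶] by
  clipping. Any user count table can be used as an empirical template
  (pooled proportions, observed depths).
- **Pairs**: 10% of species (⌈0.1·D⌉) are differentially abundant. ds1
  multiplies their proportions by a constant 2^log2FC in group 2 and
  renormalizes; ds2 applies per-species effects drawn from
  Normal(log2FC, s²), untruncated (negative draws applied as drawn).
  *Similar* pairs shift the same species set in both datasets; *dissimilar*
  pairs shift disjoint, equally sized sets. Partial taxon overlap is
  simulated by suffixing a fraction (1 − overlap) of ds2's species names
  with "xx" so they cannot be matched. Samples are multinomial at their own
  drawn depths, N per group, two groups per dataset.
- **Evaluation**: pairs alternate similar/dissimilar (≈1:1), each with a
  seed derived from (run seed, pair index) so serial and parallel execution
  agree; the call `omnibus_p ≤ t` is swept over a threshold grid into
  sensitivity, specificity and ROC points. The ≤ convention makes the
  endpoints exact: at t = 1 everything is called (sensitivity 1,
  specificity 0), at t = 0 nothing is. A `null_ds2` mode randomizes ds2's
  group labels after simulation for type-I-error studies.

What the generator does *not* emulate: real taxon-taxon correlation
structure, overdispersion beyond the multinomial, batch effects, or
compositional artifacts of differing bioinformatic pipelines. Passing the
simulated power/specificity properties therefore demonstrates correct
behavior of the statistics under the stated generative model, not
performance guarantees on arbitrary real studies.

## Problem sizes used by the test suite

The suite exercises the operating characteristics at reduced permutation
counts (n_perm = n_boot = 500) on the default 200-species template:
200 pairs per cell for the specificity grid (log2FC ∈ {1,2,3,4}, N = 6,
s = 0, overlap = 1), for the high-effect sensitivity cell, and for the
type-I run; 100 pairs per cell for the two monotonicity sweeps (s ∈
{0.5, 1, 2, 4} at log2FC = 1, and N ∈ {3, 6, 12} at log2FC = 1), compared
pairwise with one-sided two-proportion tests at α = 0.05. The acceptance
script uses 60 pairs per cell. These sizes are the package's chosen
trade-off between statistical resolution and turnaround.

## Numerical and design notes

- **Exhaustive enumeration** counts every distinct assignment of the label
  multiset once. For two equal groups the complementary assignment always
  produces the identical pseudo-F, so the smallest attainable exhaustive P
  is 2/C(n, n/2) — e.g. 2/20 = 0.1 at N = 3 per group, which makes the
  0.05-level call unattainable in that cell (its measured sensitivity is
  exactly 0; the monotonicity properties still hold).
- **cosθ exactness**: elementwise-equal (or negated) direction vectors
  short-circuit to exactly ±1, so comparing a dataset with itself reports
  cosθ = 1.0 exactly rather than 1 − ε from floating-point norms.
- **Self-comparison and the taxon null**: for ds2 literally identical to
  ds1, a taxon permutation rigidly rotates ds1's own configuration, and the
  scale-free pseudo-F of its projection back onto ds1's full PC span is
  distributed around the observed value — the taxon-matching test has, by
  design, no power against the identity comparison (there is no *specific*
  matching signal to detect beyond the shared geometry). Statistics that do
  flag the identity matching (e.g. projected between-group sums of squares)
  were evaluated and rejected: they also fire on dissimilar pairs that
  merely share noise geometry, collapsing specificity. Self-comparison is
  thus diagnosed via cosθ = 1 and the sample-level tests, while p2_taxon
  hovers near 0.5 — expected behavior, not a defect.
- **Taxon-null power grows with the taxon space**: the contrast between the
  observed and randomized matchings comes from how much geometry a random
  matching loses in projection (union size vs. PC span). With ~40 taxa and
  11 axes the null is nearly powerless; at 100–200 taxa it is sharp. Counts
  should be compared at a rank that retains a rich taxon space.
- **Degenerate inputs**: zero within-group scatter reports F = +inf (and
  only exact ties count against it); identical coordinates for all samples
  give F = 0 and p = 1; empty taxon intersections are allowed but logged,
  as is a single-sample group in the bootstrap.
- The BIOM reader mentioned alongside the TSV interface is not provided;
  count tables are plain TSV (first header cell `taxon_id`), chosen for
  unambiguous round-tripping of taxonomy strings.

## Limitations

- One ordered group pair per dataset per call; multi-group designs must be
  decomposed into pairs. No multi-factor PERMANOVA, no non-Euclidean
  dissimilarities, no strata.
- Exact string matching of taxon identifiers; nomenclature harmonization is
  the caller's responsibility (rank aggregation helpers are provided).
- P values from sampled permutations have resolution 1/(n_perm + 1);
  exhaustive mode bounds P below by 2/#assignments for equal two-group
  designs.
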