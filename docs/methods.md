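# Methods

This note records the models and procedures `plastphen` implements, the
assumptions behind them, and the choices made where the design was
genuinely open. Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

A measurement is the optical density (OD) of one protein band from one
Western-blot run of one tissue piece, already expressed relative to the
per-gel control sample (`normalize_to_gel_control` is provided for that
step when raw band densities are the input). The pipeline then:

1. **References to 5 wk normal.** Every protein column is divided by the
   mean of the reference condition (default `5wk_normal`), pooled across
   regions and runs, making the reference mean exactly 1 per protein. The
   pooling granularity (per region vs. pooled) is not dictated by the data
   model; pooled-per-protein is used because the downstream features are
   cross-regional, and the choice is recorded in the run manifest. The
   operation is idempotent and invariant to any global rescaling of the
   raw densities.
2. **Averages duplicate runs** with an unweighted arithmetic mean; a piece's
   protein cell is absent only when every run of that cell is absent.
3. **Assembles the matrix** at piece level (pieces, not runs, are the
   statistical units for PCA/clustering). Any piece with at least one
   absent protein is dropped and counted; the matrix reports
   rows × 7 = observations (e.g. 279 complete rows → 1,953 observations).

## Correlation networks

Per condition (regions pooled), all 21 protein pairs get a Pearson R and a
two-sided p-value (t transform, n−2 df, via `scipy.stats.pearsonr`).
Bonferroni correction uses the 21 pairs of one matrix — each condition's
panel is reported independently, so a per-matrix family is the natural
unit. Constant columns leave their pairs undefined (NaN) and excluded from
significance. Protein ordering is average-linkage hierarchical clustering
on distance 1 − R; undefined correlations enter the ordering as distance 1.

Leaf order is canonicalized by putting, at every merge, the subtree
containing the smallest original index first. Any left-right orientation
of a dendrogram is a valid seriation; this one makes the order a pure
function of the tree, so an all-ties input (identity correlation matrix)
keeps its input order.

## PCA and plasticity features

PCA is a plain column-centered SVD — no scaling, no rotation — matching
the view of a sample as a vector in 7-dimensional protein-expression
space. Variance fractions come from squared singular values; the test
suite checks them against an independent covariance-eigenvalue
decomposition at 1e-8. The SVD sign indeterminacy is fixed by making the
largest-magnitude entry of each basis vector positive. Per-protein cos²
(quality of representation) is the squared Pearson correlation between a
protein column and a score column; rows sum to 1 over the 7 dimensions,
with degenerate (zero-variance) score columns contributing 0 and constant
protein columns reported as missing.

The nine candidate features are three mean-scaled sums — all-protein sum
(÷7), GlutR sum (÷4), GABA_A_R sum (÷2) — and six indices (a−b)/(a+b),
bounded in [−1, 1] for nonnegative ODs. Index orientation follows the
defining formulas (e.g. the "GluN2B:GluN2A" band computes
(GluN2A − GluN2B)/(GluN2A + GluN2B), positive when GluN2A dominates); the
conventional names are kept as display labels only. Indices are invariant
to a global rescaling of the proteins; sums scale linearly.

Screening correlates each feature with Dim1–Dim3 of the sample-level
scores, Bonferroni-corrected over the 27 tests. A feature enters the
clustering input if at least one correlation survives; the E:I index
(GlutR sum vs GABA_A_R sum) is carried into the phenotype display
regardless, because the excitatory–inhibitory balance is central to
experience-dependent plasticity, but it stays out of the clustering input
when it fails screening.

## Clustering and subclusters

Features are z-scored before tSNE/k-means: the sums (≈1) and the indices
(∈[−1,1]) live on incompatible scales, and unstandardized Euclidean
distances would be dominated by the sums. tSNE uses perplexity 15 (suited
to n ≈ 110), 1,000 iterations, PCA initialization and a fixed recorded
seed; inputs with n ≤ 3·perplexity are rejected with the usable bound.

The number of clusters comes from the elbow rule: best-of-50-restarts
k-means WSS for k = 2..9, a least-squares fit of WSS(k) = A·e^(−k/τ) + C,
and k\* = round(4τ) (half-up; the rounding rule is recorded), clamped to
the scanned range. The elbow scan runs on the standardized features, not
on the tSNE coordinates: tSNE exaggerates cluster separation, making the
WSS curve collapse almost entirely at small k and biasing τ far below the
cluster count, while the feature-space curve decays smoothly on the scale
the rule presumes. The final k-means assignment runs on the 2D embedding
by default (configurable to feature space), with 50 k-means++ restarts and
labels canonicalized by descending cluster size. If the exponential fit
fails (non-decreasing WSS), the largest-second-difference elbow is used
and flagged.

Subclusters are pure bookkeeping on (condition × cluster) groups: qualify
at n ≥ 2 members and strictly more than 20% of the cluster. Labels carry a
region subscript (ordered C, P, M) when the group does not span all three
regions. Subcluster similarity is the Pearson correlation between mean
feature vectors over the screened features — with 8 features the p-values
have 6 degrees of freedom, a direct consequence of correlating
8-dimensional mean vectors — Bonferroni-corrected over C(m,2) pairs
(13 subclusters → 78 pairs → adjusted α ≈ 0.0006) and ordered by average
linkage on 1 − R.

## Phenotype bands and the bootstrap comparison

Sums map linearly to grayscale over [0, max across displayed groups]
(white → black); indices clip to [−1, 1] and map through a red–yellow–green
gradient (−1 red, 0 yellow, +1 green). The mapping is a pure monotone
function of the value.

Each (subcluster, feature) is tested against the reference group by the
bootstrap Monte-Carlo procedure: simulate a Gaussian population
(default 10⁶ points) from the subcluster's sample mean and SD, draw 10⁵
resamples of size n = the reference group's count, form two-sided
95/99/99.9% CIs of the resample means, and flag the feature with the most
extreme level whose CI excludes the reference mean. The reported direction
describes the subcluster relative to the reference. Multiple comparisons
are handled by tightening the nominal levels (0.05 → 0.05/T for T tests)
rather than widening fixed CIs — equivalent, and exactly reportable.

Two details deserve emphasis:

* **Which group anchors the simulation is underdetermined.** The procedure
  can equally be read as simulating from the subcluster and testing the
  reference mean, or the mirror image. Both conventions are implemented
  (`BootstrapConfig.convention`); the default simulates from the
  subcluster. Neither is asserted as the original intent.
* **The procedure is not calibrated at its nominal level.** The CI carries
  only the simulated group's sampling noise at size n; the tested mean's
  own sampling variability is ignored. For two groups of comparable size
  drawn from the same population, the null rejection rate at the nominal
  95% level is P(|Z| > 1.96/√2) ≈ 0.17, not 0.05 (slightly higher in
  practice because the simulated population uses the sample mean and SD).
  The test suite contains a calibration test that documents this
  miscalibration and fails at the nominal bound by design; it is a
  property of the procedure, not of the implementation. Detection of
  large planted shifts (≥3 pooled SD) is unaffected and verified at ≥95%
  power. Users comparing groups of similar size should treat the flags as
  anticonservative.

Degenerate inputs: a zero-SD simulated group reduces to an exact
comparison of means, flagged as degenerate.

## Receptor population decay kinetics

The model converts relative subunit expression into a predicted decay time
for the receptor population. With mature fraction a and immature fraction
b = 1 − a (computed as OD ratios a = OD_A/(OD_A+OD_B), so the model
depends only on the ratio):

* mixed pairs = min(a, b) — the dominant receptor species, limited by the
  scarcer subunit;
* the surplus |a − b| of the more abundant subunit is divided by 2 (two
  subunits per same-subunit receptor);
* the prediction is the τ-weighted average over the partition, with
  NMDAR constants (pair 50 ms, GluN2A-only 36 ms, GluN2B-only 333 ms) and
  GABA_A_R constants (pair 49 ms, α1-only 42.2 ms, α3-only 129 ms).

Algebraic simplification gives a continuous piecewise-linear function of
the immature fraction b — NMDAR: 36 + 28·b on [0, ½], 566·b − 233 on
[½, 1]; GABA_A_R: 42.2 + 13.6·g and 160·g − 31 — which the test suite
verifies against the implementation at 1e-9 on a 1,001-point grid. The
prediction is strictly increasing in the immature fraction and bounded by
the two pure-subunit constants. The published ± ranges on the constants
are treated as fixed; `KineticsParams` is a plain value object, so
sensitivity analyses can substitute alternatives. This is population
bookkeeping, not channel biophysics: it says nothing about individual
receptors.

Developmental/treatment trajectories are fit by nonlinear least squares:
single-exponential decay y0 + A·e^(−x/τ), or a 4-parameter logistic for
sigmoidal recovery, with R² and residuals reported and non-convergence
reported as no-fit rather than raised.

## Synthetic data generator

The generator emulates the study's structure, not its biology: per
condition, each (piece, run) record is an independent draw from a
multivariate Gaussian on the normalized-OD scale (mean vector, 7×7
correlation matrix, per-protein SD), truncated at 0 because ODs cannot be
negative. Covariance factorization uses an eigendecomposition so
zero-noise and rank-deficient specifications are exact. Missingness
removes an entire (piece, protein) cell — both duplicate runs — with
configurable probability, mirroring how single-cell dropouts arise in
blot data. A master seed fans out to per-condition substreams
(`numpy.random.SeedSequence.spawn`), so datasets are bit-reproducible and
adding a condition does not perturb the others.

The bundled layout has 113 pieces (5 wk normal 12, MD 15, RO 12, BD 14,
ST-BV 24, LT-BV 36) across the three V1 regions with duplicate runs, and
ships the per-protein measurement-count table whose GluN1 column sums to
222. Default per-protein noise SD is 0.10 on the normalized scale and the
default missing-cell rate is 0.005, which leaves roughly 109 complete
rows of 113 — chosen as a realistic dropout level for film densitometry.
The default planted effects encode the study's qualitative contrasts with
shifts of 3–7 noise SD (reference condition all 1.0; MD: GluN2A 0.55,
GluN2B 1.25, α1 1.35, cross-class correlations ≈ −0.1; RO: GluA2 1.6,
GluN2A 1.45; BD: α1 1.7, GluN2A 0.8, synapsin anticorrelated; LT-BV:
α1 0.6, α3 0.55, else near normal). A `development_effects` variant
provides maturational mean trajectories (saturating exponentials anchored
at 1.0 at 5 wks) for trajectory-fitting demonstrations.

What the generator does *not* emulate: gel-to-gel batch effects, film
saturation and background subtraction, antibody stripping efficiency,
within-animal correlation beyond the condition structure, and any
region-specific effect gradients. Passing tests therefore demonstrate the
pipeline's correctness and its ability to recover planted structure at
realistic noise, not the biological claims of any particular dataset.

## Problem sizes and tolerances used in the tests

The suite runs the full pipeline on the bundled 113-piece layout (≈110
complete rows). Monte-Carlo properties use 10 generator seeds for cluster
recovery (mean adjusted Rand index against the six planted conditions,
with k fixed at the planted count; k-selection is tested separately
against its ±1 contract), 100 replicates for planted-shift detection
power and 200 for null calibration, with bootstrap sizes reduced to
10⁵-point populations and 2,000–10,000 resamples — large enough that
Monte-Carlo error is small against the margins being tested while the
whole suite stays interactive. Exact identities use 1e-8 (PCA
reconstruction, cos² sums) or 1e-9 (kinetics closed form); statistical
assertions carry explicit Monte-Carlo slack.

## Known limitations

* The bootstrap comparison's anticonservatism (above) is inherited from
  the procedure's design; a two-sample test accounting for both groups'
  variances would be calibrated but would not be this procedure.
* The elbow rule's 4τ reference point presumes a WSS curve that is
  genuinely exponential-plus-floor; strongly separated or very flat
  structures push k\* to the clamp boundaries, and the second-difference
  fallback is a heuristic.
* Reference normalization pools regions; if regional baselines differ
  systematically, per-region normalization would change the features.
* The kinetics model ignores receptor species beyond the four modeled
  stoichiometries (e.g. GluN1-only assemblies) and assumes subunit OD is
  proportional to subunit copy number in membrane-inserted receptors.
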