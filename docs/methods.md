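# Methods

## Model

The core quantity is the cross-block covariance between an imaging block
`X` (subjects × features) and a clinical block `Y` (subjects × outcomes).
After removing nuisance covariates from both blocks by least squares
(intercept + age + gender + disease duration; gender coded 0 = male,
1 = female) and z-scoring every column (unbiased SD, ddof = 1 — stated
because z-scores differ slightly under the n convention), the method
performs an SVD of

    R = YᵀX / (n − 1),   R = V S Uᵀ,

with components capped at min(p, q) — in the target design q = 5 clinical
outcomes, so at most five latent variables. Column pairs (u_k, v_k) are
the imaging/clinical saliences, s_k the covariance captured, and
s_k²/Σs_j² the covariance-explained fraction (which by construction sums
to 1 over the full spectrum). Per-subject latent scores are X·u_k and
Y·v_k. Sign indeterminacy is resolved deterministically: the
largest-magnitude clinical salience of each LV is made positive.

Covariates are removed from **both** blocks. Removing them from only one
side leaves covariate variance in the other block's saliences; symmetric
removal is the conservative choice and makes the residual blocks
orthogonal to the covariate span.

## Permutation inference

Significance of each LV is assessed by permuting subject rows of the
clinical block with the imaging block fixed, re-running the chain, and
comparing each observed s_k against the permutation distribution of the
maximum singular value (max-statistic family-wise correction; a
`step_down`-free, strictly FWE-controlling choice). The p-value uses the
add-one estimator p = (1 + #{max s^perm ≥ s_k}) / (1 + P), so p ≥ 1/(P+1)
and p-values are monotone across LVs.

Naively permuting the *residualized* rows is anticonservative: after
regressing out an intercept and three covariates both blocks' residuals
lie in the same (n − 4)-dimensional subspace, and row permutation breaks
that shared alignment, systematically deflating the null singular values
(measured FWE ≈ 0.15 at α = 0.05, n = 35). The default scheme therefore
maps the residualized, standardized blocks into an orthonormal basis of
the covariate-orthogonal subspace and permutes there: the observed
statistic is unchanged (verified to machine precision) and the
transformed rows are exactly exchangeable under spherically symmetric
errors. Measured FWE on null cohorts with Gaussian outcomes is ≈ 0.05 at
α = 0.05. With strongly discretized or truncated outcomes (integer motor
scores clipped at 0 can place a point mass at −100% change) the
transformed-basis test becomes mildly *conservative* (≈ 0.01–0.03), never
anticonservative; `permute="raw"`, which re-runs covariate removal on
raw permuted rows, stays closer to nominal in that regime and is
available as a config switch.

## Bootstrap salience ratios

Subjects are resampled with replacement; each resample re-runs
residualize → z-score → SVD. Resampled saliences are aligned to the
original by an orthogonal Procrustes rotation computed on the
singular-value-weighted clinical saliences (V·diag(s)) and applied to
both blocks. The weighting matters: with q = 5 outcomes and 5 components
the resampled V spans the entire outcome space, so an unweighted
Procrustes would rotate it *exactly* onto the original — zero apparent
bootstrap variance. Weighting by the singular values anchors the
alignment to the data and leaves genuine resampling variability intact.

The bootstrap ratio of a salience is its original value divided by its SE
across resamples (a pseudo-z); 95% percentile CIs flag features whose
interval excludes zero as robust. Resamples whose duplicated subjects
produce collinear covariates fall back to centering-only removal, and
columns that come out constant are recentered; both are counted and
reported.

Feature selection takes the top ⌈fraction · p⌉ features by |bootstrap
ratio| (default fraction 0.05 — for 416 features exactly 21), breaking
ties deterministically by column order, then by default intersects with
the robust set. Modality contributions aggregate |bootstrap ratio| over
each modality's selected features and normalize across modalities to sum
to 1 (a modality with no selected features scores exactly 0);
`contribution="mean"` aggregates by within-modality mean instead — the
two orderings coincide when selected counts per modality are equal.

## Regional imaging features

- **Conditioning**: the first 10 volumes are dropped (unstable signal),
  then each voxel is projected in one least-squares step onto
  [intercept, linear ramp, confounds], so constants, linear trends and
  exact confound copies leave zero residual. Band-pass filtering
  (0.01–0.08 Hz, ideal frequency-domain filter — the band is specified,
  the filter shape is a package choice; edge bins are included when their
  center frequency lies in the closed band) is applied only where the
  caller asks for it.
- **fALFF** is the sum of spectral amplitudes (square roots of
  periodogram power) inside 0.01–0.08 Hz over the sum across all positive
  frequencies. It is computed on conditioned but **unfiltered** data: on
  band-limited data the ratio is identically 1. Whether the original
  pipeline ordered these two steps this way is not documented; users who
  band-pass upstream will see saturated values, and the docstrings warn
  about it. For an identically-zero series the defined sentinel 0 is
  returned.
- **ReHo** is Kendall's coefficient of concordance W = 12S/(K²(t³−t) −
  KΣT_j) with the standard tie correction, over each voxel's ≤27-voxel
  cubic neighbourhood (in-bounds neighbours at edges), computed on
  band-passed data; regional ReHo is the mean of voxel-wise W within the
  region (whether the original computed mean voxel-wise W or one joint W
  per region is not documented; mean voxel-wise is implemented). If every
  series in a neighbourhood is constant the statistic is degenerate and 1
  is returned with a warning.
- **Density/atrophy** summaries are per-region means of caller-supplied
  voxel maps (gray-matter probability, Jacobian determinant). Deformation
  fields, registration and segmentation are out of scope — inputs are
  assumed pre-aligned; no world-coordinate resampling is done.
- **Treated-side mirroring**: right-treated subjects' lateralized L/R
  column pairs are swapped and all columns relabeled treated-side (TS) /
  untreated-side (US); midline regions (e.g. cerebellar vermis) pass
  through with side `mid`, since they have no homologue. The operation is
  an involution on values.

## Clinical statistics

Outcomes are per-subject percent changes (m4 − b)/b × 100 (negative =
improvement). Summaries report the mean of per-subject ratios, not the
ratio of visit means — the two differ whenever baselines vary. A zero
baseline makes the cell undefined: it is set missing with a warning and
excluded pairwise, with a count column in the report. Paired t-tests use
df = n − 1; zero-variance differences are flagged rather than raising.

## Synthetic cohorts

The generator produces the data model the analysis assumes:

    X = Σ_k s_k t_k u_kᵀ + covariate effects + ε,
    Y = Σ_k s_k t_k v_kᵀ + covariate effects + ε,

with latent scores t_k ~ N(0,1) per subject, unit-norm saliences and
isotropic Gaussian noise — the minimal model under which PLS-SVD is the
natural estimator. Default imaging saliences put exact zeros on half the
columns (`imaging_salience_density = 0.5`), giving known null features
for CI-coverage checks. Defaults mirror the target study: 35 subjects,
104 regions (70 cortical, 16 subcortical, 18 cerebellar — 8 lateralized
cerebellar pairs plus 2 midline vermis labels) × 4 modalities = 416
features, 16/35 right-treated, age 56.6 ± 9.5, 22 male / 13 female,
duration 7.2 ± 2.8 years.

The standardized blocks are mapped to measurement scales: positive
offsets/scales for fALFF (0.30/0.02), ReHo (0.50/0.03) and density
(0.60/0.04), a negative offset for atrophy (−0.50/0.04) so those values
stay ≤ 0. Scales are ~12σ from the sign boundary, so clipping is
essentially inactive. Clinical integer scores are drawn around the study
baseline distributions (total 37.6 ± 8.0, treated side 18.8 ± 3.7,
rigidity 3.5 ± 1.0, akinesia 10.0 ± 2.7, tremor 5.3 ± 2.5; minimum 1 so
percent change is defined), and month-4 scores are baseline × (1 +
pct/100) rounded and clipped at 0, with pct the planted continuous
outcome centred on −40/−57.7/−58/−47.1/−74 with SDs 18/19/30.7/27.4/30.5.
Month-4 imaging drifts from baseline along a second latent-linked
direction with small noise (`change_drift_strength = 0.8`,
`change_noise_sd = 0.3`), so the changes analysis has recoverable
structure with realistically small change variance.

Two consequences matter for interpreting tests:

1. Column z-scoring rescales planted directions, so the recoverable
   population saliences are u_j/sd_j (renormalized), not u itself. The
   generator records both; recovery checks compare against the
   standardized-scale truth obtained by SVD of the analytic population
   cross-covariance.
2. Integer rounding and clipping of scores at 0 truncate extreme planted
   improvements (tremor's −74% mean puts mass below −100%). Recovery and
   calibration checks therefore use the planted continuous percent
   changes; the discretized path is exercised by the clinical-statistics
   and end-to-end tests.

What the generator does **not** emulate: spatial autocorrelation between
regional features, heteroscedastic or heavy-tailed noise, site/scanner
effects, registration error, lesion geometry, or item-level UPDRS
structure. Passing tests show the estimator and its inference behave
correctly under the assumed low-rank Gaussian data model at the study's
dimensions — not that real trial data satisfy that model.

Voxel test blocks mix one in-band (0.04 Hz) and one out-of-band (0.15 Hz)
sinusoid per voxel, a grid-shared component weighted by
`neighbor_coupling`, white noise, and six random-walk motion-like
confounds; 450 volumes at TR = 2 s by default.

## Problem sizes and numerical choices

The test-suite simulations use sizes chosen to make the statistical
assertions sharp at interactive runtimes: SVD-oracle agreement on 50
random 35-subject problems (tolerance 1e−8), calibration over 200 null
cohorts × 200 permutations (exact binomial 95% envelope [0.022, 0.089]
around α = 0.05), recovery over 50 planted cohorts at n = 200 with
planted strength 7 (placing s₁ ≈ 3.2–3.7× the null 95th percentile),
bootstrap B = 200 there, and fALFF/ReHo null means over 2000 × 440-sample
and 120 × (27 × 440) draws. The acceptance script uses 500
permutations/bootstraps for the headline cohort and scaled replicate
counts; all randomness flows from a single seed through independent child
streams, so permutation results do not change when the bootstrap count
does.

Degenerate inputs: constant columns abort standardization with the column
named (except inside bootstrap resamples, where they are recentered and
counted); rank-deficient covariates abort with the collinear columns
identified; a band edge at or above Nyquist aborts naming the TR and
limit; empty regions yield missing values with a warning.

## Known limitations

- In-sample association only: no cross-validated prediction, no sparse or
  regression-flavoured PLS variants.
- Percentile bootstrap CIs at B in the hundreds are slightly
  anticonservative; zero-salience features' CIs cross zero at ≈ 91–95%
  rather than a nominal 95%.
- The exact-exchangeability argument for the default permutation scheme
  assumes spherically symmetric residuals; heavy discretization shifts it
  conservative (see above).
- Regional ReHo is O(voxels × 27 × t log t); the pure-Python voxel loop
  is adequate for the small grids used here, not for whole-brain volumes.
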