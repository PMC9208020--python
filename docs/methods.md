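# Methods

## The model

Functional connectivity (FC) at a single connection (edge) of a
parcellated connectome, measured in one brain state, is treated as an
observed indicator of an unobserved, state-general latent connectivity.
For subject *i*, state *s*, edge *e*:

    y[i,s,e] = λ[s,e] · η[i,e] + ε[i,s,e]

with standardized indicators, so λ is the loading in correlation units
and the uniqueness is 1 − λ².  One single-factor model is fit per edge,
independently, over subjects × states.  Assumptions: linearity, a single
common factor per edge, Gaussian-like indicator distributions, and
between-subject independence.  Nothing couples edges to each other; this
is a deliberately simple measurement model per connection, not a
network-generative model.

The cross-state **average** is the restricted special case λ ≡ 1, ε ≡ 0,
whose factor score is the arithmetic row mean.  The free model tests the
average's assumption (equal positive loadings) instead of imposing it;
when generating loadings are equal, free scores converge to the average
(the suite checks r > 0.99 at N = 2000).

## Fitting

- **Extraction**: minimum-residual (minres) by default — minimize the
  sum of squared off-diagonal residuals of R − λλ′ with
  `scipy.optimize.least_squares`, analytic Jacobian, bounds
  |λ| ≤ √(1 − 0.001).  Gaussian ML (discrepancy
  log det Σ + tr(RΣ⁻¹) − log det R − S under ε = 1 − λ²) is available via
  `method="ml"` and agrees with minres to ~1e−3 on well-conditioned
  population matrices; it is cross-checked against R's `stats::factanal`
  in the suite.
- **Initialization**: √SMC (squared multiple correlation,
  1 − 1/(R⁻¹)ᵢᵢ) signed by the first eigenvector.  This matters: the
  minres objective for independent indicators has degenerate single-spike
  optima (one |λ| large, rest 0 fits a noisy near-identity matrix
  perfectly well); SMC starts at exactly 0 there and stays at the null
  solution for the population identity.
- **Convergence**: step/gradient tolerance 1e−12, cap 1000 evaluations.
  Non-converged fits are returned flagged with a warning, not discarded.
- **Identification**: S ≥ 3 indicators required; S = 2 is refused (the
  model is unidentified).  Sign convention Σλ ≥ 0.
- **Heywood cases**: uniquenesses are floored at 0.001 (loadings bounded
  at √0.999) and flagged; this keeps score weights finite.
- **Scores**: Thurstone regression method, W = R⁻¹λ on the *observed*
  indicator correlation matrix, applied to column-standardized
  indicators, then re-standardized to mean 0, sd 1.  Singular R falls
  back to a ridge-stabilized inverse (jitter 1e−8, logged).
- **Edgewise pipeline**: edges are fit independently (order-invariant,
  trivially parallel).  Edges whose fit fails (zero variance, numerical
  failure) fall back to the restricted average score and are flagged;
  counts are logged.  Leave-one-state-out estimation drops the held-out
  slice *before* any computation, so LOSO scores are provably independent
  of the held-out state's values.

### Group-level latent matrix

Regression scores are standardized within sample, so their per-edge mean
is identically zero and carries no group information.  The group latent
matrix therefore uses, per edge, the normalized score-weight combination
of the states' group-mean indicators, w̃ = W/ΣW applied to the state
means.  Under equal loadings this reduces exactly to the group average
matrix, consistent with the near-equivalence of latent and average FC
when loadings are uniform.

## Preprocessing designs

The nuisance design has 64 columns in a fixed order: 6 motion
parameters, their temporal derivatives, and the quadratics of those 12
(24), then 5 white-matter + 5 ventricle aCompCor components, their
derivatives, and the quadratics of those 20 (40).  Derivatives are
backward first differences with a leading zero (length-preserving, the
common fMRI convention); quadratics are computed after derivative
assembly so the 24/40 split holds by construction.  The FIR task design
allocates, per condition, one indicator column per post-onset offset up
to the maximum block duration plus 25 lag columns; blocks of a condition
pool into the same columns, and entries past the run end are simply
absent (columns are retained).  TR indexing is 0-based with half-open
blocks [onset, onset+duration).  Residualization is plain OLS per
region, optionally with intercept + linear trend prepended; it is a
projection (idempotent to 1e−10) and rank-deficient designs use the
pseudoinverse with a logged warning.  Frame removal at run start is a
separate convenience (`drop_initial_frames`), treated as upstream of the
design stage.

## FC estimation and TR matching

Pearson correlation over timepoints, with runs of the same state
concatenated (never averaged — no Fisher transform enters within-subject
estimation).  Edges use one convention everywhere: strict upper
triangle, row-major, 0-based; 360 regions give 64,620 edges.  TR budget
matching keeps 2,112 rest TRs and 264 TRs per task (eight tasks again
total 2,112) by **first-N selection in scan order** — the deterministic
choice; a seeded random selection could be added but determinism was
preferred for reproducibility.

## Synthetic data

The generator draws η ~ N(0,1) per subject × edge and builds indicators
with exact variance split λ² + (1−λ²); loadings may be scalar, per-state,
or per-state-per-edge.  All noise is Gaussian — the matching choice for
a linear factor model and the only distribution in v1.  A single integer
seed expands into fixed substreams (latent scores; one per state;
behavior; g) so adding states never perturbs earlier draws.  Time series
are multivariate Gaussian with the target correlation factorized by
eigendecomposition; there are no hemodynamics, autocorrelation, or
motion artifacts, so passing tests demonstrate statistical correctness
of the estimators, not robustness to fMRI noise structure.  Activations
solve (I − W)a = s with W the zero-diagonal connectivity (rescaled to
spectral radius 0.9 when needed, logged), which makes the activity-flow
prediction error *exactly* the injected input — an algebraic identity
the suite checks to 1e−10.  Behavior couples g to the first 10% of edges
with unit weights at correlation `coupling_strength` (default 0.5);
measures load on g with uniqueness 1 − loading² by default.

## Data-quantity experiment

`experiments.data_quantity_experiment` gives every state a subject's
*identical* intrinsic correlation matrix (edges at 0.3 ± 0.1·η, nearest-
correlation repaired), scans rest 8× longer than each 264-TR task,
estimates FC from the simulated series, and fits the edgewise factor
model.  With 60 subjects and 8 regions the rest loading sits ~0.1 above
the task loadings purely because of its lower estimation noise; matching
every state to 264 TRs (first-N masks) shrinks the gap to <0.01.  This
is the mechanism behind resting state's loading advantage evaporating
under TR matching: precision, not privileged physiology.  Problem sizes
(60 × 9 states × ≤2,112 TRs × 8 regions) were chosen to make the effect
unambiguous while the whole experiment runs in seconds.

## Inference

- Similarity of two connectomes: Pearson r over upper-triangle edges,
  per subject; paired t tests on Fisher-z similarities across subjects,
  BH-FDR across held-out states.
- Pooling of correlations across subjects is always
  **estimate-then-average**: per-subject r → atanh → mean → tanh.  The
  suite asserts this differs from correlating averaged matrices.
- Two dependent overlapping correlations (two predictors, one outcome,
  one sample): Hittner–May–Silver back-transformed-average-z statistic;
  Steiger's simple-average variant by flag.  Two-tailed by default with a
  one-tailed flag.  Type-I error is calibrated at 0.05 ± 0.01 under a
  trivariate Gaussian null (10,000 reps, n = 176).
- Meta-analysis across independent samples: z̄ = Σwᵢzᵢ/Σwᵢ with wᵢ the
  sample size; significance via χ²(1) = z̄²Σw (the pooled z has variance
  1/Σw under the null).  The χ² form is an explicit, swappable choice —
  the weighted-mean formula itself admits several tests.
- FDR is Benjamini–Hochberg (via statsmodels), inclusive-threshold
  loading summaries (λ = 0.4 counts as ≥ 0.4).
- Undefined correlations (zero-variance units) propagate as missing and
  are excluded from t tests with logged counts — never silently zero.

## Behavior prediction

g is a single-factor model over ≥3 cognitive measures (the default
configuration names the standard 11-measure battery with polarity;
reaction-time measures are sign-flipped before fitting).  Prediction is
between-sample cross-validation: factor models for FC features and for g
are fit within each split separately; ridge (penalty grid 10⁻³…10⁵,
5-fold CV inside the training split; features standardized by training
statistics only) trained on one split predicts the other.  No quantity
derived from a split's outcomes enters that split's predictions — the
suite corrupts one split's outcomes and asserts bit-identical
predictions.  Accuracy is r and R² = r² per split and pooled; feature-set
differences use the dependent-correlation test per split and the
weighted-z pooling across splits.

## Known limitations

- One factor per edge, no cross-edge structure, no rotations or fit
  indices; multi-factor variants are out of scope.
- The synthetic generator's realism stops at the linear-Gaussian factor
  structure; conclusions about real fMRI noise, motion, or hemodynamics
  are out of reach by design.
- The group latent matrix's scale is a convention (see above), not an
  estimated quantity.
- Tests involving Monte Carlo use fixed seeds; tolerances state the
  sampling slack explicitly rather than hiding it.
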