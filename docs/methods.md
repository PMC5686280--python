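# Methods

## The problem

Point estimates of a nonlinear mixed-effects model (NLMEM) — fixed effects,
inter-individual/inter-occasion variances, residual variances — come with
uncertainty that practitioners usually summarize with an asymptotic
covariance matrix, a case bootstrap, or a parametric bootstrap (stochastic
simulation and estimation, SSE). The asymptotic covariance imposes a
symmetric multivariate normal shape; the bootstraps are expensive and can
behave badly at small subject counts. Sampling importance resampling (SIR)
sits between the two: it reweights cheap draws from a parametric proposal by
the actual likelihood of the data, so the resulting parameter vectors
reflect the true, possibly asymmetric, uncertainty without any
re-estimation.

## The procedure

One SIR iteration:

1. **Sample.** Draw `M` parameter vectors from a parametric proposal
   distribution (multivariate normal built from a covariance matrix, or
   multivariate Box-Cox fitted to a set of vectors). Draws violating
   parameter bounds (e.g. negative variances) are rejected and redrawn;
   clipping is never used because it would place probability atoms on the
   bounds and corrupt the density ratios.
2. **Weight.** For each vector compute the importance ratio

   `IR = exp(-dOFV/2) / relPDF`

   where `dOFV` is the vector's objective function value (OFV,
   −2·log-likelihood up to a constant) minus the OFV at the final estimates,
   and `relPDF` is the proposal density at the vector divided by the
   proposal density at the final estimates. The numerator is the likelihood
   ratio of the data; the denominator removes the proposal's own
   preferences. Computation is done in log space.
3. **Resample.** Draw `m < M` vectors with probabilities proportional to IR,
   sequentially and without replacement, retaining the draw order. The
   implementation uses exponential race keys (sort by `Exp(1)/w`), which is
   distributionally identical to renormalized sequential draws and
   `O(M log M)`; it is verified against brute-force enumeration in the test
   suite.

The automated procedure iterates, fitting a multivariate Box-Cox proposal to
each iteration's resamples, with the default schedule `(M, m)` =
(1000, 200), (1000, 400), (1000, 500), then (2000, 1000) repeating. High
`M/m` ratios early move the proposal quickly at low cost; the final ratio of
2 gives a precise estimate. Iteration stops when the resample dOFV
distributions of two consecutive iterations are overlaid up to sampling
noise (below), or at `max_iterations` (default 15). A df trajectory that
keeps crossing itself with changes above tolerance is reported as
`oscillating` rather than converged.

### Initial proposal and inflation

The first proposal is, in order of preference: the model's covariance matrix;
a Box-Cox fit to a limited bootstrap (~200 vectors); or a generic diagonal
normal with class-specific relative standard errors — 30% on fixed effects,
50% on inter-individual and inter-occasion variabilities, 10% on residual
variabilities, no correlations (correlation-class parameters, for which no
convention exists, are treated like fixed effects at 30%).

If the first proposal's dOFV curve lies below the chi-square reference
(underestimated uncertainty — SIR shrinks distributions far more easily than
it widens them), all variances and covariances are multiplied by successive
ladder factors (default 1.5, 2, 3, i.e. cumulative totals 1.5, 3, 9) until
the curve clears the reference; an exhausted ladder aborts with a
diagnostic. The check is applied only to the first proposal; later
iterations are entrusted to the Box-Cox refit.

### The multivariate Box-Cox proposal

Each parameter is transformed by `z_k = ((x_k + s_k)^λ_k − 1)/λ_k` (log for
`λ_k = 0`) and `z` is modelled as multivariate normal, so correlations are
linear on the transformed scale and each margin interpolates between
symmetric (`λ ≈ 1`) and log-normal-like right-skew (`λ ≈ 0`) — the shape
variance parameters typically show. Shapes are per-parameter
profile-likelihood estimates (grid on [−2, 2] plus bounded local refinement,
using the standard Box-Cox log-likelihood); shifts are 0 for all-positive
margins and `−min + 0.1·range` otherwise, so sign-indefinite fixed effects
are supported. Fixed shapes per parameter class (e.g. 1 for fixed effects, 0
for random-effect variances) can be supplied, in which case only the moments
are fitted. Densities include the Jacobian `Π_k (x_k + s_k)^(λ_k − 1)`;
relPDF uses the untruncated density ratio, consistent with ratio-based
weighting, and vectors outside the support get relPDF 0 and are excluded
from resampling (their importance ratio is undefined; exclusion is
conservative). An optional cap shrinks transformed-scale correlations that
exceed a threshold (default cap 0.95, off by default). Shape identifiability
degrades as a margin's coefficient of variation shrinks: at CV ≈ 0.1 the
profile MLE of λ has a spread of roughly ±0.4, which is harmless for
sampling (the implied distributions are nearly identical) but should temper
any interpretation of fitted shapes.

## Diagnostics

All diagnostics read the dOFV distribution. If the resamples represent the
true uncertainty, their dOFV should follow a chi-square with degrees of
freedom (df) at or below the number of estimated parameters `k`.

- **df estimate**: maximum likelihood for a chi-square (gamma with shape
  df/2, scale 2), solved by root finding on the digamma score equation.
  Negative dOFVs (Monte-Carlo noise, local minima) are clipped to zero and
  counted; exact zeros carry no information for the log-based score and are
  dropped with a count.
- **dOFV curves**: empirical quantiles at percentiles 1–99 (type-7
  interpolation), against the exact chi-square(k) reference curve.
- **Noise envelope**: the weighted resampling is replayed `B` times (default
  200) with child seeds; the per-percentile 95% interval of the replicate
  quantile curves is the sampling-noise band.
- **Convergence**: the previous iteration's resample curve must lie inside
  the current iteration's envelope at ≥ 70% of percentiles in the 5–95 band.
  The envelope used for the decision is built at the previous curve's
  resample size — the hypothesis is that the previous curve is one
  resampling of its size from the current weighted sample. The 70% fraction
  was calibrated so that two independent resamplings of one weighted sample
  are accepted at ≥ 90% of seeds (quantile curves are strongly correlated
  across percentiles, so a single excursion pushes long runs outside a
  pointwise envelope; 90% containment rejects about a quarter of genuinely
  equivalent pairs), while curves shifted by 10× the envelope width are
  rejected at 100% of seeds.
- **Underestimation**: the proposal curve counts as below the reference at a
  percentile only when under `(1 − 0.05)·ref`; the proposal is flagged when
  this holds at > 50% of percentiles in the 10–90 band. The 5% margin exists
  because an exactly matched proposal would otherwise be flagged on a coin
  flip.
- **Temporal trends**: the resampling sequence is split into 5 consecutive
  bins and the per-bin fraction of draws from the top IR quintile (by rank,
  robust to ties) is tracked. Depletion — the signal that `M` should be
  increased — is declared when the fraction decreases significantly, testing
  both a Mann-Kendall trend across bins (gradual depletion) and a
  first-vs-last-bin two-proportion drop (abrupt exhaustion by a few dominant
  weights), each one-sided at α/2.
- **Local minima**: any sampled vector whose dOFV is below −0.1 triggers a
  warning and is recorded so the user can re-estimate from it; the reference
  OFV is never silently re-anchored.

## Built-in models and fixtures

The engine only requires an OFV evaluator (deterministic, −2·log-likelihood
up to a shared constant; the full `n·log 2π` term is included so oracle
comparisons are exact). Three built-in families make the workflow fully
testable offline:

- **Conjugate normal means** (`conjugate_toy`): 5 independent group means
  with known unit variance, 50 observations per group. The estimator's
  sampling covariance is exactly `diag(σ₀²/n)` and dOFV is an exact
  quadratic form, so a proposal equal to the sampling distribution yields
  identically flat importance weights and a chi-square(5) dOFV — the
  analytic anchor for the end-to-end pipeline.
- **Random-intercept linear model** (`linear_mixed_small`, 20 subjects × 4;
  `linear_mixed_large`, 200 × 4): exact marginal likelihood via the
  Sherman-Morrison identity on the compound-symmetric covariance, verified
  against a dense multivariate-normal oracle. Truth: intercept 10, slope 2,
  between-subject variance 1, residual variance 0.5 — moderate variability
  at a subject count where asymptotics hold (large) or do not quite
  (small).
- **One-compartment oral PK** (`onecomp_pk_sparse`): 30 subjects × 3
  samples, dose 100, ka 1.5 fixed, CL 5, V 50, 30% CV log-normal IIV on CL
  and V, proportional residual error (σ² = 0.01). The marginal likelihood
  integrates two random effects per subject by a Laplace approximation at
  the empirical-Bayes mode; adaptive Gauss-Hermite quadrature (9 nodes per
  axis) is available as a cross-check and agrees within 2% of OFV on
  designs with ≥ 6 observations per subject. On very sparse designs the
  total OFV can sit near zero (an artifact of the additive constant), which
  makes relative OFV comparisons ill-conditioned even though the absolute
  Laplace error is unchanged (~0.03 per subject).

Estimation for the built-in models minimizes the OFV with L-BFGS-B under the
parameter bounds; the asymptotic covariance is the pseudo-inverse of the
numeric central-difference Hessian of OFV/2, with a sandwich option
(`H⁻¹·Σ gᵢgᵢᵀ·H⁻¹` over per-subject scores). At boundary optima (a variance
estimated at ~0) the curvature is uninformative and the covariance is
returned as NaN with the estimates intact. Non-convergence returns the
best-found vector with a flag rather than raising, so bootstrap/SSE
replicates are retained regardless of termination status (only non-finite
results are dropped, with a count).

What the fixtures do **not** emulate: model misspecification (the simulator
and the estimation model always coincide, so case bootstrap and SSE agree
here by construction), categorical or time-to-event endpoints, ODE
dynamics, inter-occasion variability blocks, parameter correlations in the
truth, and estimation-software quirks (boundary estimates, non-positive-
definite covariance steps). Passing tests therefore demonstrate the
correctness of the SIR machinery, not the field performance of any
particular model family.

## Comparator methods and metrics

`cov_uncertainty` (multivariate normal draws truncated to bounds by
rejection), `case_bootstrap` (subjects resampled with replacement to the
original count, re-estimated), and `sse` (datasets simulated from the fitted
model on the original design, re-estimated) all produce 1000-vector sets by
default, interchangeable with SIR resamples. Metrics per parameter:
RSE = 100·SD/|estimate|; empirical 95% CI (2.5/50/97.5 percentiles, type-7);
relative width = (upper − lower)/estimate; asymmetry = (upper − median)/
(median − lower); plus the chi-square df of the set's dOFV distribution
normalized by `k`. Per-model summaries take medians over parameters
(magnitudes for relative width).

## Numerical conventions and degenerate inputs

- Seeds: one master seed; child generators derived via `SeedSequence`
  spawn keys indexed by (iteration, purpose), so any single iteration is
  independently reproducible.
- Slightly indefinite covariance inputs are repaired to the nearest PSD
  matrix by eigenvalue clipping, with a warning.
- OFV evaluation failures at extreme vectors become IR = 0 with a count;
  more than 20% failures aborts the run. Rejection rates above 50% while
  sampling abort (the proposal is grossly misplaced relative to the
  bounds).
- Degenerate Box-Cox margins (zero spread) get shape 1 and zero variance,
  flagged. Generic RSEs cannot be formed for zero-valued estimates; an
  explicit covariance is required instead.
- `resample` requires at least `m` vectors with positive IR; otherwise it
  aborts advising a larger `M` or inflation.

## Known limitations

- The Laplace approximation is the only likelihood available for the
  nonlinear built-in; its (small, tested) bias is assumed orthogonal to SIR
  behavior.
- The convergence rule is a numeric operationalization of a visual
  criterion; its thresholds are package conventions calibrated by
  self-consistency, not field standards.
- The inflation ladder multiplies cumulatively (totals 1.5, 3, 9 by
  default); severely underestimated proposals beyond a factor ~9 require a
  user-supplied wider proposal or a longer ladder.
- With-replacement resampling is available but disables the temporal-trends
  diagnostic, which needs the depletion structure of without-replacement
  draws.
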