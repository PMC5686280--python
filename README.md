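# sirnlme

Automated, iterative **sampling importance resampling (SIR)** for estimating
parameter uncertainty in nonlinear mixed-effects models (NLMEM), with its
dOFV diagnostics, multivariate normal and multivariate Box-Cox proposal
machinery (including inflation of underestimated proposals), comparator
methods (covariance matrix, case bootstrap, SSE/parametric bootstrap), and
confidence-interval summary metrics — all runnable offline through built-in
synthetic models with tractable likelihoods, or against any user-supplied
objective-function evaluator.

## The method

For a fitted model with final estimates θ̂, SIR approximates the parameter
uncertainty distribution in three steps:

1. sample M parameter vectors θ₁…θ_M from a parametric proposal
   distribution (e.g. the multivariate normal implied by the covariance
   matrix);
2. weight each vector by its importance ratio

   IR = exp(−dOFV/2) / relPDF,

   where dOFV = OFV(θ) − OFV(θ̂) (OFV being −2·log-likelihood up to a
   constant) and relPDF is the proposal density at θ relative to the
   density at θ̂;
3. resample m < M vectors with probabilities proportional to IR,
   sequentially and without replacement.

The procedure iterates automatically: each iteration's resamples are fitted
with a multivariate Box-Cox distribution (per-parameter shape λ_k, so
margins range from symmetric to log-normal-like) that serves as the next
proposal, until the resample dOFV distributions of two consecutive
iterations are overlaid up to sampling noise. A first proposal whose dOFV
distribution lies below the χ²(k) reference (k = number of estimated
parameters) signals underestimated uncertainty and is inflated — all
variances and covariances multiplied by ladder factors — before iterating.
If the resamples represent the true uncertainty, their dOFV follows a χ²
with degrees of freedom ≤ k; the fitted df is the main adequacy diagnostic.

See `docs/methods.md` for the full account: proposal fitting, convergence
and underestimation rules, the temporal-trends (depletion) diagnostic,
local-minimum warnings, and the built-in model families.

## Worked example

Uncertainty for a random-intercept linear mixed model (200 subjects × 4
observations; truth: intercept 10, slope 2, between-subject variance 1,
residual variance 0.5), starting SIR from the model's own asymptotic
covariance matrix:

```python
import numpy as np
import sirnlme as s
from sirnlme import proposal as prop

fx = s.make_fixture("linear_mixed_large", seed=1)
fit = s.estimate_parameters(fx.model, fx.data)
print("estimates:", dict(zip(fx.model.spec.names, np.round(fit.estimate.values, 3))))

initial = prop.from_covariance(fit.estimate, fit.covariance)
res = s.run_sir(fx.model, fx.data, initial,
                config=s.SirConfig(master_seed=14), reference_ofv=fit.ofv)
print("status:", res.status, "| iterations:", res.n_iterations,
      "| inflation:", res.inflation_applied)
final = res.final
print("df:", round(final.df_resamples.df, 2),
      "| normalized df:", round(final.df_resamples.normalized_df, 3))

from sirnlme.summaries import rse
r = rse(res.final_resamples, fit.estimate.values)
for name, val in zip(fx.model.spec.names, np.round(r, 2)):
    print(f"RSE[{name}] = {val}%")
```

prints

```
estimates: {'theta1': 9.895, 'theta2': 1.997, 'omega2': 0.86, 'sigma2': 0.5}
status: converged | iterations: 2 | inflation: 1.0
df: 4.0 | normalized df: 1.0
RSE[theta1] = 0.81%
RSE[theta2] = 1.12%
RSE[omega2] = 11.64%
RSE[sigma2] = 5.65%
```

The run converged in two iterations with no inflation needed (the
asymptotic covariance is a good proposal at this subject count), and the
resamples' dOFV distribution has df ≈ 4 with 4 estimated parameters — an
adequate uncertainty estimate. The fixed effects are known to within about
1%, the between-subject variance — the hardest parameter — to about 12%.

The same workflow is available from the shell:

```
sir fixtures make linear_mixed_large --seed 1 --out data/
sir run run.yaml --out results/          # YAML config: fixture, schedule, seeds
sir diagnose results/samples_1.csv --m 200 --k-params 4
sir compare --runs sir=results/final_resamples.csv --estimates est.csv
```

`sir run` writes per-iteration samples tables (parameters, ofv, dofv,
relpdf, ir), resamples tables with draw order, a df-per-iteration summary,
and the final resamples; `sir diagnose` emits the tidy percentile/curve/
envelope table behind the dOFV plot.

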