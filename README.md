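# virtuallux

Virtual melatonin-suppression experiments: a stochastic population model of
individual light-sensitivity dose-response curves, with Monte-Carlo power
analysis for laboratory study designs.

## The problem

Evening light suppresses nocturnal melatonin secretion, and individuals
differ enormously in how sensitive they are — the most sensitive people can
respond to light levels tens of times dimmer than the least sensitive.
Laboratory melatonin-suppression experiments are expensive (multi-hour
evening protocols, repeated saliva assays), so experimenters need principled
power calculations that take this individual variability seriously.
`virtuallux` simulates whole *virtual experiments* — sampling virtual
participants from a fitted population model and measuring them with a
realistic noise process — and estimates statistical power for a planned
design by Monte Carlo.

## The model

Each individual *i* has a two-parameter logistic-type dose-response curve on
the log-illuminance axis:

    s(x) = 1 − 1 / (1 + (log10(x) / a_i)^b_i),        x ≥ 1 lux

where `a_i = log10(ED50_i)` (ED50 = illuminance giving 50% suppression) and
`b_i > 0` is the curve shape.  The population model is fitted to a table of
raw per-individual estimates `(a_i, b_i, RMSE_i)`:

* the marginal distribution of `a` is a kernel density estimate, sampled by
  inverse transform;
* the conditional distribution of the shape is a Bayesian heteroscedastic
  regression `log b_i ~ normal(α + β a_i, σ0 + σ1 a_i)` with priors
  α, β ~ normal(0, 1) and σ0, σ1 ~ half-Cauchy(0, 1), fitted by MCMC
  (4 chains × 4000 iterations, 2000 warm-up, thinned by 2; convergence gate:
  rank-normalized split R-hat < 1.01 and bulk/tail ESS > 400);
* measurement noise is additive on the logit scale,
  `logit(s̃) ~ normal(logit(s), σ_i)`, so measurements stay inside (0, 1);
  each `σ_i` is calibrated by root-finding so that simulated experiments
  reproduce that individual's observed curve-fit RMSE, and a gamma
  population model `σ_i ~ gamma(c, d)` supplies noise levels for unseen
  virtual individuals.

Virtual individuals are drawn by sampling `a` from the KDE, a posterior
parameter set uniformly from the regression draws, and `log b` from the
conditional — rejecting curves whose ED25/ED75 fall outside bounds derived
from the raw estimates.  A heterogeneity knob η ∈ [0, 1] shrinks the
population towards its median curve (η = 0: everyone identical; η = 1:
unrestricted), and interventions that change light sensitivity are modelled
as a multiplier χ on the ED50.  Power for two-level illuminance comparisons
and for interventions, in within- (paired t-test) or between-subjects
(Welch t-test) designs, is the Monte-Carlo fraction of simulated trials that
reject *with the correct sign*.

The original participant-level estimates are not redistributable, so the
package ships a synthetic-fixtures generator with a known ground truth
(matching the published study's scale: n = 41, a ~60-fold ED50 range); all
fitting, sampling and power machinery is exercised end-to-end against it.

## Worked example

```python
import virtuallux as vl

raw, truth = vl.generate_raw_estimates(vl.FixtureSpec(n=41, seed=1234))
model = vl.VirtualPopulation(random_state=0).fit(raw)
print(f"converged: {model.converged_}")
print(f"max R-hat: {model.regression_.diagnostics.max_rhat:.4f}")
print(f"posterior means: { {k: round(v, 3) for k, v in model.regression_.means().items()} }")
print(f"median log10(ED50): {model.a_distribution_.a50:.3f}")

spec = vl.DesignSpec("comparison", "within", N=30, eta=1.0, alpha=0.05,
                     x1=100.0, x2=400.0)
cell = vl.estimate_power(model.population_model_, spec, replicates=1000, seed=1)
print(f"power (within, N=30, 100 vs 400 lx): {cell.power:.3f} "
      f"+/- {cell.mc_standard_error:.3f}")
```

prints

```
converged: True
max R-hat: 1.0030
posterior means: {'alpha': -0.719, 'beta': 0.472, 'sigma0': 0.142, 'sigma1': 0.076}
median log10(ED50): 2.040
power (within, N=30, 100 vs 400 lx): 0.666 +/- 0.015
```

i.e. the Bayesian fit passed its convergence gate, the fitted population has
a median ED50 near 110 lux, and a 30-participant within-subjects comparison
of 100 vs 400 lux detects the (correctly signed) difference about two-thirds
of the time at the 5% level.  Rerunning the same cell as a between-subjects
design gives 0.541 ± 0.016 — paired designs beat independent groups.

A `virtuallux` console script exposes the same pipeline as subcommands
(`fixtures`, `calibrate`, `fit`, `simulate`, `power`); see
`virtuallux --help`.

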