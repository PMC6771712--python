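# flexcif

Flexible parametric cause-specific hazard regression for competing risks,
with delta-method inference for cumulative incidence functions.

## The problem

In a competing-risks setting (say, death from cancer vs death from other
causes) the clinically interesting quantity is usually the *cause-specific
cumulative probability* (cumulative incidence function, CIF)

    F_j(t, x) = ∫₀ᵗ S(u, x) λ_j(u, x) du,
    S(u, x)   = exp{ −Σ_l Λ_l(u, x) },

which depends on **all** cause-specific hazards λ_l, not only the one of
interest.  `flexcif` models each cause-specific hazard on the log scale,

    log λ_j(t, x; β_j) = log λ_0j(t; γ_j) + xᵀ α_j(t),

with a clamped B-spline for the log-baseline hazard and, optionally,
B-spline *time-dependent* hazard ratios α(t) for chosen covariates.  Each
cause is fit by maximum likelihood with the competing events censored, so
the joint parameter covariance Σ̂_β is block-diagonal.  From a fitted model
the package derives:

- individual CIFs F̂_j(t, x) with delta-method variances
  ∇F̂ᵀ Σ̂_β ∇F̂ (analytic gradients) and cloglog confidence intervals built
  on the complement 1 − F;
- population-averaged CIFs F̂_jᴾ(t) = Σ_i w_i F̂_j(t, x_i) whose variance
  accounts for the correlation of predictions sharing one β̂;
- directly standardized (covariate-adjusted) CIFs — every subject's chosen
  covariate set to a fixed level — and the standardized risk difference
  D(t) between two levels, with Wald intervals;
- the nonparametric Aalen–Johansen estimator as a model-free comparator;
- a competing-risks data simulator (power generalized Weibull cancer
  hazard, life-table other-cause mortality) and a Monte-Carlo study driver
  reporting bias, empirical/model SE, RMSE and CI coverage.

All cumulative-hazard and CIF integrals use Gauss–Legendre quadrature that
splits at the spline knots, so each segment is analytic and the quadrature
is exact to machine precision at modest node counts.

Intended users: biostatisticians and epidemiologists analyzing cause-specific
mortality or registry progression data who want smooth, covariate-resolved
risk estimates that remain consistent with nonparametric curves.

## Worked example

Simulate a cohort, fit cubic-spline cause-specific models, and standardize
on sex:

```python
import numpy as np, flexcif as fc

config = fc.scenario1_config(n=1000)          # two-cause registry-like cohort
data = fc.simulate_dataset(config, seed=7)

fit = fc.fit_competing(fc.study_model_specs("b"), data)  # cubic baseline, knots {1,5}
X = data.covariate_matrix(("age", "sex"))

pop = fc.population_cif(fit, [1.0, 5.0, 10.0], X)[0]     # cause 1
print(pop.to_frame().round(4))

diff = fc.risk_difference(fit, [5.0], X, "sex", 1.0, 0.0)[0]
print(diff.to_frame().round(4))
```

Output:

```
   time  cause              setting  estimate      se  ci_low  ci_high
0   1.0      1  observed population    0.1328  0.0098  0.1148   0.1534
1   5.0      1  observed population    0.4258  0.0152  0.3966   0.4562
2  10.0      1  observed population    0.5468  0.0162  0.5153   0.5788
   time  cause            setting  estimate      se  ci_low  ci_high
0   5.0      1  sex=1.0 - sex=0.0    0.1193  0.0273  0.0657   0.1728
```

The population probability of cause-1 death reaches 55% by year 10
(95% CI 52–58%), and standardizing everyone to female vs male raises the
5-year cause-1 risk by 11.9 percentage points (CI 6.6–17.3) — the joint
effect of the sex hazard ratio on both causes, expressed on the
probability scale.

The same analysis is scriptable from the shell:

```
flexcif simulate --scenario 1 --n 1000 --seed 7 --out cohort.csv
flexcif fit --data cohort.csv --config analysis.yaml --outdir fit/
flexcif predict --fit fit/fit.json --data cohort.csv --times 1,5,10 --out cif.csv
flexcif adjust --fit fit/fit.json --data cohort.csv --variable sex \
        --levels 1,0 --times 5,10 --outdir adjusted/
```

`flexcif fit` enumerates all 2^q time-fixed/time-dependent effect
combinations per cause and keeps the AIC-best model; `simstudy` and `aj`
expose the Monte-Carlo driver and the nonparametric estimator.

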