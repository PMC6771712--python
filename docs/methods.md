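# Methods

## Model

For each cause j ∈ {1, …, J} the cause-specific hazard is modelled on the
log scale,

    log λ_j(t, x; β_j) = log λ_0j(t; γ_j) + xᵀ α_j(t),

where log λ_0j is a clamped B-spline in follow-up time t (degree 1–3,
interior knots chosen by the analyst or as event-time quantiles; boundary
knots repeated degree+1 times) and each covariate effect α is either a
constant (proportional cause-specific hazards) or a B-spline in t (a
time-dependent, TD, effect).  The baseline basis spans constants, so no
separate intercept is included — adding one would make the design rank
deficient.

Because log λ_j is linear in β_j = (γ_j, α_j), each design column
factorizes as φ_k(t)·ψ_k(x): the baseline columns have ψ = 1, a fixed
effect has φ = 1, and a TD effect has φ equal to its own basis function.
This factorization is used throughout for vectorized likelihood, CIF and
gradient evaluation.

### Likelihood and fitting

Under random censoring the likelihood factorizes over causes; cause j is
fit with all other events censored.  A subject contributes
−Λ_j(t_i, x_i) + δ_ij log λ_j(t_i, x_i).  The cumulative hazard has no
closed form and is evaluated by Gauss–Legendre (GL) quadrature.  The
log-likelihood is concave (log-linear hazard), and its score and observed
information are quadrature sums in closed form, so fitting uses damped
Newton steps: convergence when the gradient max-norm is below 1e-6, at
most 200 iterations, step halving until the likelihood does not decrease.
Initialization sets every baseline coefficient to the crude log rate
log(events / person-time) and all covariate effects to zero.  The
covariance Σ̂_{β_j} is the inverse observed information at the optimum;
AIC = −2ℓ + 2p_j.  Per-cause fits are stacked with a block-diagonal joint
covariance (zero cross-cause blocks, reflecting the factorized
likelihood).  Non-convergence is flagged, never silently returned;
a singular information matrix raises an error suggesting fewer knots.

### Quadrature

All integrals (likelihood cumulative hazards, CIFs, gradients) use GL
rules **split at the models' interior spline knots**.  A spline log-hazard
is piecewise-polynomial with limited smoothness at the knots; a single GL
rule across a knot converges only algebraically (empirically ~K⁻⁴, leaving
~2e-6 errors at K=64), whereas per-segment GL on the analytic pieces
reaches machine precision by K≈15.  Defaults: 20 nodes/segment for
fitting and prediction, 10 nodes/segment inside the Monte-Carlo study
driver.  The CIF uses a nested scheme — an outer knot-split rule on
[0, t], and at each outer node u an inner knot-split rule on [0, u] for
every cause's cumulative hazard.

### Cumulative probabilities and inference

The individual CIF is F_j(t, x) = ∫₀ᵗ S(u, x) λ_j(u, x) du with
S = exp(−Σ_l Λ_l).  Its gradient with respect to the stacked β has the
analytic form (using ∂λ_l/∂β_lk = λ_l d_lk with design column d_lk):

    ∂F_j/∂β_jk = ∫₀ᵗ S λ_j [ d_jk(u, x) − ∫₀ᵘ λ_j d_jk dv ] du
    ∂F_j/∂β_lk = −∫₀ᵗ S λ_j [ ∫₀ᵘ λ_l d_lk dv ] du        (l ≠ j)

evaluated on the same nested quadrature (tests verify agreement with
central finite differences to 1e-5 relative).  The delta-method variance
is ∇Fᵀ Σ̂_β ∇F; tiny negative values from floating-point noise are clipped
to zero with a warning.

Confidence intervals use the cloglog transform of the **complement**:
se of log(−log(1−F)) is √Var(F) / |(1−F)·log(1−F)| and the bounds are
1 − (1−F̂)^Ω with Ω = exp(±z·se).  Working on 1−F keeps the denominator
away from zero for rare events and early times; Var(1−F) = Var(F).
Estimates at exactly 0 or 1 return a degenerate interval with a warning.

The population CIF is the weighted mean of individual CIFs (weights
default to 1/N; exposing them supports standardization to a subsample or
an external reference population).  Predictions share one β̂ and are
therefore correlated; the variance contracts the weighted *sum* of
gradients with Σ̂_β: Var = (Gw)ᵀ Σ̂_β (Gw).  The adjusted (directly
standardized) CIF overwrites one covariate with a fixed level in every
row first.  The standardized risk difference D(t) between two levels uses
the gradient of the difference on the same Σ̂_β — the correlation between
the two standardized curves is thereby accounted for — with a Wald
interval on the identity scale, since differences may be negative.

### Nonparametric comparator

The Aalen–Johansen estimator increments the cause-j CIF by
KM(s⁻)·d_js/n_s at each event time s, KM being the all-cause
Kaplan–Meier estimate; deaths precede censorings at tied times.  Its
variance is the Aalen-type (Klein–Moeschberger) estimator.  The identity
Σ_j CIF_j + KM = 1 holds exactly at every event time and is asserted in
tests; point estimates are cross-checked against lifelines.

## Synthetic data

The simulator emulates a cancer-registry cohort with two causes of death.

Covariates: sex ~ Bernoulli (P(woman) 0.5 in the proportional-hazards
scenario, 0.3 in the TD scenario), year of diagnosis ~ U(2000, 2003)
(generated but not modelled), age from three classes ([30,65), [65,75),
[75,80) with probabilities 0.25/0.35/0.40) uniform within class.

Cause 1 ("cancer") uses the power generalized Weibull hazard
λ₀(t) = κ·α·ρ^κ·t^{κ−1}(1+(ρt)^κ)^{α−1}, cumulative hazard
Λ₀(t) = (1+(ρt)^κ)^α − 1, with log-linear effects
β_age = 0.03/year and β_sex = 0.3.  Scenario 1 uses (κ, ρ, α) =
(2, 1.2, 0.1) for both sexes — the hazard peaks sharply near t ≈ 0.93
years, which is exactly the feature a too-stiff baseline spline fails to
capture.  Scenario 2 uses sex-specific triples ((2, 0.4, 0.2) men,
(2, 0.3, 0.2) women, β_sex = 0), making the sex effect genuinely
time-dependent.  Event times invert Λ₀ in closed form.

Age enters the linear predictor centred at 60 years (configurable).  The
centring is a generator design choice: with the stated per-year effect an
uncentred age would drive every cancer risk to ~1; centring at 60
reproduces a realistic overall censoring fraction of ≈0.37–0.38 under the
other design parameters below.

Cause 2 ("other causes") is piecewise exponential with rates read from a
sex × integer-age × calendar-year life table; the rate switches at every
attained birthday and New Year, and sampling inverts the exact
piecewise-linear cumulative hazard (round-trip identity tested to 1e-10).
A synthetic Gompertz life table ships with the package (rate
a_sex·e^{0.097·age}; a = 2.2e-5 men, 1.4e-5 women — approximating recent
national all-cause levels, flat in calendar year); real life tables load
from CSV.  Dropout is exponential (rate 0.035/year ≈ 15% lost) and
administrative censoring is at 10 years; T = min of the four times.

True cumulative probabilities under the generating mechanism are computed
per subject by outer GL quadrature with the closed-form cancer cumulative
hazard and the exact piecewise life-table one, then averaged over a large
fixed reference sample (default 100 000) that defines the estimand for
the Monte-Carlo study.  (Using a small per-N truth sample would fold its
own sampling error into every bias and coverage figure.)

What the generator does **not** emulate: covariate measurement error,
delayed entry, informative censoring, more than two causes in the shipped
scenarios (the API accepts J ≥ 2), or any real life-table vintage — so
passing tests demonstrate internal statistical validity of the estimators
under a realistic mechanism, not agreement with any particular registry.

The registry-like fixture (`make_mgus_like_fixture`) generates a cohort
resembling a monoclonal-gammopathy study: a rare absorbing progression
event (constant hazard scaled by serum m-spike, slightly higher in women)
competing with common death (Gompertz in age, higher in men); it exists
to exercise the full AIC pipeline end to end.

## Monte-Carlo study driver

`run_study` simulates n_sim replicates (replicate r seeded base+1+r),
fits every requested model (and/or the nonparametric estimator), computes
population — and optionally subgroup — CIFs at the requested times, and
reports per (method, subgroup, cause, time): truth, bias, relative bias,
empirical SE (n−1 divisor), model SE (root mean delta variance), RMSE and
the coverage of the same cloglog CIs the estimators report.  Coverage is
judged against nominal ± 2·√(p(1−p)/n_sim), rounded to 3 decimals (the
Monte-Carlo acceptability band).  Replicates with failed or non-converged
fits are excluded and counted; more than 5% aborts the study.

Problem sizes used by the shipped test suite — 200 replicates at N = 300
and N = 1000 for the proportional-hazards scenario, 200 replicates × 3
models at N = 300 for the TD scenario, 500 replicates in the acceptance
script — were chosen to keep each headline quantity's Monte-Carlo error
small relative to its acceptance band.  Note the bias estimator's noise at
200 replicates is ≈ empSE/√200, i.e. roughly 1.4% in relative terms for
the rarer cause at mid follow-up; single-cell relative-bias readings near
a 2% bound should be interpreted with that resolution in mind.

## Numerical and design choices

- Quantile knots use the linear-interpolation (type-7) empirical quantile;
  duplicate knots raise an error advising fewer knots.
- Prediction beyond the baseline spline boundary raises a range error;
  there is no silent extrapolation.
- AIC ties break toward fewer parameters, then input order.
- TD effects default to the same spline family and knots as the baseline.
- The analysis pipeline enumerates all 2^q fixed/TD combinations over q
  covariates with the baseline spline held fixed (cubic, knots at the 33rd
  and 66th percentile of pooled event times by default) and selects per
  cause by AIC.
- Left truncation, interval censoring, frailties and subdistribution
  (Fine–Gray) modelling are out of scope; causes must be coded 0 (censored),
  1…J.
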