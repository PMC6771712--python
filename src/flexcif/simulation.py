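"""Synthetic competing-risks data: cancer deaths vs population mortality.

The generator mimics a cancer-registry cohort.  Cause 1 ("cancer") follows a
power generalized Weibull hazard with log-linear covariate effects, sampled
by inverting its closed-form cumulative hazard; cause 2 ("other causes") is
piecewise exponential with rates read off a sex x age x calendar-year life
table, so the rate steps at every attained birthday and New Year.  Subjects
also drop out at an exponential rate and are administratively censored at a
fixed horizon.

The power generalized Weibull has

    hazard      lambda0(t) = kappa * alpha * rho^kappa * t^(kappa-1)
                             * (1 + (rho t)^kappa)^(alpha - 1)
    cum. hazard Lambda0(t) = (1 + (rho t)^kappa)^alpha - 1
    survival    S0(t)      = exp{1 - (1 + (rho t)^kappa)^alpha}

With (kappa, rho, alpha) = (2, 1.2, 0.1) the hazard peaks sharply inside
the first year and declines afterwards — the hallmark shape of
cancer-specific mortality shortly after diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LifeTable, SurvDataset
from .quadrature import QuadratureRule

__all__ = [
    "ScenarioConfig", "scenario1_config", "scenario2_config",
    "gw_baseline_hazard", "gw_cumulative_hazard", "gw_survival",
    "sample_cancer_time", "sample_othercause_time", "othercause_cumhaz",
    "simulate_dataset", "true_cif", "synthetic_lifetable",
    "make_mgus_like_fixture",
]


# --------------------------------------------------------------------------
# power generalized Weibull

def _check_gw(kappa, rho, alpha):
    if kappa <= 0 or rho <= 0 or alpha <= 0:
        raise ValueError(f"generalized-Weibull parameters must be positive, "
                         f"got ({kappa}, {rho}, {alpha})")


def gw_baseline_hazard(t, kappa, rho, alpha):
    """Power generalized Weibull hazard; reduces to Weibull when alpha = 1."""
    _check_gw(kappa, rho, alpha)
    t = np.asarray(t, dtype=float)
    return (kappa * alpha * rho ** kappa * t ** (kappa - 1)
            * (1.0 + (rho * t) ** kappa) ** (alpha - 1.0))


def gw_cumulative_hazard(t, kappa, rho, alpha):
    _check_gw(kappa, rho, alpha)
    t = np.asarray(t, dtype=float)
    return (1.0 + (rho * t) ** kappa) ** alpha - 1.0


def gw_survival(t, kappa, rho, alpha):
    return np.exp(-gw_cumulative_hazard(t, kappa, rho, alpha))


def _gw_inverse_cumhaz(q, kappa, rho, alpha):
    """Solve Lambda0(T) = q for T (closed form)."""
    return ((1.0 + np.asarray(q, dtype=float)) ** (1.0 / alpha) - 1.0) \
        ** (1.0 / kappa) / rho


# --------------------------------------------------------------------------
# scenario configuration

def synthetic_lifetable(age_range=(30, 99), year_range=(2000, 2014),
                        gompertz_slope=0.097,
                        level_men=2.2e-5, level_women=1.4e-5) -> LifeTable:
    """Gompertz-shaped general-population mortality, flat in calendar year.

    The levels approximate recent national (UK-like) all-cause rates:
    roughly 1.2% per year for men at age 65, rising ~10% per year of age,
    with women about 35% lower.  Synthetic — shipped so that no external
    life-table download is needed; pass a real table for exact replication
    of registry analyses.
    """
    ages = np.arange(age_range[0], age_range[1] + 1)
    years = np.arange(year_range[0], year_range[1] + 1)
    rows = []
    for sex, level in ((0, level_men), (1, level_women)):
        for a in ages:
            rate = level * np.exp(gompertz_slope * a)
            for y in years:
                rows.append((sex, a, y, rate))
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "year", "rate"]))


@dataclass
class ScenarioConfig:
    """Everything needed to generate one competing-risks dataset.

    ``cancer_params`` maps sex code (0 man, 1 woman) to the power
    generalized Weibull triple of the cancer hazard; identical triples give
    a proportional-hazards scenario, sex-specific triples give a genuinely
    time-dependent sex effect.  Age enters the cancer log-hazard linearly
    per year, measured from ``age_center``.
    """

    n: int = 300
    sex_prob: float = 0.5                       # P(woman)
    year_range: tuple[float, float] = (2000.0, 2003.0)
    age_classes: tuple = ((30.0, 65.0, 0.25), (65.0, 75.0, 0.35),
                          (75.0, 80.0, 0.40))
    cancer_params: dict = field(default_factory=lambda: {
        0: (2.0, 1.2, 0.1), 1: (2.0, 1.2, 0.1)})
    beta_age: float = 0.03
    beta_sex: float = 0.3
    age_center: float = 60.0
    lifetable: LifeTable | None = None
    dropout_rate: float = 0.035
    admin_censor: float = 10.0

    def __post_init__(self):
        probs = [c[2] for c in self.age_classes]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"age-class probabilities sum to {sum(probs)}, not 1")
        for sex, p in self.cancer_params.items():
            _check_gw(*p)
        if self.dropout_rate < 0:
            raise ValueError("dropout rate must be >= 0")
        if self.admin_censor <= 0:
            raise ValueError("administrative censoring time must be positive")
        if self.lifetable is None:
            self.lifetable = synthetic_lifetable()

    def linear_predictor(self, age, sex):
        return (self.beta_age * (np.asarray(age, float) - self.age_center)
                + self.beta_sex * np.asarray(sex, float))

    def cancer_hazard(self, t, age, sex):
        """Cancer hazard at times ``t`` (vectorized over subjects)."""
        sex = np.asarray(sex, dtype=int)
        out = np.empty(np.broadcast_shapes(np.shape(t), sex.shape))
        eta = np.exp(self.linear_predictor(age, sex))
        for s, params in self.cancer_params.items():
            m = sex == s
            if np.any(m):
                base = gw_baseline_hazard(np.broadcast_to(t, out.shape)[..., m],
                                          *params)
                out[..., m] = base * eta[m]
        return out

    def cancer_cumhaz(self, t, age, sex):
        sex = np.asarray(sex, dtype=int)
        out = np.empty(np.broadcast_shapes(np.shape(t), sex.shape))
        eta = np.exp(self.linear_predictor(age, sex))
        for s, params in self.cancer_params.items():
            m = sex == s
            if np.any(m):
                base = gw_cumulative_hazard(
                    np.broadcast_to(t, out.shape)[..., m], *params)
                out[..., m] = base * eta[m]
        return out


def scenario1_config(n=300, **kwargs) -> ScenarioConfig:
    """Proportional-hazards scenario: common baseline, fixed sex effect."""
    return ScenarioConfig(n=n, sex_prob=0.5,
                          cancer_params={0: (2.0, 1.2, 0.1), 1: (2.0, 1.2, 0.1)},
                          beta_sex=0.3, **kwargs)


def scenario2_config(n=300, **kwargs) -> ScenarioConfig:
    """Sex-specific baselines: the sex effect on the cancer hazard is
    genuinely time-dependent; 30% women."""
    return ScenarioConfig(n=n, sex_prob=0.3,
                          cancer_params={0: (2.0, 0.4, 0.2), 1: (2.0, 0.3, 0.2)},
                          beta_sex=0.0, **kwargs)


# --------------------------------------------------------------------------
# samplers

def sample_cancer_time(config: ScenarioConfig, age, sex, u) -> np.ndarray:
    """Invert the cancer cumulative hazard: Lambda0(T) e^eta = -log u."""
    age = np.atleast_1d(np.asarray(age, float))
    sex = np.atleast_1d(np.asarray(sex, int))
    u = np.atleast_1d(np.asarray(u, float))
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("uniform draws must be in (0, 1)")
    q = -np.log(u) / np.exp(config.linear_predictor(age, sex))
    out = np.empty_like(q)
    for s, params in config.cancer_params.items():
        m = sex == s
        if np.any(m):
            out[m] = _gw_inverse_cumhaz(q[m], *params)
    return out


def _lifetable_segments(table: LifeTable, sex, age, year, horizon: float,
                        clip_to_support: bool = False):
    """Piecewise-exponential segments of the other-cause hazard.

    Returns (breaks, rates, cum): ``breaks`` (N, M+1) ascending from 0 to
    ``horizon`` including every attained-integer-age and calendar-year
    boundary, ``rates`` (N, M) the annual rate on each segment and ``cum``
    (N, M+1) the cumulative hazard at each break.  Zero-length segments
    from coincident boundaries are harmless.
    """
    age = np.atleast_1d(np.asarray(age, float))
    year = np.atleast_1d(np.asarray(year, float))
    sex = np.atleast_1d(np.asarray(sex, int))
    n = age.shape[0]
    if clip_to_support:
        span = np.minimum(table.age_max + 1 - age, table.year_max + 1 - year)
        row_horizon = np.minimum(horizon, np.maximum(span, 0.0))[:, None]
    else:
        row_horizon = np.full((n, 1), float(horizon))
    H = int(np.ceil(np.max(row_horizon)))
    ks = np.arange(H + 1, dtype=float)
    b_age = (np.floor(age[:, None]) + 1.0 - age[:, None]) + ks
    b_year = (np.floor(year[:, None]) + 1.0 - year[:, None]) + ks
    breaks = np.concatenate(
        [np.zeros((n, 1)), np.clip(b_age, 0.0, row_horizon),
         np.clip(b_year, 0.0, row_horizon), row_horizon], axis=1)
    breaks = np.sort(breaks, axis=1)
    seg = np.diff(breaks, axis=1)
    mid = (breaks[:, :-1] + breaks[:, 1:]) / 2.0
    # zero-length segments (coincident boundaries, or support edge) carry no
    # hazard; look their rate up at 0 to stay inside the table
    mid = np.where(seg > 0, mid, 0.0)
    rates = table.rate(sex[:, None], age[:, None] + mid, year[:, None] + mid)
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(rates * seg, axis=1)],
                         axis=1)
    return breaks, rates, cum


def othercause_cumhaz(table: LifeTable, sex, age, year, t,
                      horizon: float | None = None) -> np.ndarray:
    """Exact piecewise-linear cumulative other-cause hazard at times ``t``.

    ``t`` has shape (T,); the result has shape (N, T).
    """
    t = np.atleast_1d(np.asarray(t, float))
    horizon = float(np.max(t)) if horizon is None else horizon
    breaks, rates, _ = _lifetable_segments(table, sex, age, year, horizon)
    incr = np.clip(t[None, None, :] - breaks[:, :-1, None], 0.0,
                   np.diff(breaks, axis=1)[:, :, None])
    return np.einsum("nm,nmt->nt", rates, incr)


def sample_othercause_time(table: LifeTable, sex, age, year, u,
                           horizon: float = 10.0) -> np.ndarray:
    """Piecewise-exponential draw; +inf when -log u exceeds the cumulative
    hazard reachable before ``horizon``."""
    u = np.atleast_1d(np.asarray(u, float))
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("uniform draws must be in (0, 1)")
    target = -np.log(u)
    # never walk past the life table's own span: beyond it the draw is +inf
    age_arr = np.atleast_1d(np.asarray(age, float))
    year_arr = np.atleast_1d(np.asarray(year, float))
    cap = min(table.age_max + 1 - age_arr.min(),
              table.year_max + 1 - year_arr.min())
    horizon = float(min(horizon, max(cap, 1e-9)))
    breaks, rates, cum = _lifetable_segments(table, sex, age, year, horizon,
                                             clip_to_support=True)
    n = breaks.shape[0]
    idx = np.array([np.searchsorted(cum[i], target[i], side="right") - 1
                    for i in range(n)])
    out = np.full(n, np.inf)
    inside = idx < rates.shape[1]
    ii = np.where(inside)[0]
    r = rates[ii, idx[ii]]
    ok = r > 0
    out[ii[ok]] = breaks[ii[ok], idx[ii][ok]] \
        + (target[ii[ok]] - cum[ii[ok], idx[ii][ok]]) / r[ok]
    # zero-rate segment exactly at the target boundary: event at the break
    out[ii[~ok]] = breaks[ii[~ok], idx[ii][~ok]]
    return out


def draw_covariates(config: ScenarioConfig, rng, n=None):
    """Sample (age, sex, year) per the scenario's covariate distribution."""
    n = config.n if n is None else n
    sex = (rng.random(n) < config.sex_prob).astype(int)
    year = rng.uniform(config.year_range[0], config.year_range[1], n)
    probs = [c[2] for c in config.age_classes]
    cls = rng.choice(len(config.age_classes), size=n, p=probs)
    lo = np.array([c[0] for c in config.age_classes])[cls]
    hi = np.array([c[1] for c in config.age_classes])[cls]
    age = lo + rng.random(n) * (hi - lo)
    return pd.DataFrame({"age": age, "sex": sex, "year": year})


def simulate_dataset(config: ScenarioConfig, seed=None, rng=None) -> SurvDataset:
    """Generate one dataset: T = min(T_cancer, T_other, T_dropout, C)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    cov = draw_covariates(config, rng)
    age = cov["age"].to_numpy()
    sex = cov["sex"].to_numpy(int)
    year = cov["year"].to_numpy()
    n = config.n
    t_cancer = sample_cancer_time(config, age, sex, rng.random(n))
    t_other = sample_othercause_time(config.lifetable, sex, age, year,
                                     rng.random(n),
                                     horizon=config.admin_censor)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, config.admin_censor)
    t_event = np.minimum(t_cancer, t_other)
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)
    cause = np.where(status == 0, 0, np.where(t_cancer <= t_other, 1, 2))
    time = np.maximum(time, 1e-8)  # guard against a zero draw
    return SurvDataset(time, status, cause, cov)


def true_cif(config: ScenarioConfig, times, covariates=None, n_ref=100_000,
             seed=12345, rule: QuadratureRule | None = None,
             average: bool = True, chunk: int = 5000):
    """Cumulative probabilities under the *generating* hazards.

    For each subject, F_j(t) = int_0^t S(u) lambda_j(u) du with the cancer
    cumulative hazard in closed form and the other-cause one summed exactly
    over the life-table segments; the outer integral uses Gauss-Legendre.
    ``covariates`` defaults to a large fresh sample from the scenario's
    covariate distribution (the reference population defining the estimand).
    Returns an array (2, T) of population means (causes 1 and 2), or
    (2, T, N) per-subject values when ``average=False``.
    """
    rule = rule or QuadratureRule(64)
    times = np.atleast_1d(np.asarray(times, float))
    if covariates is None:
        covariates = draw_covariates(config, np.random.default_rng(seed), n_ref)
    age = covariates["age"].to_numpy(float)
    sex = covariates["sex"].to_numpy(int)
    year = covariates["year"].to_numpy(float)
    N = age.shape[0]
    out = np.zeros((2, times.shape[0], N))
    horizon = float(np.max(times))
    for lo in range(0, N, chunk):
        sl = slice(lo, min(lo + chunk, N))
        a, s, y = age[sl], sex[sl], year[sl]
        for ti, t in enumerate(times):
            if t == 0:
                continue
            u, W = rule.map_to(0.0, float(t))
            L1 = config.cancer_cumhaz(u[:, None], a, s)        # (K, n)
            lam1 = config.cancer_hazard(u[:, None], a, s)
            L2 = othercause_cumhaz(config.lifetable, s, a, y, u,
                                   horizon=horizon).T           # (K, n)
            lam2 = config.lifetable.rate(s[None, :], a[None, :] + u[:, None],
                                         y[None, :] + u[:, None])
            S = np.exp(-L1 - L2)
            out[0, ti, sl] = W @ (S * lam1)
            out[1, ti, sl] = W @ (S * lam2)
    if average:
        return out.mean(axis=2)
    return out


# --------------------------------------------------------------------------
# registry-like fixture with a rare progression event

def make_mgus_like_fixture(n: int = 1373, seed: int = 20240601) -> SurvDataset:
    """Synthetic cohort resembling a monoclonal-gammopathy registry.

    Two competing events: progression to plasma-cell malignancy (cause 1,
    rare, driven mainly by the serum m-spike size and slightly higher in
    women) and death without progression (cause 2, common, Gompertz in age
    and higher in men).  Generating model: age ~ N(70, 11) clipped to
    [35, 94]; P(woman) = 0.45; mspike ~ N(1.2, 0.5) clipped to [0.1, 3.0];
    progression hazard 0.005 * exp{0.9 (mspike - 1.2) + 0.25 sex +
    0.01 (age - 70)} per year (constant in time); death hazard
    0.045 * exp{0.088 (age - 70) + 0.32 (1 - sex)}; censoring at
    min(Uniform(4, 32), Exp(rate 0.01)) years.  Covariates: age, sex
    (1 = woman), mspike; times in years.
    """
    if n < 50:
        raise ValueError("fixture needs n >= 50")
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(70.0, 11.0, n), 35.0, 94.0)
    sex = (rng.random(n) < 0.45).astype(int)
    mspike = np.clip(rng.normal(1.2, 0.5, n), 0.1, 3.0)
    lam1 = 0.005 * np.exp(0.9 * (mspike - 1.2) + 0.25 * sex
                          + 0.01 * (age - 70.0))
    lam2 = 0.045 * np.exp(0.088 * (age - 70.0) + 0.32 * (1 - sex))
    t1 = rng.exponential(1.0 / lam1)
    t2 = rng.exponential(1.0 / lam2)
    cens = np.minimum(rng.uniform(4.0, 32.0, n), rng.exponential(100.0, n))
    t_event = np.minimum(t1, t2)
    time = np.minimum(t_event, cens)
    status = (t_event <= cens).astype(int)
    cause = np.where(status == 0, 0, np.where(t1 <= t2, 1, 2))
    cov = pd.DataFrame({"age": age, "sex": sex, "mspike": mspike})
    return SurvDataset(np.maximum(time, 1e-6), status, cause, cov)
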