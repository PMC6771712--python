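"""Monte-Carlo performance measures and the simulation-study driver.

For an estimand theta with true value theta_tilde and per-replicate
estimates theta_hat_i and model variances Var_hat_i, the standard report
is: bias (mean estimate minus truth), relative bias in percent, empirical
SE (sample SD of the estimates), model SE (root mean model variance), RMSE
(root mean squared error against the truth) and the coverage of the
nominal-level confidence interval.  Coverage is judged against the
acceptability band of nominal +- 2 Monte-Carlo SEs (Burton et al.).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .aalen_johansen import aalen_johansen
from .cif import cif_ci_cloglog
from .hazard import fit_competing
from .population import population_cif
from .quadrature import QuadratureRule
from .simulation import ScenarioConfig, simulate_dataset, true_cif

__all__ = ["performance", "acceptable_coverage_range", "run_study"]


def performance(estimates, variances, truth: float, alpha: float = 0.05) -> dict:
    """One row of the performance report for a single estimand.

    Coverage uses the same cloglog confidence intervals the estimators
    report.  The empirical SE uses the n-1 divisor; the RMSE uses 1/n, so
    RMSE^2 = bias^2 + empSE^2 (n-1)/n.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape[0] < 2:
        raise ValueError("need at least two replicates")
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(var))):
        raise ValueError("non-finite estimates or variances")
    n = est.shape[0]
    bias = est.mean() - truth
    if truth == 0:
        raise ZeroDivisionError("relative bias undefined for zero truth")
    inside = (est >= 0) & (est <= 1)
    lo = np.empty(n)
    hi = np.empty(n)
    if inside.any():
        lo[inside], hi[inside] = cif_ci_cloglog(est[inside], var[inside], alpha)
    if not inside.all():
        # estimand not a probability: fall back to a Wald interval
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        se = np.sqrt(var[~inside])
        lo[~inside] = est[~inside] - z * se
        hi[~inside] = est[~inside] + z * se
    return {
        "true": truth,
        "bias": bias,
        "rel_bias_pct": 100.0 * bias / truth,
        "empSE": est.std(ddof=1),
        "ModSE": float(np.sqrt(var.mean())),
        "RMSE": float(np.sqrt(np.mean((est - truth) ** 2))),
        "coverage": float(np.mean((lo <= truth) & (truth <= hi))),
        "n_sim": n,
    }


def acceptable_coverage_range(nominal: float, n_sim: int) -> tuple[float, float]:
    """Nominal coverage +- 2 sqrt(p(1-p)/n_sim), rounded to 3 decimals."""
    if not 0 < nominal < 1:
        raise ValueError("nominal coverage must be in (0, 1)")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    half = 2.0 * np.sqrt(nominal * (1.0 - nominal) / n_sim)
    return (round(nominal - half, 3), round(nominal + half, 3))


def _aj_at(data, times):
    aj = aalen_johansen(data)
    est = {}
    for j in (1, 2):
        if j in aj.causes:
            est[j] = (aj.evaluate(j, times), aj.variance_at(j, times))
        else:
            est[j] = (np.zeros(len(times)), np.zeros(len(times)))
    return est


def run_study(config: ScenarioConfig, methods: dict, n_sim: int, times,
              seed: int, fit_rule: QuadratureRule | None = None,
              pred_rule: QuadratureRule | None = None,
              n_truth: int = 100_000, subgroups: dict | None = None,
              alpha: float = 0.05, covariate_names=("age", "sex"),
              max_fail_frac: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Full Monte-Carlo study: simulate, fit every method, tabulate.

    ``methods`` maps a method label to either ``None`` (the nonparametric
    Aalen-Johansen comparator) or a list of cause-model specs.  The truth
    for each (cause, time) — and for each subgroup — is computed once from
    the generating hazards on a large fixed covariate sample.  Replicates
    where any model fails or does not converge are excluded and counted;
    more than ``max_fail_frac`` exclusions aborts the study.

    ``subgroups`` maps a label to ``(column, value)``; estimates are then
    also reported restricted to matching subjects (truth restricted the
    same way on the reference sample).

    Returns ``(table, info)`` where ``table`` has one row per
    (method, subgroup, cause, time).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    # all quadratures split integrals at the spline knots, so small
    # per-segment rules are already exact to machine precision
    fit_rule = fit_rule or QuadratureRule(10)
    pred_rule = pred_rule or QuadratureRule(10)
    groups = {"population": None}
    if subgroups:
        groups.update(subgroups)

    from .simulation import draw_covariates
    ref = draw_covariates(config, np.random.default_rng(seed), n_truth)
    truths = {}
    per_subject_truth = true_cif(config, times, covariates=ref, average=False)
    for gname, sel in groups.items():
        mask = np.ones(len(ref), dtype=bool) if sel is None else \
            (ref[sel[0]].to_numpy() == sel[1])
        truths[gname] = per_subject_truth[:, :, mask].mean(axis=2)

    store = {(meth, g): {j: ([], []) for j in (1, 2)}
             for meth in methods for g in groups}
    n_excluded = 0
    for r in range(n_sim):
        data = simulate_dataset(config, seed=seed + 1 + r)
        rep = {}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                for meth, specs in methods.items():
                    if specs is None:
                        continue
                    fit = fit_competing(specs, data, fit_rule)
                    if not all(m.converged for m in fit.models):
                        raise RuntimeError("non-converged fit")
                    rep[meth] = fit
        except Exception:
            n_excluded += 1
            continue
        X_all = data.covariate_matrix(covariate_names)
        for gname, sel in groups.items():
            mask = np.ones(data.n, dtype=bool) if sel is None else \
                (data.covariates[sel[0]].to_numpy() == sel[1])
            if mask.sum() == 0:
                continue
            sub = data.subset(mask)
            for meth, specs in methods.items():
                if specs is None:
                    est = _aj_at(sub, times)
                    for j in (1, 2):
                        store[(meth, gname)][j][0].append(est[j][0])
                        store[(meth, gname)][j][1].append(est[j][1])
                else:
                    pops = population_cif(rep[meth], times, X_all[mask],
                                          pred_rule, alpha=alpha)
                    for pop in pops:
                        store[(meth, gname)][pop.cause][0].append(pop.estimate)
                        store[(meth, gname)][pop.cause][1].append(pop.se ** 2)
    n_used = n_sim - n_excluded
    if n_used < 2 or n_excluded > max_fail_frac * n_sim:
        raise RuntimeError(
            f"{n_excluded}/{n_sim} replicates failed or did not converge")

    rows = []
    for (meth, gname), by_cause in store.items():
        for j in (1, 2):
            ests = np.array(by_cause[j][0])
            vars_ = np.array(by_cause[j][1])
            for ti, t in enumerate(times):
                row = {"method": meth, "subgroup": gname, "cause": j,
                       "time": t}
                row.update(performance(ests[:, ti], vars_[:, ti],
                                       truths[gname][j - 1, ti], alpha))
                rows.append(row)
    table = pd.DataFrame(rows)
    info = {"n_sim": n_sim, "n_excluded": n_excluded,
            "coverage_range": acceptable_coverage_range(1 - alpha, n_used)}
    return table, info


def study_model_specs(model: str, boundary=(0.0, 10.0)) -> list:
    """Cause-model pairs used in the shipped simulation study.

    Model "a": quadratic B-spline cancer baseline, knots {1, 5}, fixed age
    and sex effects.  Model "b": the same with a cubic baseline.  Model
    "c": cubic baseline plus a time-dependent sex effect on a cubic spline
    with the same knots.  The other-cause model is always a quadratic
    B-spline baseline with one knot at 1 year and fixed age and sex effects.
    """
    from .hazard import CauseModelSpec
    from .splines import SplineSpec

    cubic = SplineSpec(3, (1.0, 5.0), boundary)
    quad = SplineSpec(2, (1.0, 5.0), boundary)
    covs = ("age", "sex")
    if model == "a":
        cancer = CauseModelSpec(1, quad, covs)
    elif model == "b":
        cancer = CauseModelSpec(1, cubic, covs)
    elif model == "c":
        cancer = CauseModelSpec(1, cubic, covs, (("sex", cubic),))
    else:
        raise ValueError(f"unknown study model {model!r}; use 'a', 'b' or 'c'")
    other = CauseModelSpec(2, SplineSpec(2, (1.0,), boundary), covs)
    return [cancer, other]
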