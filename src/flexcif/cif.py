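"""Individual-level cause-specific cumulative probabilities.

The cumulative probability of failing from cause j by time t (the cumulative
incidence function, CIF) combines all cause-specific hazards:

    F_j(t, x) = int_0^t S(u, x) lambda_j(u, x) du,
    S(u, x)   = exp(-sum_l Lambda_l(u, x)).

Point estimates use a nested Gauss-Legendre scheme: an outer rule on [0, t]
and, at every outer node u, an inner rule on [0, u] for each cause's
cumulative hazard.  The same scheme yields the analytic gradient of F_j with
respect to the stacked parameter vector.  Writing the design column k of
cause l as d_lk(u, x) (so that d lambda_l / d beta_lk = lambda_l d_lk):

    dF_j/dbeta_jk = int_0^t S lambda_j [ d_jk(u,x) - int_0^u lambda_j d_jk dv ] du
    dF_j/dbeta_lk = -int_0^t S lambda_j [ int_0^u lambda_l d_lk dv ] du   (l != j)

Delta-method variances contract the gradient with the block-diagonal
parameter covariance; confidence intervals are formed on the
log(-log(1 - F)) scale, i.e. via the complement of F, which behaves well
for small probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .hazard import CompetingRisksFit
from .quadrature import QuadratureRule, composite_map

__all__ = ["CIFEstimate", "cif_point", "cif_gradient", "cif_variance",
           "cif_ci_cloglog", "predict_cif", "cif_curves"]

# per-segment node count; integrals split at spline knots, so this is
# already exact to machine precision for fitted models
_DEFAULT_PREDICT_K = 20


def _as_X(fit: CompetingRisksFit, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    ncov = len(fit.models[0].spec.covariates)
    for m in fit.models:
        if len(m.spec.covariates) != ncov:
            raise ValueError(
                "cause models use different covariate lists; pass the "
                "matrix matching each spec explicitly")
    if x.shape[1] != ncov:
        raise ValueError(f"covariate row has {x.shape[1]} entries, "
                         f"models expect {ncov}")
    return x


def cif_curves(fit: CompetingRisksFit, times, X, rule: QuadratureRule | None = None,
               gradient: bool = False, chunk: int = 1024):
    """Evaluate F_j(t, x_i) for every cause, time and covariate row.

    Returns ``(F, G)`` with ``F`` of shape (J, T, N).  With
    ``gradient=True``, ``G`` has shape (J, T, m, N) where m is the stacked
    parameter length, in block order matching the fit; otherwise ``G`` is
    None.  Both quadrature levels split at the models' interior knots so
    each segment of the integrand is analytic.  Rows of ``X`` are processed
    in chunks to bound memory.
    """
    from .hazard import model_knot_cuts

    rule = rule or QuadratureRule(_DEFAULT_PREDICT_K)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("prediction times must be >= 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, J, m = X.shape[0], len(fit.models), fit.n_params
    F = np.zeros((J, times.shape[0], N))
    G = np.zeros((J, times.shape[0], m, N)) if gradient else None
    slices = fit.block_slices()
    cuts = model_knot_cuts(*[m_.spec for m_ in fit.models])

    for ti, t in enumerate(times):
        if t == 0.0:
            continue
        u, W = composite_map(rule, float(t), cuts)   # (R,), outer
        R = u.shape[0]
        v, iw = composite_map(rule, u, cuts)         # (R, S), inner on [0, u_r]
        S_in = v.shape[1]
        phi_out = [m_.spec.time_factor(u) for m_ in fit.models]       # (R, p)
        phi_in = [m_.spec.time_factor(v.ravel()).reshape(R, S_in, -1)
                  for m_ in fit.models]                               # (R, S, p)
        for lo in range(0, N, chunk):
            sel = slice(lo, min(lo + chunk, N))
            psi = [m_.spec.cov_factor(X[sel]) for m_ in fit.models]   # (n, p)
            lam_out, Lam, C = [], [], []
            for j, m_ in enumerate(fit.models):
                bp = psi[j] * m_.beta                                  # (n, p)
                lam_o = np.exp(phi_out[j] @ bp.T)                      # (R, n)
                lam_i = np.exp(np.einsum("rsk,nk->rsn", phi_in[j], bp))
                Lam_j = np.einsum("rs,rsn->rn", iw, lam_i)             # (R, n)
                lam_out.append(lam_o)
                Lam.append(Lam_j)
                if gradient:
                    # C_j[r, k, n] = int_0^{u_r} lambda_j phi_jk dv (psi applied later)
                    C.append(np.einsum("rs,rsn,rsk->rkn", iw, lam_i, phi_in[j]))
            S = np.exp(-np.sum(Lam, axis=0))                           # (K, n)
            for j in range(J):
                core = S * lam_out[j]                                  # (K, n)
                F[j, ti, sel] = W @ core
                if gradient:
                    for l in range(J):
                        inner = np.einsum("rn,rkn->kn", core * W[:, None], C[l])
                        inner *= psi[l].T
                        if l == j:
                            own = np.einsum("rn,rk->kn", core * W[:, None],
                                            phi_out[j]) * psi[j].T
                            G[j, ti, slices[l], sel] = own - inner
                        else:
                            G[j, ti, slices[l], sel] = -inner
    return F, G


def cif_point(fit, times, x, rule: QuadratureRule | None = None) -> np.ndarray:
    """CIF of every cause at ``times`` for a single covariate row.

    Returns an array of shape (J, T), causes ordered as in the fit.
    """
    X = _as_X(fit, x)
    F, _ = cif_curves(fit, times, X, rule)
    return F[:, :, 0]


def cif_gradient(fit, t, x, rule: QuadratureRule | None = None,
                 cause: int | None = None) -> np.ndarray:
    """Gradient of F_j(t, x) w.r.t. the stacked parameters (length m).

    ``cause`` defaults to the first cause in the fit.
    """
    X = _as_X(fit, x)
    cause = fit.causes[0] if cause is None else cause
    j = fit.causes.index(cause)
    _, G = cif_curves(fit, [float(t)], X, rule, gradient=True)
    return G[j, 0, :, 0]


def cif_variance(fit, t, x, rule: QuadratureRule | None = None,
                 cause: int | None = None) -> float:
    """Delta-method variance of the individual CIF: grad' Sigma grad."""
    g = cif_gradient(fit, t, x, rule, cause)
    v = float(g @ fit.Sigma @ g)
    return _clip_var(v)


def _clip_var(v: float) -> float:
    if v < 0:
        if v < -1e-10:
            warnings.warn(f"negative delta-method variance {v:.3g} clipped to 0",
                          RuntimeWarning)
        return 0.0
    return float(v)


def cif_ci_cloglog(F, varF, alpha: float = 0.05):
    """Confidence interval for a cumulative probability on the cloglog scale.

    The transform is applied to the complement 1 - F: the SE of
    log(-log(1 - F)) is sqrt(Var F) / |(1 - F) log(1 - F)| and the bounds
    are 1 - (1 - F)^Omega with Omega = exp(+-z * se).  Degenerate inputs
    (F at 0 or 1, or zero variance) return the point estimate for both
    bounds.  Accepts arrays.
    """
    F = np.asarray(F, dtype=float)
    varF = np.maximum(np.asarray(varF, dtype=float), 0.0)
    z = norm.ppf(1.0 - alpha / 2.0)
    scalar = F.ndim == 0
    F, varF = np.atleast_1d(F), np.atleast_1d(varF)
    if np.any((F < 0) | (F > 1)):
        raise ValueError("F must lie in [0, 1]")
    lo = F.copy()
    hi = F.copy()
    interior = (F > 0) & (F < 1) & (varF > 0)
    if np.any(F[varF > 0] == 0) or np.any(F[varF > 0] == 1):
        warnings.warn("CIF at 0 or 1: returning a degenerate interval",
                      RuntimeWarning)
    comp = 1.0 - F[interior]
    # F tiny enough that 1-F rounds to 1 yields an infinite cloglog SE and
    # the degenerate full interval (0, 1); suppress the intermediate warnings
    with np.errstate(divide="ignore", over="ignore"):
        se_cll = np.sqrt(varF[interior]) / np.abs(comp * np.log(comp))
        omega_hi = np.exp(z * se_cll)
        omega_lo = np.exp(-z * se_cll)
        b1 = 1.0 - comp ** omega_hi
        b2 = 1.0 - comp ** omega_lo
    lo[interior] = np.minimum(b1, b2)
    hi[interior] = np.maximum(b1, b2)
    if scalar:
        return float(lo[0]), float(hi[0])
    return lo, hi


@dataclass
class CIFEstimate:
    """CIF values with delta-method SEs and cloglog confidence intervals."""

    times: np.ndarray
    cause: int
    estimate: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "cause": self.cause,
            "estimate": self.estimate, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def predict_cif(fit, times, x, rule: QuadratureRule | None = None,
                alpha: float = 0.05) -> list[CIFEstimate]:
    """Individual CIF estimate with SE and CI for every cause in the fit."""
    X = _as_X(fit, x)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    F, G = cif_curves(fit, times, X, rule, gradient=True)
    Sigma = fit.Sigma
    out = []
    for j, cause in enumerate(fit.causes):
        g = G[j, :, :, 0]                            # (T, m)
        var = np.array([_clip_var(float(gt @ Sigma @ gt)) for gt in g])
        lo, hi = cif_ci_cloglog(F[j, :, 0], var, alpha)
        out.append(CIFEstimate(times.copy(), cause, F[j, :, 0].copy(),
                               np.sqrt(var), lo, hi, alpha))
    return out
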