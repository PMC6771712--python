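"""Nonparametric Aalen-Johansen estimator of cumulative incidence.

Serves as the model-free comparator: the cause-j CIF jumps at each event
time s by KM(s-) * d_js / n_s, where KM is the all-cause Kaplan-Meier
survival and n_s the number at risk.  At tied times, events are processed
before censorings.  The variance is the Aalen-type estimator given by
Marubini & Valsecchi / Klein & Moeschberger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvDataset

__all__ = ["AJEstimate", "aalen_johansen"]


@dataclass
class AJEstimate:
    """Step-function CIF estimates for every cause on the event-time grid."""

    times: np.ndarray                   # distinct event times, ascending
    causes: list[int]
    cif: dict[int, np.ndarray]          # cause -> CIF right after each time
    variance: dict[int, np.ndarray]
    km: np.ndarray                      # all-cause KM right after each time
    at_risk: np.ndarray
    events: dict[int, np.ndarray]       # cause -> event count at each time

    def evaluate(self, cause: int, t) -> np.ndarray:
        """CIF of ``cause`` at arbitrary times (right-continuous step)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = np.concatenate([[0.0], self.cif[cause]])
        return vals[idx + 1]

    def variance_at(self, cause: int, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = np.concatenate([[0.0], self.variance[cause]])
        return vals[idx + 1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in self.causes:
            rows.append(pd.DataFrame({
                "time": self.times, "cause": j, "estimate": self.cif[j],
                "se": np.sqrt(self.variance[j]),
                "at_risk": self.at_risk, "events": self.events[j],
            }))
        return pd.concat(rows, ignore_index=True)


def aalen_johansen(data: SurvDataset) -> AJEstimate:
    """Aalen-Johansen CIF estimate for every cause present in the data."""
    if data.n == 0:
        raise ValueError("empty dataset")
    causes = data.causes
    order = np.lexsort((1 - data.status, data.time))  # events before censorings
    t = data.time[order]
    cause = data.cause[order]

    times = np.unique(t[cause > 0])
    n_t = times.shape[0]
    at_risk = np.zeros(n_t, dtype=int)
    d_all = np.zeros(n_t, dtype=int)
    d_j = {j: np.zeros(n_t, dtype=int) for j in causes}
    # at-risk counts subjects with follow-up >= s (ties: events and
    # censorings at s are still at risk just before s)
    for k, s in enumerate(times):
        at_risk[k] = int(np.sum(t >= s))
        here = t == s
        d_all[k] = int(np.sum(here & (cause > 0)))
        for j in causes:
            d_j[j][k] = int(np.sum(here & (cause == j)))

    km_prev = np.empty(n_t)        # KM(s-)
    km = np.empty(n_t)             # KM(s)
    running = 1.0
    for k in range(n_t):
        km_prev[k] = running
        running *= 1.0 - d_all[k] / at_risk[k]
        km[k] = running

    cif = {}
    var = {}
    for j in causes:
        jump = km_prev * d_j[j] / at_risk
        cif[j] = np.cumsum(jump)
        var[j] = _aalen_variance(cif[j], km_prev, at_risk, d_all, d_j[j])
    return AJEstimate(times, causes, cif, var, km, at_risk, d_j)


def _aalen_variance(cif_j, km_prev, n, d_all, dj) -> np.ndarray:
    """Klein-Moeschberger variance of the cause-j CIF at each event time."""
    n_t = cif_j.shape[0]
    out = np.empty(n_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n > d_all, d_all / (n * (n - d_all).astype(float)), 0.0)
    b = km_prev ** 2 * dj * (n - dj) / n.astype(float) ** 3
    c = km_prev * dj / n.astype(float) ** 2
    for k in range(n_t):
        diff = cif_j[k] - cif_j[: k + 1]
        out[k] = (np.sum(diff ** 2 * a[: k + 1]) + np.sum(b[: k + 1])
                  - 2.0 * np.sum(diff * c[: k + 1]))
    return np.maximum(out, 0.0)
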