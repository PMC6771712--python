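"""Clamped B-spline bases for log-baseline hazards and time-dependent effects.

The knot vector repeats each boundary knot ``degree + 1`` times, so a basis
with degree ``d`` and ``q`` internal knots has ``d + 1 + q`` functions that
form a partition of unity on the boundary interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "bspline_basis", "quantile_knots"]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a clamped B-spline basis.

    Parameters
    ----------
    degree
        Polynomial degree: 1 (linear), 2 (quadratic) or 3 (cubic).
    internal_knots
        Strictly increasing knot locations strictly inside the boundary
        interval, in time units (years).
    boundary
        ``(lower, upper)`` support of the basis; ``lower >= 0``.
    """

    degree: int
    internal_knots: tuple[float, ...] = ()
    boundary: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        object.__setattr__(self, "degree", int(self.degree))
        object.__setattr__(
            self, "internal_knots", tuple(float(k) for k in self.internal_knots)
        )
        object.__setattr__(
            self, "boundary", (float(self.boundary[0]), float(self.boundary[1]))
        )
        self._validate()

    def _validate(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")
        lo, hi = self.boundary
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or hi <= lo:
            raise ValueError(f"invalid boundary {self.boundary}: need 0 <= lower < upper")
        ik = np.asarray(self.internal_knots, dtype=float)
        if ik.size:
            if np.any(np.diff(ik) <= 0):
                raise ValueError("internal knots must be strictly increasing")
            if ik[0] <= lo or ik[-1] >= hi:
                raise ValueError(
                    f"internal knots {self.internal_knots} must lie strictly "
                    f"inside boundary {self.boundary}"
                )

    @property
    def n_basis(self) -> int:
        """Number of basis functions: degree + 1 + #internal knots."""
        return self.degree + 1 + len(self.internal_knots)

    @property
    def knot_vector(self) -> np.ndarray:
        """Full clamped knot vector with boundary knots repeated degree+1 times."""
        lo, hi = self.boundary
        return np.concatenate(
            [
                np.full(self.degree + 1, lo),
                np.asarray(self.internal_knots, dtype=float),
                np.full(self.degree + 1, hi),
            ]
        )

    def with_boundary(self, boundary: tuple[float, float]) -> "SplineSpec":
        return SplineSpec(self.degree, self.internal_knots, boundary)


def bspline_basis(t, spec: SplineSpec) -> np.ndarray:
    """Evaluate the clamped B-spline basis at times ``t``.

    Returns an array of shape ``(len(t), spec.n_basis)``.  Rows sum to one
    and all entries are non-negative.  Times outside the boundary interval
    raise a ``ValueError`` — the basis is never extrapolated silently.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.size == 0:
        return np.zeros((0, spec.n_basis))
    lo, hi = spec.boundary
    if np.any(t < lo) or np.any(t > hi):
        bad = t[(t < lo) | (t > hi)]
        raise ValueError(
            f"times {bad[:5]} outside spline boundary [{lo}, {hi}]; "
            "no extrapolation is performed"
        )
    out = BSpline.design_matrix(t, spec.knot_vector, spec.degree,
                                extrapolate=False).toarray()
    return out


def quantile_knots(event_times, probs) -> list[float]:
    """Empirical quantiles of event times to be used as internal knots.

    Uses the linear-interpolation quantile definition (numpy default,
    'linear' / type 7).  Raises if the resulting knots are not strictly
    increasing, which signals too many knots for the data at hand.
    """
    event_times = np.asarray(event_times, dtype=float)
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if event_times.size == 0:
        raise ValueError("event_times is empty")
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("quantile probabilities must lie strictly in (0, 1)")
    knots = np.quantile(event_times, probs, method="linear")
    if knots.size > 1 and np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"quantile knots {knots} are not strictly increasing; "
            "reduce the number of knots"
        )
    return [float(k) for k in knots]
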