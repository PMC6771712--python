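"""Gauss-Legendre quadrature used for all cumulative-hazard integrals."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["QuadratureRule", "gl_integrate"]


@lru_cache(maxsize=None)
def _leggauss(k: int):
    z, w = np.polynomial.legendre.leggauss(k)
    z.setflags(write=False)
    w.setflags(write=False)
    return z, w


@dataclass(frozen=True)
class QuadratureRule:
    """K-point Gauss-Legendre rule on [-1, 1].

    Exact for polynomials up to degree 2K-1; nodes are symmetric about 0
    and the weights sum to 2.
    """

    K: int = 20
    nodes: np.ndarray = field(init=False, repr=False, compare=False)
    weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("quadrature rule needs at least one node")
        z, w = _leggauss(int(self.K))
        object.__setattr__(self, "nodes", z)
        object.__setattr__(self, "weights", w)

    def map_to(self, a, b):
        """Nodes and weights mapped to [a, b] (broadcast over array a, b).

        Returns ``(points, weights)`` with a trailing axis of length K.
        """
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        half = (b - a) / 2.0
        mid = (a + b) / 2.0
        pts = mid[..., None] + half[..., None] * self.nodes
        wts = half[..., None] * self.weights
        return pts, wts


def gl_integrate(f, a: float, b: float, rule: QuadratureRule) -> float:
    """Integrate ``f`` on [a, b] with the given Gauss-Legendre rule."""
    if a > b:
        raise ValueError(f"integration bounds inverted: a={a} > b={b}")
    if a == b:
        return 0.0
    pts, wts = rule.map_to(float(a), float(b))
    return float(np.sum(wts * np.asarray(f(pts), dtype=float)))


def composite_map(rule: QuadratureRule, b, cuts=()):
    """Nodes and weights for integrals from 0 to ``b``, split at ``cuts``.

    Splitting at the interior knots of a spline model keeps every segment
    analytic, so Gauss-Legendre converges at machine precision with modest
    K.  ``b`` may be an array; cuts above ``b`` contribute zero-length
    segments with zero weight.  The trailing axis has length
    ``(len(cuts) + 1) * rule.K``.
    """
    b = np.asarray(b, dtype=float)
    cuts = np.sort(np.asarray(cuts, dtype=float))
    edges = [np.zeros(b.shape + (1,))]
    for c in cuts:
        edges.append(np.minimum(float(c), b)[..., None])
    edges.append(b[..., None])
    E = np.concatenate(edges, axis=-1)
    half = np.diff(E, axis=-1) / 2.0
    mid = (E[..., :-1] + E[..., 1:]) / 2.0
    pts = mid[..., None] + half[..., None] * rule.nodes
    wts = half[..., None] * rule.weights
    return pts.reshape(*b.shape, -1), wts.reshape(*b.shape, -1)
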