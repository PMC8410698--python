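"""Clamped B-spline basis systems on a closed interval.

A basis system is defined by its order ``O`` (polynomial degree ``O - 1``),
the number of basis functions ``K`` and a non-decreasing knot vector of
length ``K + O``.  The default builder produces a *clamped* knot vector
(boundary knots repeated ``O`` times, interior knots equally spaced), for
which the basis forms a partition of unity on the whole closed domain.

Evaluation follows the Cox–de Boor recursion with the usual conventions:
any 0/0 term in the recursion is taken as 0 (required for repeated knots),
and the half-open support indicators are closed at the right end of the
domain so the last grid point of a spectrum is representable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import roots_legendre

__all__ = ["BasisSystem", "build_basis", "evaluate_basis", "gram_matrix"]


@dataclass(frozen=True)
class BasisSystem:
    """A B-spline basis of ``n_basis`` functions of order ``order``.

    The domain is the closed interval ``[knots[order-1], knots[n_basis]]``.
    """

    order: int
    n_basis: int
    knots: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", knots)
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.n_basis < self.order:
            raise ValueError(
                f"need n_basis >= order, got K={self.n_basis} < O={self.order}"
            )
        if knots.ndim != 1 or len(knots) != self.n_basis + self.order:
            raise ValueError(
                f"knot vector must have K + O = {self.n_basis + self.order} "
                f"entries, got {len(knots)}"
            )
        if np.any(np.diff(knots) < 0):
            raise ValueError("knot vector must be non-decreasing")

    @property
    def domain(self) -> tuple[float, float]:
        return (float(self.knots[self.order - 1]), float(self.knots[self.n_basis]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BasisSystem):
            return NotImplemented
        return (
            self.order == other.order
            and self.n_basis == other.n_basis
            and np.array_equal(self.knots, other.knots)
        )

    def to_json(self) -> str:
        """Serialize order and knots (everything needed to rebuild)."""
        return json.dumps(
            {"order": self.order, "n_basis": self.n_basis, "knots": self.knots.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "BasisSystem":
        d = json.loads(text)
        return cls(order=d["order"], n_basis=d["n_basis"], knots=np.asarray(d["knots"]))


def build_basis(domain: tuple[float, float], n_basis: int, order: int = 4) -> BasisSystem:
    """Build a clamped B-spline basis with equally spaced interior knots.

    Parameters
    ----------
    domain : (lo, hi)
        Closed interval on which the basis lives; must be non-degenerate.
    n_basis : int
        Number of basis functions K; requires K >= order.
    order : int
        Spline order O (4 = cubic, the default used throughout).
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError(f"degenerate domain [{lo}, {hi}]")
    if n_basis < order:
        raise ValueError(f"need n_basis >= order, got K={n_basis} < O={order}")
    n_interior = n_basis - order
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([np.full(order, lo), interior, np.full(order, hi)])
    return BasisSystem(order=order, n_basis=n_basis, knots=knots)


def evaluate_basis(basis: BasisSystem, points: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions at ``points``; returns a |points| x K matrix.

    Points must lie inside the closed domain.  At the right endpoint the
    last basis function evaluates to 1 (closed-end convention).
    """
    pts = np.asarray(points, dtype=float)
    lo, hi = basis.domain
    if pts.size and (pts.min() < lo or pts.max() > hi):
        raise ValueError(
            f"evaluation points must lie in the basis domain [{lo}, {hi}]"
        )
    mat = BSpline.design_matrix(
        pts, basis.knots, basis.order - 1, extrapolate=False
    )
    return mat.toarray()


def gram_matrix(basis: BasisSystem) -> np.ndarray:
    """Matrix of L2 inner products W[k, l] = integral of phi_k * phi_l.

    Computed by a fixed-order Gauss–Legendre rule applied per knot span
    with O nodes, which is exact for the integrand (a piecewise polynomial
    of degree 2O - 2).  The result is symmetric PSD and banded: entries
    with |k - l| >= O vanish exactly because the supports are disjoint.
    """
    nodes, weights = roots_legendre(basis.order)
    # unique spans inside the domain
    lo, hi = basis.domain
    breaks = np.unique(basis.knots)
    breaks = breaks[(breaks >= lo) & (breaks <= hi)]
    K = basis.n_basis
    W = np.zeros((K, K))
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        x = mid + half * nodes
        phi = evaluate_basis(basis, x)  # len(nodes) x K
        W += half * (phi.T * weights) @ phi
    # enforce exact zeros outside the band and exact symmetry
    k_idx = np.arange(K)
    W[np.abs(k_idx[:, None] - k_idx[None, :]) >= basis.order] = 0.0
    return 0.5 * (W + W.T)
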