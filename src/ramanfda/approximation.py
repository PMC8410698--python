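"""Least-squares functional approximation of discrete spectra.

Each spectrum x_i, observed on a shared grid, is represented as a smooth
function x_i(t) = sum_k c_ik phi_k(t) in a B-spline basis.  Coefficients
minimize the per-spectrum sum of squared errors against the observed
points, solved by an orthogonal-decomposition least-squares routine (the
normal-equations form exists only as a test oracle).

The number of basis functions K is chosen by the elbow method on the
RMSE-vs-K curve: the candidate whose (K, RMSE) point lies farthest from
the chord joining the first and last candidates, with both axes min-max
normalized first so that counts and errors are commensurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .bspline import BasisSystem, build_basis, evaluate_basis

__all__ = ["FunctionalDataset", "fit_functional", "evaluate_functional", "elbow_select"]


@dataclass
class FunctionalDataset:
    """Functional representation of N spectra: coefficients tied to a basis."""

    basis: BasisSystem
    coefficients: np.ndarray  # N x K
    labels: np.ndarray
    batches: np.ndarray | None
    fit_sse: np.ndarray  # per-spectrum sum of squared residuals

    @property
    def n_spectra(self) -> int:
        return self.coefficients.shape[0]


def fit_functional(spectra, basis: BasisSystem) -> FunctionalDataset:
    """Fit every spectrum by least squares in the given basis.

    Requires the spectra grid to lie inside the basis domain and the
    grid-evaluated design matrix to have full column rank (K <= p with
    equally spaced clamped knots).
    """
    phi = evaluate_basis(basis, spectra.grid)  # p x K
    p, K = phi.shape
    if K > p:
        raise ValueError(
            f"design matrix is rank deficient: K = {K} basis functions for "
            f"p = {p} grid points"
        )
    coef, _, rank, _ = scipy.linalg.lstsq(phi, spectra.intensities.T)
    if rank < K:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < K = {K}); "
            f"reduce the number of basis functions (p = {p})"
        )
    coef = coef.T  # N x K
    resid = spectra.intensities - coef @ phi.T
    sse = np.sum(resid**2, axis=1)
    return FunctionalDataset(
        basis=basis,
        coefficients=coef,
        labels=np.asarray(spectra.labels),
        batches=None if spectra.batches is None else np.asarray(spectra.batches),
        fit_sse=sse,
    )


def evaluate_functional(fd: FunctionalDataset, points: np.ndarray) -> np.ndarray:
    """Evaluate all N functions at ``points``; returns an N x |points| matrix."""
    phi = evaluate_basis(fd.basis, points)
    return fd.coefficients @ phi.T


def elbow_select(spectra, candidate_ks, order: int = 4) -> int:
    """Pick the number of basis functions by the elbow of the RMSE curve.

    RMSE(K) is pooled over all spectra and grid points.  Both the K axis
    and the RMSE axis are min-max normalized to [0, 1], then the candidate
    maximizing perpendicular distance to the line through the first and
    last points is returned; ties go to the smallest K.
    """
    ks = np.asarray(list(candidate_ks), dtype=int)
    if len(ks) < 3:
        raise ValueError("need at least 3 candidate basis sizes")
    if np.any(np.diff(ks) <= 0):
        raise ValueError("candidate basis sizes must be strictly ascending")
    rmse = np.empty(len(ks), dtype=float)
    domain = (float(spectra.grid[0]), float(spectra.grid[-1]))
    n_total = spectra.intensities.size
    for i, k in enumerate(ks):
        fd = fit_functional(spectra, build_basis(domain, int(k), order))
        rmse[i] = np.sqrt(fd.fit_sse.sum() / n_total)
    return int(ks[_elbow_index(ks.astype(float), rmse)])


def _elbow_index(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the point farthest from the chord, after min-max scaling."""

    def norm(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    xn, yn = norm(x), norm(y)
    p0 = np.array([xn[0], yn[0]])
    p1 = np.array([xn[-1], yn[-1]])
    d = p1 - p0
    nrm = np.hypot(*d)
    if nrm == 0:
        return 0
    # perpendicular distance of each point to the chord; distances within
    # numerical noise of the maximum tie, and ties go to the smallest K
    dist = np.abs(d[0] * (p0[1] - yn) - d[1] * (p0[0] - xn)) / nrm
    return int(np.flatnonzero(dist >= dist.max() - 1e-12)[0])
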