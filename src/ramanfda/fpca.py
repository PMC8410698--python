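"""Functional principal component analysis in coefficient space.

For functions x_i(t) = sum_k c_ik phi_k(t) the covariance-operator
eigenproblem V beta = rho beta is solved exactly via the basis Gram matrix
W (entries integral phi_k phi_l): with centered coefficients C~ the
symmetric matrix (1/N) W^{1/2} C~' C~ W^{1/2} has the operator's
eigenvalues, and an eigenvector u maps back to the eigenfunction
coefficient vector b = W^{-1/2} u.  Eigenfunctions are orthonormal in the
functional inner product (b_j' W b_l = delta_jl, i.e. integral beta^2 = 1)
and scores are the functional inner products f_ij = (C_i - mean)' W b_j.

Because the sample covariance operator of N functions has rank at most
N - 1 after centering, at most N - 1 eigenvalues are nonzero.

Centering is the default; ``center=False`` computes the covariance of the
raw (uncentered) functions instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .bspline import BasisSystem, gram_matrix
from .approximation import FunctionalDataset

__all__ = ["FPCAModel", "ScoreMatrix", "fpca_fit", "fpca_scores"]

#: Eigenvalues of W below this floor are clipped when forming W^{+/-1/2}.
GRAM_EIGENVALUE_FLOOR = 1e-12


@dataclass
class ScoreMatrix:
    """N x m component scores plus a tag naming the producing method."""

    scores: np.ndarray
    origin: str  # "fpca" or "pca"


@dataclass
class FPCAModel:
    basis: BasisSystem
    mean_coefficients: np.ndarray  # K
    eigenfunction_coefficients: np.ndarray  # m x K, rows b_j
    eigenvalues: np.ndarray  # m, non-increasing
    gram: np.ndarray  # K x K, cached for scoring
    centered: bool
    #: all K operator eigenvalues (non-increasing); at most N - 1 are nonzero
    full_eigenvalues: np.ndarray | None = None


def _gram_sqrt(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric W^{1/2} and W^{-1/2} via eigendecomposition with a floor."""
    vals, vecs = scipy.linalg.eigh(W)
    vals = np.maximum(vals, GRAM_EIGENVALUE_FLOOR)
    root = np.sqrt(vals)
    return (vecs * root) @ vecs.T, (vecs / root) @ vecs.T


def _fix_signs(B: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(B), axis=1)
    signs = np.sign(B[np.arange(B.shape[0]), idx])
    signs[signs == 0] = 1.0
    return B * signs[:, None]


def fpca_fit(fd: FunctionalDataset, n_components: int, center: bool = True) -> FPCAModel:
    """Fit an FPCA model with ``n_components`` leading eigenfunctions."""
    C = fd.coefficients
    N, K = C.shape
    if N < 2:
        raise ValueError("need at least 2 functions")
    max_m = min(K, N - 1) if center else min(K, N)
    if n_components > max_m:
        raise ValueError(
            f"n_components = {n_components} exceeds the covariance rank bound "
            f"{max_m} (N = {N} functions, K = {K} basis functions)"
        )
    mean = C.mean(axis=0) if center else np.zeros(K)
    Ct = C - mean
    W = gram_matrix(fd.basis)
    Whalf, Wihalf = _gram_sqrt(W)
    M = (Whalf @ (Ct.T @ Ct) @ Whalf) / N
    M = 0.5 * (M + M.T)
    vals, vecs = scipy.linalg.eigh(M)
    full = np.maximum(vals[::-1], 0.0)
    order = np.argsort(vals)[::-1][:n_components]
    rho = np.maximum(vals[order], 0.0)
    B = (Wihalf @ vecs[:, order]).T  # m x K
    B = _fix_signs(B)
    return FPCAModel(
        basis=fd.basis,
        mean_coefficients=mean,
        eigenfunction_coefficients=B,
        eigenvalues=rho,
        gram=W,
        centered=center,
        full_eigenvalues=full,
    )


def fpca_scores(model: FPCAModel, fd: FunctionalDataset) -> ScoreMatrix:
    """Project functions onto the eigenfunctions: f_ij = <x_i - mean, beta_j>."""
    if fd.basis != model.basis:
        raise ValueError("functional dataset basis differs from the model basis")
    Ct = fd.coefficients - model.mean_coefficients
    scores = Ct @ model.gram @ model.eigenfunction_coefficients.T
    return ScoreMatrix(scores=scores, origin="fpca")
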