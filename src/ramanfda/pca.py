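"""Classical PCA on discrete spectra — the baseline arm of the comparison.

Loadings are the leading eigenvectors of the sample covariance
(1/N) X~' X~ of the mean-centered rows, computed from a thin SVD of the
centered matrix (contract-equivalent to the covariance eigenproblem and
numerically preferable).  The 1/N population convention matches the
functional arm's covariance operator, so the two arms see identical
conventions everywhere except the inner product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .fpca import ScoreMatrix, _fix_signs

__all__ = ["PCAModel", "pca_fit", "pca_project"]


@dataclass
class PCAModel:
    mean: np.ndarray  # p
    loadings: np.ndarray  # m x p, orthonormal rows
    eigenvalues: np.ndarray  # m, non-increasing


def pca_fit(spectra, n_components: int) -> PCAModel:
    """Fit PCA with ``n_components`` leading directions on the spectra rows."""
    X = spectra.intensities
    N, p = X.shape
    if N < 2:
        raise ValueError("need at least 2 spectra")
    if n_components > min(p, N - 1):
        raise ValueError(
            f"n_components = {n_components} exceeds min(p, N - 1) = {min(p, N - 1)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    loadings = _fix_signs(Vt[:n_components])
    eigenvalues = (s[:n_components] ** 2) / N
    return PCAModel(mean=mean, loadings=loadings, eigenvalues=eigenvalues)


def pca_project(model: PCAModel, spectra) -> ScoreMatrix:
    """Scores of (possibly held-out) spectra: (x - mean) @ loadings'."""
    X = spectra.intensities
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"spectra have {X.shape[1]} points but the model expects "
            f"{model.mean.shape[0]}"
        )
    return ScoreMatrix(scores=(X - model.mean) @ model.loadings.T, origin="pca")
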