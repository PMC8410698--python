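"""Linear discriminant analysis on principal-component scores.

Fisher's LDA: between-class scatter B = sum_l n_l (m_l - m)(m_l - m)' and
within-class scatter W = sum_l sum_{i in l} (x_i - m_l)(x_i - m_l)'.  The
L - 1 discriminant directions are the leading eigenvectors of W^{-1} B,
solved stably by Cholesky whitening of W followed by a symmetric
eigen-solve.  The bias is chosen as b0 = -Omega m so discriminant
coordinates are centered at the overall mean.

Classification uses the equal-prior linear Gaussian rule: each sample is
assigned the class minimizing the Mahalanobis distance to the class mean
under the pooled within-class covariance; ties go to the lexicographically
smallest label.  No automatic regularization is applied — a singular
within-scatter raises, with an optional explicit ridge escape hatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .fpca import ScoreMatrix

__all__ = ["LDAModel", "lda_fit", "lda_predict"]


@dataclass
class LDAModel:
    class_labels: np.ndarray  # L sorted distinct labels
    class_means: np.ndarray  # L x m
    overall_mean: np.ndarray  # m
    within_scatter: np.ndarray  # m x m
    between_scatter: np.ndarray  # m x m
    directions: np.ndarray  # (L - 1) x m, rows of Omega
    bias: np.ndarray  # L - 1
    counts: np.ndarray  # L
    # Cholesky factor of the pooled within covariance, cached for prediction
    _pooled_chol: np.ndarray | None = None


def lda_fit(scores: ScoreMatrix | np.ndarray, labels, ridge: float = 0.0) -> LDAModel:
    """Fit LDA on an N x m score matrix with N class labels."""
    X = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    X = np.atleast_2d(X)
    labels = np.asarray(labels)
    N, m = X.shape
    classes, inv = np.unique(labels, return_inverse=True)
    L = len(classes)
    if L < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(inv, minlength=L)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")

    overall = X.mean(axis=0)
    means = np.stack([X[inv == l].mean(axis=0) for l in range(L)])
    dm = means - overall
    B = (dm.T * counts) @ dm
    Xc = X - means[inv]
    W = Xc.T @ Xc
    if ridge > 0:
        W = W + ridge * np.eye(m)

    try:
        chol = scipy.linalg.cholesky(W, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"within-class scatter is singular at m = {m} score dimensions; "
            "reduce the number of components (or pass an explicit ridge)"
        ) from exc

    # whiten: solve chol Y = B chol^{-T}, eigen-decompose the symmetric result
    Y = scipy.linalg.solve_triangular(chol, B, lower=True)
    S = scipy.linalg.solve_triangular(chol, Y.T, lower=True)
    S = 0.5 * (S + S.T)
    vals, vecs = scipy.linalg.eigh(S)
    order = np.argsort(vals)[::-1][: L - 1]
    # map whitened eigenvectors back: omega = chol^{-T} u, then scale each
    # discriminant direction to unit Euclidean norm (predictions are
    # invariant to the scaling; unit norm makes the directions comparable)
    omega = scipy.linalg.solve_triangular(chol.T, vecs[:, order], lower=False).T
    omega = omega / np.linalg.norm(omega, axis=1, keepdims=True)

    pooled = W / (N - L)
    pooled_chol = scipy.linalg.cholesky(pooled, lower=True)
    return LDAModel(
        class_labels=classes,
        class_means=means,
        overall_mean=overall,
        within_scatter=W,
        between_scatter=B,
        directions=omega,
        bias=-omega @ overall,
        counts=counts,
        _pooled_chol=pooled_chol,
    )


def lda_predict(model: LDAModel, scores: ScoreMatrix | np.ndarray) -> np.ndarray:
    """Assign each row the class with minimal pooled-Mahalanobis distance."""
    X = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    X = np.atleast_2d(X)
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"scores have {X.shape[1]} dimensions but the model expects "
            f"{model.class_means.shape[1]}"
        )
    d2 = np.empty((X.shape[0], len(model.class_labels)))
    for l, mu in enumerate(model.class_means):
        z = scipy.linalg.solve_triangular(
            model._pooled_chol, (X - mu).T, lower=True
        )
        d2[:, l] = np.sum(z**2, axis=0)
    # argmin picks the first minimizer; class_labels are sorted, so ties go
    # to the lexicographically smallest label
    return model.class_labels[np.argmin(d2, axis=1)]


def discriminant_coordinates(model: LDAModel, scores) -> np.ndarray:
    """LD = Omega beta + b0: project scores onto the discriminant axes."""
    X = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    return X @ model.directions.T + model.bias
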