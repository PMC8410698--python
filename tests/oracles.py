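"""Independent brute-force oracles, written separately from the package.

Each function here recomputes a quantity by the most direct definition
available (explicit recursions, normal equations, dense-grid quadrature,
exhaustive rank/distance computations) so the production paths can be
checked against an implementation that shares no code with them.
"""

import numpy as np


def cox_de_boor(knots, k, order, t, domain_right):
    """phi_{k,order}(t) by the literal recursion, one point at a time.

    Zero-denominator terms are 0; the support indicator is half-open
    except that the interval ending at the right domain endpoint is
    closed there.
    """
    knots = np.asarray(knots, dtype=float)
    if order == 1:
        if knots[k] <= t < knots[k + 1]:
            return 1.0
        # closed right end: the last nonempty interval contains the endpoint
        if t == domain_right and knots[k] < knots[k + 1] == domain_right:
            return 1.0
        return 0.0
    left = 0.0
    denom = knots[k + order - 1] - knots[k]
    if denom > 0:
        left = (t - knots[k]) / denom * cox_de_boor(knots, k, order - 1, t, domain_right)
    right = 0.0
    denom = knots[k + order] - knots[k + 1]
    if denom > 0:
        right = (
            (knots[k + order] - t)
            / denom
            * cox_de_boor(knots, k + 1, order - 1, t, domain_right)
        )
    return left + right


def basis_matrix(basis, points):
    """Dense basis evaluation via the recursion above."""
    right = basis.domain[1]
    return np.array(
        [
            [cox_de_boor(basis.knots, k, basis.order, t, right) for k in range(basis.n_basis)]
            for t in np.asarray(points, dtype=float)
        ]
    )


def normal_equations_coefficients(phi, x):
    """Least-squares coefficients via the explicit normal equations."""
    return np.linalg.solve(phi.T @ phi, phi.T @ x)


def gram_trapezoid(basis, n_grid=20001):
    """Gram matrix by trapezoid-rule quadrature on a dense grid."""
    lo, hi = basis.domain
    t = np.linspace(lo, hi, n_grid)
    phi = basis_matrix_fast(basis, t)
    w = np.full(n_grid, (hi - lo) / (n_grid - 1))
    w[0] /= 2
    w[-1] /= 2
    return (phi.T * w) @ phi


def basis_matrix_fast(basis, points):
    """Vectorized bottom-up recursion (still independent of the package)."""
    t = np.asarray(points, dtype=float)
    knots = basis.knots
    right = basis.domain[1]
    n_funcs = len(knots) - 1
    B = np.zeros((len(t), n_funcs))
    for k in range(n_funcs):
        B[:, k] = (knots[k] <= t) & (t < knots[k + 1])
        if knots[k] < knots[k + 1] == right:
            B[t == right, k] = 1.0
    for o in range(2, basis.order + 1):
        Bn = np.zeros((len(t), len(knots) - o))
        for k in range(len(knots) - o):
            d1 = knots[k + o - 1] - knots[k]
            if d1 > 0:
                Bn[:, k] += (t - knots[k]) / d1 * B[:, k]
            d2 = knots[k + o] - knots[k + 1]
            if d2 > 0:
                Bn[:, k] += (knots[k + o] - t) / d2 * B[:, k + 1]
        B = Bn
    return B[:, : basis.n_basis]


def dense_grid_fpca(fd_evaluator, coefficients_n, domain, n_components, n_grid=10001):
    """FPCA by quadrature-weighted discrete PCA on a dense evaluation grid.

    ``fd_evaluator(points)`` must return the N x |points| function values.
    Returns (eigenvalues, scores) with score columns sign-aligned to have
    a positive largest-magnitude first entry column-wise left to callers.
    """
    lo, hi = domain
    t = np.linspace(lo, hi, n_grid)
    F = fd_evaluator(t)
    w = np.full(n_grid, (hi - lo) / (n_grid - 1))
    w[0] /= 2
    w[-1] /= 2
    Fc = F - F.mean(axis=0)
    Y = Fc * np.sqrt(w)
    _, s, vt = np.linalg.svd(Y, full_matrices=False)
    eigenvalues = (s**2) / coefficients_n
    scores = Y @ vt[:n_components].T
    return eigenvalues[:n_components], scores


def kruskal_wallis_bruteforce(a, b):
    """H statistic from first principles: average ranks plus tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1  # average rank, 1-based
        i = j
    ra, rb = ranks[: len(a)], ranks[len(a):]
    h = 12.0 / (n * (n + 1)) * (
        len(a) * (ra.mean() - (n + 1) / 2) ** 2
        + len(b) * (rb.mean() - (n + 1) / 2) ** 2
    )
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def mahalanobis_predict(means, labels, pooled_cov, X):
    """Assign each row of X the label with minimal Mahalanobis distance."""
    inv = np.linalg.inv(pooled_cov)
    out = []
    for x in np.atleast_2d(X):
        d = [(x - mu) @ inv @ (x - mu) for mu in means]
        out.append(labels[int(np.argmin(d))])
    return np.array(out)


def covariance_pca(X, n_components):
    """PCA by explicit eigendecomposition of the 1/N sample covariance."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / X.shape[0]
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1][:n_components]
    return vals[order], vecs[:, order].T
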