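"""L1-penalized regression solvers used by the stability-selection stage.

Coordinate descent with active-set updates and warm starts along a
descending penalty path.  Only the support (which coefficients are
nonzero) matters downstream, but the solvers converge to the penalized
optimum and are cross-checked against closed forms and scikit-learn in
the test suite.

Objectives (X is expected column-standardized, n = len(y)):

* logistic:  -(1/n) * sum_i [y_i eta_i - log(1 + exp(eta_i))] + lam * ||b||_1
* linear:    (1/(2n)) * ||y - b0 - X b||^2 + lam * ||b||_1

The intercept is never penalized.  The logistic path kernel is compiled
with numba when available; a pure-numpy fallback keeps behaviour
identical (just slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "soft_threshold",
    "logistic_lambda_max",
    "logistic_lasso_path",
    "linear_lasso",
    "standardize_columns",
]


def soft_threshold(z: float, lam: float) -> float:
    """S(z, lam) = sign(z) * max(|z| - lam, 0)."""
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Center and scale columns to unit (population) sd.

    Zero-variance columns are mapped to all-zero columns so that their
    coefficients can never leave zero.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = X - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def logistic_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the penalized logistic fit is fully shrunk.

    At the intercept-only optimum p_hat = mean(y), so the KKT bound is
    max_j |x_j'(y - ybar)| / n.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    r = y - y.mean()
    return float(np.max(np.abs(X.T @ r)) / n)


@njit(cache=True)
def _logistic_path_kernel(X, y, lambdas, tol, max_sweeps, coefs, icepts):  # pragma: no cover - compiled
    # IRLS with an inner penalized weighted-least-squares coordinate
    # descent (the glmnet scheme) plus active-set/KKT screening.
    n, p = X.shape
    nlam = lambdas.shape[0]
    b = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    pr = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)  # weighted working residual z - b0 - Xb
    active = np.zeros(p, dtype=np.bool_)
    wx2 = np.empty(p)

    for li in range(nlam):
        lam = lambdas[li]
        for _kkt in range(100):
            idx = np.flatnonzero(active)
            for _outer in range(50):
                # quadratic approximation at current eta
                for i in range(n):
                    e = eta[i]
                    if e >= 0.0:
                        pr[i] = 1.0 / (1.0 + np.exp(-e))
                    else:
                        ex = np.exp(e)
                        pr[i] = ex / (1.0 + ex)
                    wi = pr[i] * (1.0 - pr[i])
                    if wi < 1e-6:
                        wi = 1e-6
                    w[i] = wi
                    # r = z - eta where z = eta + (y - pr)/w
                    r[i] = (y[i] - pr[i]) / wi
                wsum = 0.0
                for i in range(n):
                    wsum += w[i]
                for k in range(idx.shape[0]):
                    j = idx[k]
                    s = 0.0
                    for i in range(n):
                        s += w[i] * X[i, j] * X[i, j]
                    wx2[j] = s / n
                outer_delta = 0.0
                for _sweep in range(max_sweeps):
                    delta = 0.0
                    # intercept (unpenalized)
                    num = 0.0
                    for i in range(n):
                        num += w[i] * r[i]
                    d0 = num / wsum
                    if d0 != 0.0:
                        b0 += d0
                        for i in range(n):
                            r[i] -= d0
                        if abs(d0) > delta:
                            delta = abs(d0)
                    for k in range(idx.shape[0]):
                        j = idx[k]
                        g = 0.0
                        for i in range(n):
                            g += w[i] * X[i, j] * r[i]
                        g /= n
                        u = wx2[j] * b[j] + g
                        if u > lam:
                            bj = (u - lam) / wx2[j]
                        elif u < -lam:
                            bj = (u + lam) / wx2[j]
                        else:
                            bj = 0.0
                        d = bj - b[j]
                        if d != 0.0:
                            b[j] = bj
                            for i in range(n):
                                r[i] -= d * X[i, j]
                            if abs(d) > delta:
                                delta = abs(d)
                    if delta > outer_delta:
                        outer_delta = delta
                    if delta < tol:
                        break
                # rebuild eta from the working residual shift
                # eta_new = z - r = (eta_old + (y-pr)/w) - r
                for i in range(n):
                    eta[i] = eta[i] + (y[i] - pr[i]) / w[i] - r[i]
                if outer_delta < tol:
                    break
            # full KKT pass over inactive coordinates at the true gradient
            for i in range(n):
                e = eta[i]
                if e >= 0.0:
                    pr[i] = 1.0 / (1.0 + np.exp(-e))
                else:
                    ex = np.exp(e)
                    pr[i] = ex / (1.0 + ex)
            nviol = 0
            for j in range(p):
                if not active[j]:
                    g = 0.0
                    for i in range(n):
                        g += X[i, j] * (y[i] - pr[i])
                    g /= n
                    if abs(g) > lam * (1.0 + 1e-9):
                        active[j] = True
                        nviol += 1
            if nviol == 0:
                break
        for j in range(p):
            active[j] = b[j] != 0.0
            coefs[j, li] = b[j]
        icepts[li] = b0


def logistic_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-6,
    max_sweeps: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the penalized logistic objective along a descending grid.

    Majorize-minimize coordinate descent (curvature bound 1/4 for the
    logistic loss on standardized columns) with an active-set strategy:
    sweep the current active set to convergence, then run a full KKT
    pass and absorb any violators.

    Returns ``(coefs, intercepts)`` with ``coefs`` of shape
    ``(p, len(lambdas))``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty penalty grid")
    if np.any(lambdas <= 0) or np.any(np.diff(lambdas) > 0):
        raise ValueError("penalty grid must be positive and non-increasing")
    ybar = y.mean()
    if not (0.0 < ybar < 1.0):
        raise ValueError("outcome has a single class")
    coefs = np.zeros((X.shape[1], lambdas.size))
    icepts = np.zeros(lambdas.size)
    _logistic_path_kernel(X, y, lambdas, tol, max_sweeps, coefs, icepts)
    return coefs, icepts


def linear_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-10,
    max_sweeps: int = 10000,
    fit_intercept: bool = True,
) -> tuple[np.ndarray, float]:
    """Coordinate descent for the linear-lasso objective at a single penalty.

    On an orthonormal design (x'x/n = 1) with a centered response the
    solution is the soft-thresholded OLS estimate; the test suite pins
    this closed form.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if lam < 0:
        raise ValueError("negative penalty")
    colsq = (X * X).sum(axis=0) / n
    b = np.zeros(p)
    b0 = float(y.mean()) if fit_intercept else 0.0
    r = y - b0  # residual y - b0 - Xb
    for _ in range(max_sweeps):
        delta = 0.0
        if fit_intercept:
            d0 = float(r.mean())
            if d0 != 0.0:
                b0 += d0
                r -= d0
                delta = max(delta, abs(d0))
        for j in range(p):
            if colsq[j] == 0.0:
                continue
            u = colsq[j] * b[j] + float(X[:, j] @ r) / n
            bj = soft_threshold(u, lam) / colsq[j]
            d = bj - b[j]
            if d != 0.0:
                b[j] = bj
                r -= d * X[:, j]
                delta = max(delta, abs(d))
        if delta < tol:
            return b, b0
    return b, b0
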