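"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, pairwise regressions,
ECDF scans) and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ks_D_bruteforce(a, b) -> float:
    """sup |ECDF_a - ECDF_b| by scanning every observed point."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = np.mean(a <= t)
        fb = np.mean(b <= t)
        best = max(best, abs(fa - fb))
    return best


def kmo_bruteforce(X) -> float:
    """KMO via explicit partial correlations from pairwise residual regressions."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    R = np.corrcoef(Z, rowvar=False)
    r2 = q2 = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            others = [k for k in range(p) if k not in (i, j)]
            if others:
                A = Z[:, others]
                coef_i, *_ = np.linalg.lstsq(A, Z[:, i], rcond=None)
                coef_j, *_ = np.linalg.lstsq(A, Z[:, j], rcond=None)
                ri = Z[:, i] - A @ coef_i
                rj = Z[:, j] - A @ coef_j
            else:
                ri, rj = Z[:, i], Z[:, j]
            q = np.corrcoef(ri, rj)[0, 1]
            r2 += R[i, j] ** 2
            q2 += q**2
    return r2 / (r2 + q2)


def bartlett_bruteforce(X):
    """Bartlett sphericity chi-square from the determinant, written longhand."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(np.linalg.det(R))
    df = p * (p - 1) // 2
    return chi2, df, stats.chi2.sf(chi2, df)


def regression_metrics_bruteforce(y, yhat):
    """R^2 / RMSE / RPD with explicit loops."""
    y = list(map(float, y))
    yhat = list(map(float, yhat))
    n = len(y)
    ybar = sum(y) / n
    ss_res = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    r2 = 1 - ss_res / ss_tot
    rmse = (ss_res / n) ** 0.5
    sd = (ss_tot / (n - 1)) ** 0.5
    return r2, rmse, sd / rmse


def cwt_bruteforce(values, kernel):
    """Per-spectrum correlation with a kernel under symmetric (half-sample)
    boundary reflection, via explicit index arithmetic."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    half = (len(kernel) - 1) // 2
    n, L = values.shape
    out = np.zeros_like(values)

    def reflect(idx: int) -> int:
        # half-sample symmetry: ... x1 x0 | x0 x1 ... xL-1 | xL-1 xL-2 ...
        while idx < 0 or idx >= L:
            if idx < 0:
                idx = -idx - 1
            else:
                idx = 2 * L - idx - 1
        return idx

    for s in range(n):
        for j in range(L):
            acc = 0.0
            for k, w in enumerate(kernel):
                acc += values[s, reflect(j - half + k)] * w
            out[s, j] = acc
    return out


def exact_correlation_data(R_target, n: int, seed: int = 0) -> np.ndarray:
    """Data whose *sample* correlation matrix equals R_target exactly.

    Draw noise, empirically whiten it, then color with the Cholesky factor.
    """
    R_target = np.asarray(R_target, dtype=float)
    p = R_target.shape[0]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = X - X.mean(axis=0)
    cov = X.T @ X / n
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T  # exact identity covariance
    return X @ np.linalg.cholesky(R_target).T
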