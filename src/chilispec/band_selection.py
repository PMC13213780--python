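"""Characteristic-wavelength screening: KMO/Bartlett, PCA, composite scores
and backward stepwise regression.

The screening logic follows the classical chemometrics recipe: verify PCA
applicability (sampling adequacy and sphericity of the band correlation
matrix), compress the spectra into a variance-weighted composite score of the
leading principal components, then regress that score on the individual band
reflectances and prune predictors backward until every survivor is
significant.  The surviving wavelengths are the characteristic bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

from .preprocess import SpectrumTable

__all__ = [
    "BandSelectionResult",
    "kmo_measure",
    "bartlett_sphericity",
    "pca_decompose",
    "composite_score",
    "backward_stepwise",
    "select_bands",
]

_RIDGE_EPS = 1e-8  # stabilises the inverse of near-singular correlation matrices


@dataclass
class BandSelectionResult:
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # p x k
    composite_scores: np.ndarray  # per sample
    selected_wavelengths_nm: list[float]
    stepwise_r: float
    stepwise_r2: float
    stepwise_pvalues: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kmo": self.kmo,
            "bartlett_chi2": self.bartlett_chi2,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
            "explained_variance_ratio": list(map(float, self.explained_variance_ratio)),
            "loadings": self.loadings.tolist(),
            "composite_scores": self.composite_scores.tolist(),
            "selected_wavelengths_nm": list(map(float, self.selected_wavelengths_nm)),
            "stepwise_r": self.stepwise_r,
            "stepwise_r2": self.stepwise_r2,
            "stepwise_pvalues": {str(k): float(v) for k, v in self.stepwise_pvalues.items()},
        }


def _correlation_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero variance feature")
    return np.corrcoef(X, rowvar=False)


def kmo_measure(X) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are the
    anti-image partial correlations obtained from the inverse correlation
    matrix.  A small ridge keeps the inverse finite for the near-singular
    correlation matrices that heavily collinear band sets produce.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 features")
    R = _correlation_matrix(X)
    # ridge only when R is near-singular (collinear bands), so well-conditioned
    # inputs are computed exactly
    if np.linalg.cond(R) > 1e10:
        R_inv_target = R + _RIDGE_EPS * np.eye(R.shape[0])
    else:
        R_inv_target = R
    S = np.linalg.inv(R_inv_target)
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    Q = -S / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(X) -> tuple[float, int, float]:
    """Bartlett's test of sphericity of the feature correlation matrix.

    chi2 = -(n - 1 - (2p + 5) / 6) * ln det(R), df = p (p - 1) / 2.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    R = _correlation_matrix(X)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError(
            "singular correlation matrix; consider a ridge on R before retrying"
        )
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def pca_decompose(X, k: int):
    """PCA of standardized features with a deterministic sign convention.

    Returns (loadings p x k, scores n x k, explained variance ratios).  Each
    component is flipped so its largest-magnitude loading is positive.
    Standardizing first means the decomposition acts on the correlation
    matrix, matching the KMO/Bartlett framing.
    """
    X = np.asarray(X, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(X.shape):
        raise ValueError("k exceeds min(n, p)")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero variance feature")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()  # p x k
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores, pca.explained_variance_ratio_.copy()


def composite_score(scores, ratios, k: int = 2) -> np.ndarray:
    """Variance-ratio weighted mean of the leading component scores:
    F_i = sum_{j<=k} ratio_j * score_ij / sum_{j<=k} ratio_j."""
    scores = np.asarray(scores, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if k > scores.shape[1] or k > ratios.size:
        raise ValueError("k exceeds the number of components")
    w = ratios[:k]
    if w.sum() == 0:
        raise ValueError("ratio sum is zero")
    return scores[:, :k] @ w / w.sum()


def backward_stepwise(F, X_bands, wavelengths_nm, alpha_remove: float = 0.05,
                      max_bands: int | None = None):
    """Backward elimination of band predictors against the composite score.

    Starts from all bands and repeatedly drops the predictor with the largest
    p-value above ``alpha_remove`` (or, if ``max_bands`` is set, keeps pruning
    the least significant predictor until at most that many survive), refitting
    after each removal.  Returns (selected wavelengths, multiple r, R^2,
    p-values of the survivors).
    """
    F = np.asarray(F, dtype=float)
    X = np.asarray(X_bands, dtype=float)
    wl = [float(w) for w in np.asarray(wavelengths_nm, dtype=float)]
    if not 0 < alpha_remove < 1:
        raise ValueError("alpha_remove must be in (0, 1)")
    keep = list(range(X.shape[1]))
    while keep:
        model = sm.OLS(F, sm.add_constant(X[:, keep])).fit()
        pvals = model.pvalues[1:]  # skip intercept
        worst = int(np.argmax(pvals))
        over_alpha = pvals[worst] > alpha_remove
        over_cap = max_bands is not None and len(keep) > max_bands
        if over_alpha or over_cap:
            del keep[worst]
            continue
        fitted = model.fittedvalues
        r = float(np.corrcoef(F, fitted)[0, 1])
        return (
            [wl[i] for i in keep],
            r,
            float(model.rsquared),
            {wl[i]: float(p) for i, p in zip(keep, pvals)},
        )
    raise ValueError("empty model: no predictor survives backward elimination")


def select_bands(table: SpectrumTable, n_pcs: int = 2, alpha_remove: float = 0.05,
                 max_bands: int | None = None) -> BandSelectionResult:
    """Full screening pipeline on a spectrum table.

    KMO + Bartlett gate interpretation only (the result records them; no hard
    threshold is enforced), PCA + composite score compress the spectra, and
    backward stepwise regression returns the characteristic wavelengths.
    """
    X = table.values
    kmo = kmo_measure(X)
    chi2, df, pval = bartlett_sphericity(X)
    loadings, scores, ratios = pca_decompose(X, n_pcs)
    F = composite_score(scores, ratios, k=n_pcs)
    selected, r, r2, pvalues = backward_stepwise(
        F, X, table.wavelengths_nm, alpha_remove=alpha_remove, max_bands=max_bands
    )
    return BandSelectionResult(
        kmo=kmo,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
        explained_variance_ratio=ratios,
        loadings=loadings,
        composite_scores=F,
        selected_wavelengths_nm=selected,
        stepwise_r=r,
        stepwise_r2=r2,
        stepwise_pvalues=pvalues,
    )
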