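"""Spectra/chemistry containers, I/O, wavelet preprocessing, splitting and the
composite red index (CRI).

The pipeline contract is mean reflectance per sample over a fixed wavelength
grid.  Preprocessing is a single-scale continuous wavelet transform (Mexican
hat by default) that removes smooth baseline structure, followed by per-band
min-max normalization whose statistics are fit on the calibration set only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import stats

__all__ = [
    "SpectrumTable",
    "ChemistryTable",
    "SplitAssignment",
    "read_spectra",
    "write_spectra",
    "read_chemistry",
    "write_chemistry",
    "cwt_preprocess",
    "MinMaxNormalizer",
    "minmax_normalize",
    "stratified_split",
    "ks_two_sample",
    "compute_cri",
    "extract_rgb",
    "cri_from_spectra",
    "DEFAULT_RGB_RANGES",
]


@dataclass
class SpectrumTable:
    """n_samples x n_bands reflectance matrix with wavelength labels (nm)."""

    sample_ids: list[str]
    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample id")
        if self.values.shape != (len(self.sample_ids), self.wavelengths_nm.size):
            raise ValueError("values shape does not match ids/wavelengths")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths not increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite reflectance values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{w:g}" for w in self.wavelengths_nm]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def subset_bands(self, wavelengths_nm) -> "SpectrumTable":
        """Restrict to a subset of bands (given as wavelengths in nm)."""
        want = np.asarray(wavelengths_nm, dtype=float)
        idx = []
        for w in want:
            hit = np.nonzero(np.isclose(self.wavelengths_nm, w))[0]
            if hit.size == 0:
                raise ValueError(f"wavelength {w} nm not in table")
            idx.append(hit[0])
        idx = np.sort(np.asarray(idx))
        return SpectrumTable(
            sample_ids=list(self.sample_ids),
            wavelengths_nm=self.wavelengths_nm[idx],
            values=self.values[:, idx],
        )


@dataclass
class ChemistryTable:
    """Per-sample pigment contents in g/kg dry exocarp."""

    sample_ids: list[str]
    zeaxanthin_g_per_kg: np.ndarray
    capsanthin_g_per_kg: np.ndarray
    total_carotenoids_g_per_kg: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        for name in ("zeaxanthin_g_per_kg", "capsanthin_g_per_kg",
                     "total_carotenoids_g_per_kg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (len(self.sample_ids),):
                raise ValueError(f"{name} length mismatch")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and >= 0")
        upper = np.maximum(self.zeaxanthin_g_per_kg, self.capsanthin_g_per_kg)
        if np.any(self.total_carotenoids_g_per_kg < upper - 1e-12):
            raise ValueError("total carotenoids below an individual pigment")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "zeaxanthin_g_per_kg": self.zeaxanthin_g_per_kg,
                "capsanthin_g_per_kg": self.capsanthin_g_per_kg,
                "total_carotenoids_g_per_kg": self.total_carotenoids_g_per_kg,
            }
        )


@dataclass
class SplitAssignment:
    """Calibration/test labels plus LOOCV fold ids within the calibration set."""

    labels: np.ndarray  # 'calibration' | 'test', length n
    loocv_fold: np.ndarray  # fold index within calibration, -1 for test samples
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.loocv_fold = np.asarray(self.loocv_fold)
        if self.labels.shape != self.loocv_fold.shape:
            raise ValueError("labels/loocv_fold length mismatch")
        if not set(np.unique(self.labels)) <= {"calibration", "test"}:
            raise ValueError("labels must be 'calibration' or 'test'")

    @property
    def calibration_mask(self) -> np.ndarray:
        return self.labels == "calibration"

    @property
    def test_mask(self) -> np.ndarray:
        return self.labels == "test"


# ---------------------------------------------------------------- I/O


def write_spectra(table: SpectrumTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_spectra(path) -> SpectrumTable:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("missing sample_id column")
    ids = df["sample_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample id")
    band_cols = [c for c in df.columns if c != "sample_id"]
    try:
        wl = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise ValueError(f"non-wavelength column name: {exc}") from exc
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths not increasing")
    vals = df[band_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-numeric or missing reflectance cell")
    return SpectrumTable(sample_ids=ids, wavelengths_nm=wl, values=vals)


def write_chemistry(table: ChemistryTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_chemistry(path) -> ChemistryTable:
    df = pd.read_csv(path)
    required = ["sample_id", "zeaxanthin_g_per_kg", "capsanthin_g_per_kg",
                "total_carotenoids_g_per_kg"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing {col} column")
    return ChemistryTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        zeaxanthin_g_per_kg=df["zeaxanthin_g_per_kg"].to_numpy(float),
        capsanthin_g_per_kg=df["capsanthin_g_per_kg"].to_numpy(float),
        total_carotenoids_g_per_kg=df["total_carotenoids_g_per_kg"].to_numpy(float),
    )


# ------------------------------------------------ wavelet preprocessing


def wavelet_kernel(scale: float, wavelet: str = "mexh") -> np.ndarray:
    """Sample a continuous wavelet at integer band offsets for one scale.

    The kernel is forced to exactly zero sum, so a constant spectrum (or a
    constant offset added to any spectrum) maps to exactly zero coefficients.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    cw = pywt.ContinuousWavelet(wavelet)
    psi, grid = cw.wavefun(length=4096)
    lo, hi = cw.lower_bound, cw.upper_bound
    half = int(np.ceil(max(abs(lo), abs(hi)) * scale))
    offsets = np.arange(-half, half + 1, dtype=float)
    kern = np.interp(offsets / scale, grid, psi, left=0.0, right=0.0)
    kern = kern / np.sqrt(scale)
    return kern - kern.mean()


def cwt_preprocess(table: SpectrumTable, scale: float = 3.0,
                   wavelet: str = "mexh") -> SpectrumTable:
    """Single-scale continuous wavelet coefficients per spectrum.

    Symmetric (reflect) boundary extension keeps the output length equal to
    the number of bands.  The zero-mean kernel removes additive baseline
    offsets exactly.
    """
    if table.n_bands < 5:
        raise ValueError("need at least 5 bands for wavelet preprocessing")
    kern = wavelet_kernel(scale, wavelet)
    half = (kern.size - 1) // 2
    ext = np.pad(table.values, ((0, 0), (half, half)), mode="symmetric")
    # correlation against the kernel at each position
    out = np.empty_like(table.values)
    for j in range(table.n_bands):
        out[:, j] = ext[:, j:j + kern.size] @ kern
    return SpectrumTable(sample_ids=list(table.sample_ids),
                         wavelengths_nm=table.wavelengths_nm.copy(),
                         values=out)


# ------------------------------------------------------- normalization


class MinMaxNormalizer:
    """Per-feature (x - min) / (max - min) with stored calibration statistics.

    Constant features map to 0.5 (a neutral value) rather than erroring, and
    held-out data are *not* clipped, so values outside [0, 1] signal genuine
    extrapolation beyond the calibration range.
    """

    def __init__(self) -> None:
        self.data_min_: np.ndarray | None = None
        self.data_max_: np.ndarray | None = None

    def fit(self, X) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        return self

    def transform(self, X) -> np.ndarray:
        if self.data_min_ is None:
            raise RuntimeError("normalizer not fitted")
        X = np.asarray(X, dtype=float)
        span = self.data_max_ - self.data_min_
        out = np.empty_like(X, dtype=float)
        const = span == 0
        safe = np.where(const, 1.0, span)
        out = (X - self.data_min_) / safe
        out[:, const] = 0.5
        return out

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


def minmax_normalize(X, normalizer: MinMaxNormalizer | None = None):
    """Functional wrapper: returns (normalized matrix, fitted normalizer)."""
    if normalizer is None:
        normalizer = MinMaxNormalizer().fit(X)
    return normalizer.transform(X), normalizer


# ------------------------------------------------------------ splitting


def stratified_split(y, n_test: int = 33, n_bins: int = 5,
                     seed: int = 0) -> SplitAssignment:
    """Quantile-stratified calibration/test split of a continuous response.

    ``y`` is binned into ``n_bins`` quantile strata; test samples are drawn
    proportionally per stratum (largest-remainder rounding keeps the test size
    exact).  The default 33/126 split of n=159 follows the 8:2 design.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_test >= n:
        raise ValueError("n_test must be < n")
    if n_test < n_bins:
        raise ValueError("n_test must be >= n_bins")
    rng = np.random.default_rng(seed)
    # rank-based qcut is robust to ties
    ranks = pd.Series(y).rank(method="first")
    strata = pd.qcut(ranks, n_bins, labels=False).to_numpy()

    counts = np.bincount(strata, minlength=n_bins)
    exact = counts * n_test / n
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    short = n_test - alloc.sum()
    for idx in np.argsort(-remainder)[:short]:
        alloc[idx] += 1

    labels = np.full(n, "calibration", dtype=object)
    for b in range(n_bins):
        members = np.nonzero(strata == b)[0]
        take = rng.choice(members, size=alloc[b], replace=False)
        labels[take] = "test"

    fold = np.full(n, -1, dtype=int)
    cal_idx = np.nonzero(labels == "calibration")[0]
    fold[cal_idx] = np.arange(cal_idx.size)
    return SplitAssignment(labels=labels.astype(str), loocv_fold=fold, seed=seed)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------------ CRI

#: Nominal RGB band windows (nm) on the instrument grid; configurable because
#: any mapping of bands to R/G/B is a convention, not physics.
DEFAULT_RGB_RANGES: dict[str, tuple[float, float]] = {
    "R": (630.0, 660.0),
    "G": (515.0, 570.0),
    "B": (430.0, 470.0),
}


def extract_rgb(table: SpectrumTable, ranges: dict | None = None):
    """Mean reflectance over the R, G and B band windows, per sample."""
    ranges = ranges or DEFAULT_RGB_RANGES
    out = []
    for key in ("R", "G", "B"):
        lo, hi = ranges[key]
        mask = (table.wavelengths_nm >= lo) & (table.wavelengths_nm <= hi)
        if not mask.any():
            raise ValueError(f"no bands in {key} range {lo}-{hi} nm")
        out.append(table.values[:, mask].mean(axis=1))
    return tuple(out)


def compute_cri(R, G, B):
    """Composite red index: 0.4 R/G + 0.3 R/B + 0.2 NRGI + 0.1 RPI.

    NRGI = (R-G)/(R+G); RPI = R/(R+G+B).  All four terms are reflectance
    ratios, so the index is invariant to a common positive scaling of the
    three bands.  Serves as an optical proxy for capsanthin (fruit redness).
    """
    R = np.asarray(R, dtype=float)
    G = np.asarray(G, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(G <= 0) or np.any(B <= 0):
        raise ValueError("division by non-positive band")
    nrgi = (R - G) / (R + G)
    rpi = R / (R + G + B)
    return 0.4 * R / G + 0.3 * R / B + 0.2 * nrgi + 0.1 * rpi


def cri_from_spectra(table: SpectrumTable, ranges: dict | None = None) -> np.ndarray:
    return compute_cri(*extract_rgb(table, ranges))
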