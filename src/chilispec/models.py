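"""Model construction, training, cross-validation and baselines.

The two reconstructed architectures are the spectral-only 1-D CNN (2177
trainable parameters) and the chemical-spectral fusion regressor (3929); the
fusion variant with the composite red index substituted for measured
capsanthin ("mcsf_fr") shares the fusion architecture exactly.  Baselines
(random forest, back-propagation MLP, PLS) are thin wrappers over
scikit-learn.  Training is full-batch Adam on mean squared error with early
stopping on a held-out fold, deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from . import nn
from .evaluation import regression_metrics
from .preprocess import (
    MinMaxNormalizer,
    SplitAssignment,
    SpectrumTable,
    cri_from_spectra,
    cwt_preprocess,
)

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "ExperimentResult",
    "NEURAL_TAGS",
    "BASELINE_TAGS",
    "build_model",
    "count_parameters",
    "train",
    "loocv",
    "fit_baseline",
    "run_model_on_split",
    "save_model",
    "load_model",
]

NEURAL_TAGS = ("spectral", "mcsf", "mcsf_fr", "chemical")
BASELINE_TAGS = ("rf", "bp", "pls")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings for the numpy networks.

    Full-batch Adam (n <= 159 makes mini-batching pointless), MSE loss,
    early stopping monitored on a held-out fraction of the training data with
    best-weight restoration.
    """

    epochs: int = 2000
    lr: float = 1e-3
    batch_size: int | None = None  # None = full batch
    patience: int = 100
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class TrainedModel:
    """A fitted model plus whatever state prediction needs."""

    tag: str
    net: object  # nn._Net for neural tags, sklearn estimator for baselines
    config: TrainConfig | None = None
    history: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def predict(self, X, C=None) -> np.ndarray:
        if self.tag in NEURAL_TAGS:
            return self.net.forward(X, C, train=False)
        if self.tag == "pls":
            return np.ravel(self.net.predict(np.asarray(X)))
        return self.net.predict(np.asarray(X))

    def features(self, X, C=None) -> np.ndarray:
        if self.tag not in NEURAL_TAGS:
            raise ValueError(f"model tag '{self.tag}' exposes no feature vector")
        return self.net.features(X, C)


def build_model(tag: str, n_bands: int, seed: int = 0, n_chem: int = 2):
    """Instantiate an untrained network for one of the neural tags.

    'mcsf_fr' is architecturally identical to 'mcsf'; only the meaning of the
    chemical inputs differs (CRI + total carotenoids instead of measured
    capsanthin + total carotenoids).
    """
    if tag == "spectral":
        return nn.SpectralCNN(n_bands, seed=seed)
    if tag in ("mcsf", "mcsf_fr"):
        net = nn.FusionNet(n_bands, n_chem=n_chem, seed=seed)
        net.tag = tag
        return net
    if tag == "chemical":
        return nn.ChemNet(n_bands, n_chem=n_chem, seed=seed)
    raise ValueError(f"unknown model tag '{tag}'")


def count_parameters(model) -> int:
    """Number of trainable scalars (batch-norm running statistics excluded)."""
    net = model.net if isinstance(model, TrainedModel) else model
    if isinstance(net, nn._Net):
        return net.n_params()
    raise ValueError("parameter counting is defined for the numpy networks")


def train(model, X, C, y, cfg: TrainConfig | None = None) -> TrainedModel:
    """Fit a numpy network by full-batch Adam with early stopping.

    A ``val_fraction`` share of the samples (at least one) is held out to
    monitor generalization; the weights giving the best held-out MSE are
    restored at the end.  Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    X = None if X is None else np.asarray(X, dtype=float)
    C = None if C is None else np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    def take(A, idx):
        return None if A is None else A[idx]

    Xtr, Xva = take(X, tr_idx), take(X, val_idx)
    Ctr, Cva = take(C, tr_idx), take(C, val_idx)
    ytr, yva = y[tr_idx], y[val_idx]

    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    best_loss = np.inf
    best_state = model.get_state()
    best_epoch = 0
    history = {"train_loss": [], "val_loss": []}
    since_best = 0
    for epoch in range(cfg.epochs):
        model.zero_grad()
        yhat = model.forward(Xtr, Ctr, train=True)
        resid = yhat - ytr
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise ValueError("diverged: reduce learning rate")
        model.backward(2.0 * resid / resid.size)
        opt.step(model.gradients())

        yv = model.forward(Xva, Cva, train=False)
        vloss = float(np.mean((yv - yva) ** 2))
        history["train_loss"].append(loss)
        history["val_loss"].append(vloss)
        if vloss < best_loss - 1e-12:
            best_loss = vloss
            best_state = model.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_loss
    return TrainedModel(tag=model.tag, net=model, config=cfg, history=history)


def loocv(fit_fn, X, y, C=None) -> np.ndarray:
    """Leave-one-out cross-validation: pooled out-of-fold predictions.

    ``fit_fn(X_train, y_train, C_train)`` must return a callable
    ``predict(X, C)``; metrics are meant to be computed on the returned pooled
    vector (length n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Ci = None if C is None else np.asarray(C)[mask]
        predict = fit_fn(X[mask], y[mask], Ci)
        Cq = None if C is None else np.asarray(C)[[i]]
        preds[i] = np.asarray(predict(X[[i]], Cq)).ravel()[0]
    return preds


def fit_baseline(tag: str, X, y, hyperparams: dict | None = None,
                 seed: int = 0) -> TrainedModel:
    """Thin wrappers over the standard tabular learners.

    rf: random forest; bp: back-propagation MLP; pls: partial least squares.
    Hyperparameters are recorded on the returned model for reporting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    hp = dict(hyperparams or {})
    if tag == "rf":
        est = RandomForestRegressor(
            n_estimators=hp.pop("n_estimators", 300), random_state=seed, **hp)
    elif tag == "bp":
        est = MLPRegressor(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (16,)),
            max_iter=hp.pop("max_iter", 4000), random_state=seed, **hp)
    elif tag == "pls":
        k = hp.pop("n_components", min(10, X.shape[1]))
        if k > np.linalg.matrix_rank(X - X.mean(axis=0)):
            raise ValueError("pls components exceed the rank of X")
        est = PLSRegression(n_components=k, **hp)
    else:
        raise ValueError(f"unknown baseline tag '{tag}'")
    est.fit(X, y)
    return TrainedModel(tag=tag, net=est,
                        extras={"hyperparams": hp, "seed": seed})


# ----------------------------------------------------- split-level runner


@dataclass
class ExperimentResult:
    """Everything one train/test experiment produced."""

    tag: str
    model: TrainedModel
    r2_test: float
    rmse_test: float
    rpd_test: float
    r2_train: float
    y_test: np.ndarray
    yhat_test: np.ndarray
    X_cal: np.ndarray
    X_test: np.ndarray
    C_cal: np.ndarray | None
    C_test: np.ndarray | None
    wavelengths_nm: np.ndarray


def _chem_matrix(tag, chemistry, spectra_raw, chem_override):
    if chem_override is not None:
        return np.asarray(chem_override, dtype=float)
    if tag == "mcsf_fr":
        cri = cri_from_spectra(spectra_raw)
        return np.column_stack([cri, chemistry.total_carotenoids_g_per_kg])
    return np.column_stack([
        chemistry.capsanthin_g_per_kg,
        chemistry.total_carotenoids_g_per_kg,
    ])


def run_model_on_split(dataset, split: SplitAssignment, tag: str,
                       cfg: TrainConfig | None = None, *,
                       wavelengths_nm=None, chem_override=None,
                       cwt_scale: float = 3.0, wavelet: str = "mexh",
                       y=None) -> ExperimentResult:
    """Train one model on the calibration half of a dataset and score the test half.

    Preprocessing (wavelet transform + min-max, statistics fit on calibration
    only) happens inside, so every configuration sees identical treatment.
    For 'mcsf_fr' the CRI is always computed from the full-band raw spectra
    (the RGB windows are measured regardless of which bands feed the
    encoder); ``chem_override`` replaces the chemical feature matrix entirely
    (used by the ablation and sensitivity suites).
    """
    cfg = cfg or TrainConfig()
    spectra_raw: SpectrumTable = dataset.spectra
    chemistry = dataset.chemistry
    y = np.asarray(dataset.chemistry.zeaxanthin_g_per_kg if y is None else y,
                   dtype=float)

    table = spectra_raw
    if wavelengths_nm is not None:
        table = table.subset_bands(wavelengths_nm)
    proc = cwt_preprocess(table, scale=cwt_scale, wavelet=wavelet)

    cal, test = split.calibration_mask, split.test_mask
    xnorm = MinMaxNormalizer().fit(proc.values[cal])
    X_cal = xnorm.transform(proc.values[cal])
    X_test = xnorm.transform(proc.values[test])

    C_cal = C_test = None
    if tag in ("mcsf", "mcsf_fr", "chemical"):
        Cfull = _chem_matrix(tag, chemistry, spectra_raw, chem_override)
        cnorm = MinMaxNormalizer().fit(Cfull[cal])
        C_cal, C_test = cnorm.transform(Cfull[cal]), cnorm.transform(Cfull[test])

    if tag in NEURAL_TAGS:
        net = build_model(tag, n_bands=table.n_bands, seed=cfg.seed,
                          n_chem=2 if C_cal is None else C_cal.shape[1])
        trained = train(net, X_cal if tag != "chemical" else None,
                        C_cal, y[cal], cfg)
        trained.tag = tag
    elif tag in BASELINE_TAGS:
        trained = fit_baseline(tag, X_cal, y[cal], seed=cfg.seed)
    else:
        raise ValueError(f"unknown model tag '{tag}'")

    def _pred(X, C):
        if tag == "chemical":
            return trained.predict(None, C)
        if tag in BASELINE_TAGS:
            return trained.predict(X)
        return trained.predict(X, C)

    yhat_test = _pred(X_test, C_test)
    yhat_cal = _pred(X_cal, C_cal)
    r2_t, rmse_t, rpd_t = regression_metrics(y[test], yhat_test)
    r2_c = regression_metrics(y[cal], yhat_cal)[0]
    return ExperimentResult(
        tag=tag, model=trained, r2_test=r2_t, rmse_test=rmse_t, rpd_test=rpd_t,
        r2_train=r2_c, y_test=y[test], yhat_test=yhat_test,
        X_cal=X_cal, X_test=X_test, C_cal=C_cal, C_test=C_test,
        wavelengths_nm=table.wavelengths_nm.copy(),
    )


# ------------------------------------------------------------ persistence


def save_model(model: TrainedModel, path) -> None:
    """Self-describing JSON checkpoint (neural tags only)."""
    if model.tag not in NEURAL_TAGS:
        raise ValueError("only the numpy networks are JSON-serializable")
    net = model.net
    state = [a.tolist() for a in net.get_state()]
    blob = {
        "tag": model.tag,
        "n_bands": getattr(net, "n_bands", 0),
        "n_chem": net.chem_fc1.params["W"].shape[0] if hasattr(net, "chem_fc1")
                  else (net.fc1.params["W"].shape[0] if isinstance(net, nn.ChemNet) else 2),
        "state": state,
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        blob = json.load(fh)
    n_bands = blob["n_bands"] if blob["tag"] == "chemical" else max(blob["n_bands"], 4)
    net = build_model(blob["tag"], n_bands, n_chem=blob["n_chem"])
    net.set_state([np.asarray(a, dtype=float) for a in blob["state"]])
    return TrainedModel(tag=blob["tag"], net=net)
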