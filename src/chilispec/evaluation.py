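"""Regression metrics, model-adequacy statistics and report assembly.

Conventions: R^2 = 1 - SS_res / SS_tot (the standard coefficient of
determination), RMSE with division by n, RPD = SD(y) / RMSE with the sample
standard deviation (ddof = 1), so RPD * RMSE = SD(y) exactly.  The paired
t-test of predicted against measured values uses df = n - 2 with a two-sided
critical value (at n = 33 and alpha = 0.01 this gives 2.744).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "regression_metrics",
    "r2_explained",
    "paired_t_test",
    "PairedTResult",
    "rpd_category",
    "build_report",
    "report_to_json",
    "report_from_json",
]


def regression_metrics(y, yhat) -> tuple[float, float, float]:
    """(R^2, RMSE, RPD) of predictions against reference values."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 3 or y.size != yhat.size:
        raise ValueError("need aligned vectors of length >= 3")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance reference")
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / y.size))
    if rmse == 0:
        raise ValueError("zero RMSE: RPD undefined for perfect predictions")
    rpd = float(np.std(y, ddof=1) / rmse)
    return r2, rmse, rpd


def r2_explained(y, yhat) -> float:
    """Alternative R^2 as explained variance ratio, sum(yhat - ybar)^2 /
    sum(y - ybar)^2; equals the standard definition only for least-squares
    fits.  Provided for completeness, not used by default."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance reference")
    return float(np.sum((yhat - y.mean()) ** 2) / ss_tot)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    t_critical: float
    df: int
    alpha: float
    significant: bool
    mean_difference: float


def paired_t_test(y, yhat, alpha: float = 0.01) -> PairedTResult:
    """Paired t-test of predicted minus measured values.

    t = mean(d) / (SD(d) / sqrt(n)) with d = yhat - y; compared against the
    two-sided critical value at ``alpha`` with df = n - 2.  A zero-variance,
    nonzero-mean difference reports an infinite t.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = y.size
    if n < 3 or n != yhat.size:
        raise ValueError("need aligned vectors of length >= 3")
    d = yhat - y
    sd = float(np.std(d, ddof=1))
    mean_d = float(d.mean())
    if sd == 0:
        t = 0.0 if mean_d == 0 else float(np.inf) * np.sign(mean_d)
    else:
        t = mean_d / (sd / np.sqrt(n))
    df = n - 2
    t_crit = float(stats.t.ppf(1 - alpha / 2, df))
    return PairedTResult(t=float(t), t_critical=t_crit, df=df, alpha=alpha,
                         significant=bool(abs(t) > t_crit),
                         mean_difference=mean_d)


def rpd_category(rpd: float) -> str:
    """Reliability reading of an RPD value: >= 3 reliable, 2.4-3 adequate only
    for general prediction, below that poor."""
    if rpd >= 3.0:
        return "reliable"
    if rpd >= 2.4:
        return "general"
    return "poor"


_SPLITS = ("train", "calibration", "validation", "test")


def build_report(entries: dict) -> dict:
    """Assemble a per-model/per-band-set evaluation report.

    ``entries`` maps a configuration name (e.g. ``"mcsf/all_bands"``) to a
    dict with ``y_<split>``/``yhat_<split>`` vectors for any of the splits
    train, calibration, validation, test.  At minimum the train and test
    splits must be present.  The report records R^2 and RMSE per split, the
    overfitting gap delta_r2 = Rt^2 - Rv^2 (when a validation split exists),
    test-set RPD with its reliability category, the paired t-test, and the
    measured/predicted pairs for 1:1 plotting.
    """
    report: dict = {}
    for name, data in entries.items():
        for required in ("train", "test"):
            if f"y_{required}" not in data or f"yhat_{required}" not in data:
                raise ValueError(f"missing split '{required}' in entry '{name}'")
        entry: dict = {}
        for split in _SPLITS:
            if f"y_{split}" in data:
                y = np.asarray(data[f"y_{split}"], dtype=float)
                yhat = np.asarray(data[f"yhat_{split}"], dtype=float)
                r2, rmse, rpd = regression_metrics(y, yhat)
                entry[f"r2_{split}"] = r2
                entry[f"rmse_{split}"] = rmse
                if split == "test":
                    entry["rpd"] = rpd
                    entry["rpd_category"] = rpd_category(rpd)
                    tres = paired_t_test(y, yhat)
                    entry["paired_t"] = {
                        "t": tres.t, "t_critical": tres.t_critical,
                        "df": tres.df, "significant": tres.significant,
                        "mean_difference": tres.mean_difference,
                    }
                    entry["one_to_one"] = {
                        "measured": y.tolist(), "predicted": yhat.tolist()}
        if "r2_train" in entry and "r2_validation" in entry:
            entry["delta_r2"] = entry["r2_train"] - entry["r2_validation"]
        report[name] = entry
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def report_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
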