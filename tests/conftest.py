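"""Shared fixtures: synthetic populations and the multi-seed trained model
runs that several property tests interrogate.

The heavy session-scoped fixtures train each model once per seed and are
reused by the headline-gap, ablation, band-reduction, Grad-CAM and t-SNE
tests, keeping total suite runtime manageable.  The reduced training schedule
(700 epochs, lr 3e-3) is a runtime choice; the qualitative behavior matches
the module defaults.
"""

from __future__ import annotations

import sys
from dataclasses import replace
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chilispec import (
    SyntheticConfig,
    TrainConfig,
    ablation_suite,
    generate_population,
    run_model_on_split,
    select_bands,
    sensitivity_sweep,
    stratified_split,
)

N_SEEDS = 10
FAST_CFG = TrainConfig(epochs=1500, lr=5e-3, patience=150, val_fraction=0.2)


def make_dataset(seed: int, **kwargs):
    return generate_population(SyntheticConfig(seed=seed, **kwargs))


def make_split(dataset, seed: int):
    return stratified_split(dataset.chemistry.zeaxanthin_g_per_kg,
                            n_test=33, n_bins=5, seed=seed)


@pytest.fixture(scope="session")
def default_dataset():
    return make_dataset(0)


@pytest.fixture(scope="session")
def default_split(default_dataset):
    return make_split(default_dataset, 0)


@pytest.fixture(scope="session")
def paired_runs():
    """Spectral-only and fusion models trained on the same split, 10 seeds."""
    runs = []
    for seed in range(N_SEEDS):
        ds = make_dataset(seed)
        split = make_split(ds, seed)
        cfg = replace(FAST_CFG, seed=seed)
        runs.append({
            "seed": seed,
            "dataset": ds,
            "split": split,
            "spectral": run_model_on_split(ds, split, "spectral", cfg),
            "mcsf": run_model_on_split(ds, split, "mcsf", cfg),
        })
    return runs


@pytest.fixture(scope="session")
def ablation_runs():
    """Five-configuration ablation per seed, 10 seeds, shared hyperparameters."""
    out = []
    for seed in range(N_SEEDS):
        ds = make_dataset(seed)
        split = make_split(ds, seed)
        cfg = replace(FAST_CFG, seed=seed)
        out.append(ablation_suite(ds, split, cfg))
    return out


@pytest.fixture(scope="session")
def selected_band_runs(paired_runs):
    """Characteristic-band (5 bands via stepwise with a cap) retraining of both
    architectures, paired with the full-band runs."""
    out = []
    for run in paired_runs:
        ds, split, seed = run["dataset"], run["split"], run["seed"]
        sel = select_bands(ds.spectra, max_bands=5)
        cfg = replace(FAST_CFG, seed=seed)
        out.append({
            "seed": seed,
            "selected": sel.selected_wavelengths_nm,
            "spectral_full": run["spectral"],
            "mcsf_full": run["mcsf"],
            "spectral_sel": run_model_on_split(
                ds, split, "spectral", cfg,
                wavelengths_nm=sel.selected_wavelengths_nm),
            "mcsf_sel": run_model_on_split(
                ds, split, "mcsf", cfg,
                wavelengths_nm=sel.selected_wavelengths_nm),
        })
    return out


@pytest.fixture(scope="session")
def sensitivity_curves():
    """Correlation-sensitivity curves of the fusion model over 5 seeds."""
    rhos = [0.2, 0.5, 0.8, 0.95]
    curves = []
    for seed in range(5):
        ds = make_dataset(seed)
        split = make_split(ds, seed)
        cfg = replace(FAST_CFG, seed=seed)
        curves.append(sensitivity_sweep(ds, rhos, cfg, split=split))
    return curves
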