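"""Shared fixtures: deterministic RNGs, synthetic benchmarks, tiny cohort."""

from __future__ import annotations

import numpy as np
import pytest

from docfc import synthgen
from docfc.pipeline import ExperimentConfig, run_experiment
from docfc.types import CANONICAL_BANDS, CLASS_ORDER


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_spec(rho: float, kappa: float, lag_step: float = 0.8,
                 n_channels: int = 4, noise_sd: float = 0.0,
                 drift: float = 0.0, bands=CANONICAL_BANDS,
                 group: str = "HC") -> synthgen.GroupConnectivitySpec:
    """A spec with one uniform rho/kappa level and linearly spaced lags."""
    nb = len(bands)
    return synthgen.GroupConnectivitySpec(
        group_label=group,
        loadings=np.full((nb, n_channels), np.sqrt(rho)),
        kappa=np.full((nb, n_channels), kappa),
        phase_offsets=np.tile(lag_step * np.arange(n_channels), (nb, 1)),
        noise_sd=noise_sd, line_amp=0.0, state_drift_sd=drift, bands=bands)


@pytest.fixture(scope="session")
def blob_benchmark():
    """Well-separated 4-class Gaussian blobs in 855 dimensions.

    Returns (X_train, Y_train, X_test, Y_test, y_test_labels); 480 training
    and 600 test rows, balanced classes.
    """
    from docfc import dataset

    rng = np.random.default_rng(7)
    n_train_per, n_test_per, d = 120, 150, 855
    centers = rng.standard_normal((4, d)) * 0.6
    Xtr, ytr, Xte, yte = [], [], [], []
    for c, label in enumerate(CLASS_ORDER):
        Xtr.append(centers[c] + rng.standard_normal((n_train_per, d)))
        Xte.append(centers[c] + rng.standard_normal((n_test_per, d)))
        ytr += [label] * n_train_per
        yte += [label] * n_test_per
    Xtr, Xte = np.concatenate(Xtr), np.concatenate(Xte)
    ytr = np.asarray(ytr, dtype=object)
    yte = np.asarray(yte, dtype=object)
    perm = rng.permutation(len(ytr))
    Xtr, ytr = Xtr[perm], ytr[perm]
    Xtr, Xte, _ = dataset.standardize(Xtr, Xte)
    return Xtr, dataset.one_hot(ytr), Xte, dataset.one_hot(yte), yte


@pytest.fixture(scope="session")
def tiny_experiment(tmp_path_factory):
    """End-to-end run on a small synthetic cohort (3 subjects/group, 260 s).

    Returns (config, summary table, output dir). Used by the pipeline smoke
    test, the protocol-sanity checks, and the CLI artifact checks.
    """
    out = tmp_path_factory.mktemp("experiment")
    cfg = ExperimentConfig(
        n_subjects_per_group=3, duration_s=260.0, trim_s=5.0, seed=11,
        window_lengths=[20], feature_sets=[["AEC"]],
        swc_metrics=["AEC"], architectures=["mlp2"],
        split="fixed_80_20", outdir=str(out / "run"))
    summary = run_experiment(cfg)
    return cfg, summary, out / "run"
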