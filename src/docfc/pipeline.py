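"""End-to-end experiment orchestration.

Stages (each reads and writes only files, so real EDF recordings can replace
the simulator at the preprocess boundary):

    simulate -> preprocess -> connect -> swc -> features -> train

Every stage is idempotent: outputs already on disk are reused unless
``force`` is set. A manifest JSON records the configuration, seeds, and
per-stage wall-clock timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, connectivity, dataset, preprocess, swc, synthgen
from .edf import read_edf
from .types import BAND_NAMES, CANONICAL_BANDS, CLASS_ORDER, BandSpec

log = logging.getLogger("docfc")

_FEATURE_SET_SEP = "+"


@dataclass
class ExperimentConfig:
    """One experiment: cohort, preprocessing, features, models, splits."""

    groups: list[str] = field(default_factory=lambda: list(CLASS_ORDER))
    n_subjects_per_group: int = 15
    duration_s: float = 1800.0
    fs: float = 256.0
    seed: int = 0
    trim_s: float = 120.0
    separation: float = 1.0
    band_edges: dict[str, list[float]] | None = None
    window_lengths: list[int] = field(default_factory=lambda: [20])
    feature_sets: list[list[str]] = field(default_factory=lambda: [["AEC"]])
    swc_metrics: list[str] = field(default_factory=lambda: list(
        connectivity.METRICS))
    split: str = "fixed_80_20"
    k_folds: int = 10
    architectures: list[str] = field(default_factory=lambda: ["mlp2"])
    epochs_override: int | None = None
    outdir: str = "experiment"

    def validate(self) -> None:
        if not set(self.window_lengths) <= {16, 17, 18, 19, 20}:
            raise ValueError("window_lengths must be a subset of 16..20 s")
        if not self.feature_sets or not self.architectures:
            raise ValueError("need at least one feature set and architecture")
        for fs_ in self.feature_sets:
            unknown = set(fs_) - set(connectivity.METRICS)
            if unknown:
                raise ValueError(f"unknown metrics {sorted(unknown)}")
        for arch in self.architectures:
            if arch not in classify.ARCHITECTURES:
                raise ValueError(f"unknown architecture {arch!r}")
        if self.split not in ("fixed_80_20", "group_kfold"):
            raise ValueError(f"unknown split kind {self.split!r}")
        if self.duration_s <= 2 * self.trim_s + max(self.window_lengths):
            raise ValueError("duration too short for trimming + one window")

    def bands(self) -> tuple[BandSpec, ...]:
        if self.band_edges is None:
            return CANONICAL_BANDS
        return tuple(BandSpec(name, lo, hi)
                     for name, (lo, hi) in self.band_edges.items())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: ExperimentConfig, out: Path, force: bool = False
                   ) -> Path:
    raw = out / "raw"
    manifest = raw / "manifest.csv"
    if manifest.exists() and not force:
        log.info("simulate: reusing %s", manifest)
        return manifest
    presets = {s.group_label: s for s in synthgen.default_presets(
        bands=cfg.bands(), separation=cfg.separation)}
    specs = [presets[g] for g in cfg.groups]
    cohort = synthgen.generate_cohort(
        specs, cfg.n_subjects_per_group, cfg.fs, cfg.duration_s,
        seed=cfg.seed)
    return synthgen.write_cohort(cohort, raw)


def stage_preprocess(cfg: ExperimentConfig, out: Path, force: bool = False
                     ) -> Path:
    bands_dir = out / "bands"
    bands_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(out / "raw" / "manifest.csv")
    bands = cfg.bands()
    for _, row in manifest.iterrows():
        target = bands_dir / f"{row.subject_id}.npz"
        if target.exists() and not force:
            continue
        rec = read_edf(out / "raw" / row.file)
        rec.subject_id, rec.group_label = row.subject_id, row.group
        rec = preprocess.trim_edges(rec, cfg.trim_s)
        rec = preprocess.average_reference(rec)
        rec = preprocess.broadband_clean(rec)
        decomposed = preprocess.band_decompose(rec, bands)
        np.savez(target, **{name: r.samples
                            for name, r in decomposed.items()})
    sidecar = {
        "fs": cfg.fs,
        "bands": {b.name: [b.lo, b.hi] for b in bands},
        "channels": list(read_edf(
            out / "raw" / manifest.iloc[0].file).channel_labels),
    }
    with open(bands_dir / "meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return bands_dir


def _k_target(cfg: ExperimentConfig, window_s: int, usable_samples: int
              ) -> int:
    W = int(round(window_s * cfg.fs))
    S = W // 2
    guard = 2 * int(round(1.0 * cfg.fs))
    k_avail = (usable_samples - guard - W) // S + 1
    if k_avail < 1:
        raise ValueError(f"recordings too short for {window_s} s windows")
    canonical = dataset.WINDOWS_PER_SUBJECT.get(window_s)
    if canonical is not None and canonical <= k_avail:
        return canonical
    return int(k_avail)


def stage_connect(cfg: ExperimentConfig, out: Path, force: bool = False
                  ) -> Path:
    bands_dir = out / "bands"
    conn_dir = out / "conn"
    with open(bands_dir / "meta.json") as fh:
        meta = json.load(fh)
    manifest = pd.read_csv(out / "raw" / "manifest.csv")
    metrics = sorted({m for s in cfg.feature_sets for m in s}
                     | set(cfg.swc_metrics))
    for window_s in cfg.window_lengths:
        wdir = conn_dir / f"w{window_s}"
        wdir.mkdir(parents=True, exist_ok=True)
        for _, row in manifest.iterrows():
            data = None
            for metric in metrics:
                target = wdir / f"{row.subject_id}_{metric}.npz"
                if target.exists() and not force:
                    continue
                if data is None:
                    with np.load(bands_dir / f"{row.subject_id}.npz") as z:
                        data = {name: z[name] for name in z.files}
                usable = next(iter(data.values())).shape[1]
                tensor = connectivity.compute_tensor(
                    data, cfg.fs, window_s, metric,
                    K_target=_k_target(cfg, window_s, usable),
                    channel_labels=tuple(meta["channels"]),
                    subject_id=row.subject_id, group_label=row.group)
                np.savez(target, values=tensor.values,
                         band_names=np.array(tensor.band_names),
                         channels=np.array(tensor.channel_labels))
    return conn_dir


def _load_tensor(path: Path, metric: str, subject: str, group: str
                 ) -> connectivity.ConnectivityTensor:
    with np.load(path) as z:
        return connectivity.ConnectivityTensor(
            metric=metric, values=z["values"],
            band_names=tuple(z["band_names"]),
            channel_labels=tuple(z["channels"]),
            subject_id=subject, group_label=group)


def stage_swc(cfg: ExperimentConfig, out: Path, force: bool = False) -> Path:
    swc_dir = out / "swc"
    swc_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(out / "raw" / "manifest.csv")
    groups = dict(zip(manifest.subject_id, manifest.group))
    for window_s in cfg.window_lengths:
        table_path = swc_dir / f"w{window_s}_group_table.csv"
        if table_path.exists() and not force:
            continue
        series = []
        for _, row in manifest.iterrows():
            for metric in cfg.swc_metrics:
                t = _load_tensor(
                    out / "conn" / f"w{window_s}" /
                    f"{row.subject_id}_{metric}.npz",
                    metric, row.subject_id, row.group)
                for band in t.band_names:
                    series.append(swc.swc_series(
                        t.band_vectorized(band), band=band, metric=metric,
                        subject_id=row.subject_id))
        swc.swc_group_table(series, groups).to_csv(table_path)
        swc.subject_swc_frame(series).to_csv(
            swc_dir / f"w{window_s}_subject_series.csv", index=False)
    return swc_dir


def _set_name(metrics: list[str]) -> str:
    return _FEATURE_SET_SEP.join(metrics)


def stage_features(cfg: ExperimentConfig, out: Path, force: bool = False
                   ) -> Path:
    feat_dir = out / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(out / "raw" / "manifest.csv")
    for window_s in cfg.window_lengths:
        for metrics in cfg.feature_sets:
            name = _set_name(metrics)
            target = feat_dir / f"w{window_s}_{name}.npz"
            if target.exists() and not force:
                continue
            tensors = {m: [_load_tensor(
                out / "conn" / f"w{window_s}" / f"{r.subject_id}_{m}.npz",
                m, r.subject_id, r.group)
                for _, r in manifest.iterrows()] for m in metrics}
            fm = dataset.build_feature_matrix(tensors, tuple(metrics))
            np.savez(target, X=fm.X, y=fm.y.astype(str),
                     subject=fm.subject.astype(str),
                     window_index=fm.window_index)
            pd.DataFrame({
                "subject": fm.subject.astype(str), "group": fm.y.astype(str),
                "window": fm.window_index}).to_csv(
                feat_dir / f"w{window_s}_{name}_rows.csv", index=False)
    return feat_dir


def _load_features(out: Path, window_s: int, metrics: list[str]
                   ) -> dataset.FeatureMatrix:
    name = _set_name(metrics)
    with np.load(out / "features" / f"w{window_s}_{name}.npz",
                 allow_pickle=False) as z:
        X, y = z["X"], z["y"].astype(object)
        subject, widx = z["subject"].astype(object), z["window_index"]
    n_per_band = X.shape[1] // len(metrics) // len(BAND_NAMES)
    n_ch = int(round((1 + np.sqrt(1 + 8 * n_per_band)) / 2))
    pairs = connectivity.pair_index(n_ch)
    names = [(m, b, i, j) for m in metrics for b in BAND_NAMES
             for (i, j) in pairs]
    return dataset.FeatureMatrix(X=X, y=y, subject=subject,
                                 window_index=widx, feature_names=names)


def _fit_eval(cfg: ExperimentConfig, fm: dataset.FeatureMatrix,
              metrics: list[str], arch: str, tr: np.ndarray, te: np.ndarray,
              seed: int) -> classify.EvalReport:
    Xtr, Xte, _ = dataset.standardize(fm.X[tr], fm.X[te])
    classes = tuple(cfg.groups)
    Ytr = dataset.one_hot(fm.y[tr], classes)
    Yte = dataset.one_hot(fm.y[te], classes)
    model, spec = classify.build_model(
        arch, fm.n_features, seed=seed, n_metrics=len(metrics),
        n_classes=len(classes))
    hist = classify.train(model, spec, Xtr, Ytr,
                          epochs=cfg.epochs_override)
    return classify.evaluate(model, spec, Xte, Yte, class_order=classes,
                             ci_seed=seed, history=hist)


def stage_train(cfg: ExperimentConfig, out: Path, force: bool = False
                ) -> pd.DataFrame:
    models_dir = out / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for window_s in cfg.window_lengths:
        for metrics in cfg.feature_sets:
            name = _set_name(metrics)
            fm = _load_features(out, window_s, metrics)
            if cfg.split == "fixed_80_20":
                plan = dataset.split_fixed(fm, seed=cfg.seed)
            else:
                plan = dataset.split_group_kfold(fm, k=cfg.k_folds)
            for arch in cfg.architectures:
                fold_reports = []
                for f, (tr, te) in enumerate(plan.folds):
                    rep = _fit_eval(cfg, fm, metrics, arch, tr, te,
                                    seed=cfg.seed + f)
                    fold_reports.append(rep)
                    rep.to_json(models_dir /
                                f"w{window_s}_{name}_{arch}_fold{f}.json")
                    if rep.history is not None:
                        pd.DataFrame({
                            "epoch": range(1, len(rep.history.loss) + 1),
                            "loss": rep.history.loss,
                            "val_loss": rep.history.val_loss,
                            "acc": rep.history.acc,
                            "val_acc": rep.history.val_acc,
                        }).to_csv(models_dir /
                                  f"w{window_s}_{name}_{arch}_fold{f}"
                                  "_history.csv", index=False)
                accs = [r.accuracy for r in fold_reports]
                best = int(np.argmax(accs))
                rows.append({
                    "window_s": window_s, "features": name, "arch": arch,
                    "split": cfg.split, "n_folds": len(plan.folds),
                    "best_fold": best + 1,
                    "accuracy_best": fold_reports[best].accuracy,
                    "precision_best": fold_reports[best].precision,
                    "recall_best": fold_reports[best].recall,
                    "f1_best": fold_reports[best].f1,
                    "accuracy_mean": float(np.mean(accs)),
                })
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)
    return summary


_STAGES = ("simulate", "preprocess", "connect", "swc", "features", "train")


def run_experiment(cfg: ExperimentConfig, force: bool = False
                   ) -> pd.DataFrame:
    """Run all stages; returns the summary table (also written to disk)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    timings = {}
    result = None
    for stage_name in _STAGES:
        fn = globals()[f"stage_{stage_name}"]
        t0 = time.monotonic()
        log.info("stage %s ...", stage_name)
        result = fn(cfg, out, force=force)
        timings[stage_name] = round(time.monotonic() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": dataclasses.asdict(cfg),
                   "seed": cfg.seed, "timings_s": timings,
                   "stages": list(_STAGES)}, fh, indent=2)
    return result
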