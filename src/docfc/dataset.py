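"""Design-matrix assembly, standardization, and evaluation splits.

A row of the design matrix is one sliding window of one subject; its
features are the vectorized strict-upper-triangular connectivity values,
band-major (delta..gamma) within each metric, metrics concatenated in the
order given. With 19 channels that is 171 pairs x 5 bands = 855 features per
metric. Two split protocols are provided: a stratified fixed 80/20 split
(windows of one subject may land on both sides) and the leakage-safe
subject-grouped k-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GroupKFold, train_test_split

from .connectivity import ConnectivityTensor, pair_index
from .types import CLASS_ORDER

#: Canonical number of sliding windows per subject for each window length in
#: seconds, used to equalise window counts across subjects (truncation).
WINDOWS_PER_SUBJECT = {16: 120, 17: 115, 18: 109, 19: 103, 20: 95}


def n_pairs(n_channels: int) -> int:
    """Unique channel pairs: n(n-1)/2."""
    return n_channels * (n_channels - 1) // 2


def design_size(window_s: int, n_subjects_per_group: int = 15,
                n_groups: int = 4, n_channels: int = 19,
                n_bands: int = 5) -> tuple[int, int]:
    """(n_samples, n_features) of the single-metric design matrix."""
    K = WINDOWS_PER_SUBJECT[window_s]
    return (K * n_subjects_per_group * n_groups, n_bands * n_pairs(n_channels))


@dataclass
class FeatureMatrix:
    """Windows-by-features design matrix with per-row annotations."""

    X: np.ndarray
    y: np.ndarray              # group label per row (strings)
    subject: np.ndarray        # subject id per row
    window_index: np.ndarray   # window index per row
    feature_names: list[tuple[str, str, int, int]]  # (metric, band, i, j)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = self.X.shape[0]
        if not (len(self.y) == len(self.subject)
                == len(self.window_index) == n):
            raise ValueError("row annotation length mismatch")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_feature_matrix(tensors: dict[str, list[ConnectivityTensor]],
                         metrics: tuple[str, ...]) -> FeatureMatrix:
    """Stack per-subject connectivity tensors into a design matrix.

    ``tensors`` maps metric name -> list of per-subject tensors (same subject
    order for every metric). Rows are subject-major then window-major;
    feature columns are metric-major, then band-major, then pair-major.
    """
    if not metrics:
        raise ValueError("need at least one metric")
    for m in metrics:
        if m not in tensors:
            raise ValueError(f"no tensors supplied for metric {m!r}")
    ref = tensors[metrics[0]]
    n_subj = len(ref)
    Ks = {t.n_windows for lst in tensors.values() for t in lst}
    if len(Ks) != 1:
        raise ValueError(f"inconsistent window counts across subjects: {Ks}")
    bands = ref[0].band_names
    chans = ref[0].channel_labels
    pairs = pair_index(len(chans))

    feature_names = [(m, b, i, j) for m in metrics for b in bands
                     for (i, j) in pairs]
    blocks, y, subj, widx = [], [], [], []
    for s in range(n_subj):
        per_metric = []
        for m in metrics:
            t = tensors[m][s]
            if t.band_names != bands or t.channel_labels != chans:
                raise ValueError("band/channel layout differs across subjects")
            if t.subject_id != ref[s].subject_id:
                raise ValueError("subject order differs across metrics")
            per_metric.append(t.vectorized())
        rows = np.concatenate(per_metric, axis=1)
        blocks.append(rows)
        K = rows.shape[0]
        y.extend([ref[s].group_label] * K)
        subj.extend([ref[s].subject_id] * K)
        widx.extend(range(K))
    return FeatureMatrix(
        X=np.concatenate(blocks, axis=0),
        y=np.asarray(y, dtype=object),
        subject=np.asarray(subj, dtype=object),
        window_index=np.asarray(widx, dtype=np.int64),
        feature_names=feature_names,
    )


@dataclass
class Standardizer:
    """Per-feature affine map fitted on training rows only."""

    mean: np.ndarray
    scale: np.ndarray  # SD with zero-variance features mapped to scale 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.scale


def standardize(train_X: np.ndarray, *other_X: np.ndarray
                ) -> tuple[np.ndarray, ...]:
    """Zero-mean/unit-variance scaling fitted on train, applied everywhere.

    Returns (scaled train, *scaled others, Standardizer). Constant features
    map to 0 on every split.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    if train_X.size == 0:
        raise ValueError("empty training matrix")
    mean = train_X.mean(axis=0)
    scale = train_X.std(axis=0)
    scale[scale == 0] = 1.0
    sc = Standardizer(mean=mean, scale=scale)
    return (sc.transform(train_X), *(sc.transform(X) for X in other_X), sc)


def one_hot(y: np.ndarray, classes: tuple[str, ...] = CLASS_ORDER
            ) -> np.ndarray:
    """Indicator matrix with column order fixed by ``classes``."""
    index = {c: k for k, c in enumerate(classes)}
    out = np.zeros((len(y), len(classes)))
    for r, label in enumerate(y):
        if label not in index:
            raise ValueError(f"unknown label {label!r}")
        out[r, index[label]] = 1.0
    return out


def labels_from_one_hot(Y: np.ndarray,
                        classes: tuple[str, ...] = CLASS_ORDER) -> np.ndarray:
    return np.asarray([classes[k] for k in np.argmax(Y, axis=1)], dtype=object)


@dataclass
class SplitPlan:
    """Row-level assignment of one or more train/test splits."""

    kind: str                       # "fixed_80_20" | "group_kfold"
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    seed: int | None = None
    meta: dict = field(default_factory=dict)


def split_fixed(fm: FeatureMatrix, test_fraction: float = 0.2,
                seed: int = 0) -> SplitPlan:
    """Stratified fixed 80/20 split, reproducible by seed.

    Stratification is by class label; windows of one subject can appear on
    both sides (the group k-fold plan is the leakage-safe protocol).
    """
    labels, counts = np.unique(fm.y.astype(str), return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    idx = np.arange(fm.n_samples)
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=fm.y.astype(str), shuffle=True)
    counts_by_class = {
        c: {"train": int((fm.y[tr] == c).sum()),
            "test": int((fm.y[te] == c).sum())}
        for c in labels
    }
    return SplitPlan(kind="fixed_80_20", folds=[(np.sort(tr), np.sort(te))],
                     seed=seed, meta={"per_class": counts_by_class})


def split_group_kfold(fm: FeatureMatrix, k: int = 10) -> SplitPlan:
    """Subject-grouped k-fold: no subject straddles train and validation."""
    subjects = np.unique(fm.subject.astype(str))
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects < {k} folds")
    gkf = GroupKFold(n_splits=k)
    folds = [(tr, te) for tr, te in
             gkf.split(fm.X, fm.y.astype(str), groups=fm.subject.astype(str))]
    return SplitPlan(kind="group_kfold", folds=folds, meta={"k": k})
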