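"""Sliding-window correlation of connectivity patterns.

For each subject, band and metric, the vectorized connectivity of
consecutive windows k and k+1 is correlated (Pearson), yielding a series
r_1..r_{K-1}. The mean of that series measures how *stable* the connectivity
pattern is over time, its standard deviation how *variable*; both are
aggregated to a (group x band x metric) table at the cohort level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SWCSeries:
    """Consecutive-window pattern correlations for one subject/band/metric."""

    r: np.ndarray          # length K-1, entries in [-1, 1] (NaN if skipped)
    band: str = ""
    metric: str = ""
    subject_id: str = ""
    n_skipped: int = 0     # window pairs skipped due to zero-variance rows

    @property
    def mean_swc(self) -> float:
        valid = self.r[~np.isnan(self.r)]
        return float(valid.mean()) if valid.size else float("nan")

    @property
    def std_swc(self) -> float:
        # population SD; at K ~ 95 the sample/population distinction is
        # negligible but the convention is fixed for reproducibility
        valid = self.r[~np.isnan(self.r)]
        return float(valid.std()) if valid.size else float("nan")


def swc_series(conn_vectors: np.ndarray, band: str = "", metric: str = "",
               subject_id: str = "") -> SWCSeries:
    """Correlate consecutive rows of a (K, p) window-by-feature matrix.

    Zero-variance rows make the correlation undefined; the affected r_k are
    recorded as NaN and counted in ``n_skipped``.
    """
    X = np.asarray(conn_vectors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("need a 2-D (windows x features) matrix")
    K, p = X.shape
    if K < 2:
        raise ValueError("need at least two windows")
    if p < 2:
        raise ValueError("need at least two features")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    r = np.empty(K - 1)
    skipped = 0
    for k in range(K - 1):
        d = norms[k] * norms[k + 1]
        if d == 0:
            r[k] = np.nan
            skipped += 1
        else:
            r[k] = np.clip((Xc[k] * Xc[k + 1]).sum() / d, -1.0, 1.0)
    return SWCSeries(r=r, band=band, metric=metric, subject_id=subject_id,
                     n_skipped=skipped)


@dataclass
class SWCGroupTable:
    """Cohort-level aggregation: one row per (group, band, metric)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def swc_group_table(series: list[SWCSeries],
                    groups: dict[str, str]) -> SWCGroupTable:
    """Aggregate per-subject SWC summaries by (group, band, metric).

    ``groups`` maps subject_id -> group label. Columns: group, band, metric,
    mean_swc (mean of per-subject means), std_swc (mean of per-subject SDs),
    n_subjects.
    """
    if not series:
        raise ValueError("no SWC series supplied")
    rows = []
    for s in series:
        if s.subject_id not in groups:
            raise ValueError(f"subject {s.subject_id!r} has no group")
        rows.append({
            "group": groups[s.subject_id], "band": s.band, "metric": s.metric,
            "subject_id": s.subject_id, "mean_swc": s.mean_swc,
            "std_swc": s.std_swc,
        })
    df = pd.DataFrame(rows)
    agg = (df.groupby(["group", "band", "metric"], sort=False)
           .agg(mean_swc=("mean_swc", "mean"), std_swc=("std_swc", "mean"),
                n_subjects=("subject_id", "nunique"))
           .reset_index())
    if (agg["n_subjects"] == 0).any():
        raise ValueError("empty group in SWC aggregation")
    return SWCGroupTable(table=agg)


def subject_swc_frame(series: list[SWCSeries]) -> pd.DataFrame:
    """Long-format per-subject series: subject, band, metric, k, r_k."""
    rows = []
    for s in series:
        for k, rk in enumerate(s.r, start=1):
            rows.append({"subject_id": s.subject_id, "band": s.band,
                         "metric": s.metric, "k": k, "r_k": rk})
    return pd.DataFrame(rows)
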