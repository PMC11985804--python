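"""Phase- and amplitude-based connectivity: PLI, wPLI, and AEC.

All three estimators operate on the analytic signal z(t) = x(t) + i H(x(t))
of a band-limited channel, whose magnitude is the amplitude envelope and
whose argument is the instantaneous phase.

* PLI  = |E[sgn(sin(phi_x - phi_y))]| — consistency of the *direction* of the
  phase lag; 0 for symmetric phase-difference distributions, 1 for a
  perfectly consistent non-zero lag.
* wPLI = |E[Im X]| / E[|Im X|] with X = z_x conj(z_y), the analytic
  cross-spectrum (Vinck estimator) — samples are weighted by the magnitude of
  the imaginary cross-spectrum, damping near-zero-lag contributions that
  volume conduction produces.
* AEC  = Pearson correlation of the two amplitude envelopes in the window.

The Hilbert transform is applied once to the full band-filtered series, which
is then segmented, avoiding edge transients inside every window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .types import BandSpec, Recording, WindowGrid

METRICS = ("PLI", "wPLI", "AEC")


@dataclass
class AnalyticSignal:
    """Analytic representation of a real band-limited signal."""

    z: np.ndarray  # complex, same length as the input

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.complex128)

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase(self) -> np.ndarray:
        # all-zero stretches report phase 0 by convention (angle(0) == 0)
        return np.angle(self.z)


def analytic(x: np.ndarray) -> AnalyticSignal:
    """Analytic signal via the Hilbert transform (per recording, not window)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 8:
        raise ValueError("signal too short for a meaningful Hilbert transform")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    return AnalyticSignal(_sig.hilbert(x, axis=-1))


def _as_z(x) -> np.ndarray:
    return x.z if isinstance(x, AnalyticSignal) else np.asarray(x)


def pli(x: AnalyticSignal, y: AnalyticSignal) -> float:
    """Phase lag index of two analytic signals over one window."""
    zx, zy = _as_z(x), _as_z(y)
    if zx.shape != zy.shape:
        raise ValueError("length mismatch")
    dphi = np.angle(zx) - np.angle(zy)
    return float(np.abs(np.mean(np.sign(np.sin(dphi)))))


def wpli(x: AnalyticSignal, y: AnalyticSignal) -> float:
    """Weighted phase lag index (cross-spectrum estimator).

    Returns 0 when E[|Im X|] vanishes (e.g. identical zero-lag signals), so
    the estimator is total and bounded in [0, 1].
    """
    zx, zy = _as_z(x), _as_z(y)
    if zx.shape != zy.shape:
        raise ValueError("length mismatch")
    imx = np.imag(zx * np.conj(zy))
    denom = np.mean(np.abs(imx))
    # relative guard: |Im X| that is pure rounding noise counts as zero
    floor = 1e-12 * np.mean(np.abs(zx) * np.abs(zy))
    if denom <= floor:
        return 0.0
    return float(np.abs(np.mean(imx)) / denom)


def aec(x: AnalyticSignal, y: AnalyticSignal) -> float:
    """Amplitude envelope correlation (Pearson r of the two envelopes).

    A zero-variance envelope makes the correlation undefined; 0 is returned
    in that case so connectivity matrices stay total.
    """
    ax, ay = np.abs(_as_z(x)), np.abs(_as_z(y))
    if ax.shape != ay.shape:
        raise ValueError("length mismatch")
    mx, my = ax.mean(), ay.mean()
    ax = ax - mx
    ay = ay - my
    # near-constant envelopes (relative to their level) are degenerate
    n = ax.size
    if (ax.std() <= 1e-9 * (abs(mx) + 1e-30)
            or ay.std() <= 1e-9 * (abs(my) + 1e-30)):
        return 0.0
    denom = np.sqrt((ax ** 2).sum() * (ay ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((ax * ay).sum() / denom, -1.0, 1.0))


_DIAGONAL = {"PLI": 0.0, "wPLI": 0.0, "AEC": 1.0}


@dataclass
class ConnectivityMatrix:
    """Symmetric channel-by-channel connectivity for one window and band."""

    metric: str
    values: np.ndarray
    band: BandSpec | None = None
    window_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        self.values = v


def _window_metrics(zw: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized all-pairs metric for one window.

    ``zw``: (n_channels, W) complex analytic samples. Returns (n, n).
    """
    n, W = zw.shape
    if metric == "AEC":
        env = np.abs(zw)
        means = env.mean(axis=1, keepdims=True)
        env = env - means
        norms = np.sqrt((env ** 2).sum(axis=1))
        degenerate = (env.std(axis=1)
                      <= 1e-9 * (np.abs(means[:, 0]) + 1e-30))
        norms[degenerate | (norms == 0)] = np.inf  # zero-variance -> AEC 0
        c = (env @ env.T) / np.outer(norms, norms)
        c = np.clip(c, -1.0, 1.0)
    elif metric == "PLI":
        ph = np.exp(1j * np.angle(zw))
        # sin(phi_i - phi_j) = Im(e^{i phi_i} conj(e^{i phi_j}))
        s = np.sign(np.einsum("iw,jw->ijw", ph, ph.conj()).imag)
        c = np.abs(s.mean(axis=2))
    elif metric == "wPLI":
        imx = np.einsum("iw,jw->ijw", zw, zw.conj()).imag
        num = np.abs(imx.mean(axis=2))
        den = np.abs(imx).mean(axis=2)
        amp = np.abs(zw)
        floor = 1e-12 * (amp @ amp.T) / W  # rounding-noise guard
        den[den <= floor] = np.inf
        c = num / den
    else:
        raise ValueError(f"unknown metric {metric!r}")
    c = (c + c.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(c, _DIAGONAL[metric])
    return c


def connectivity_matrix(windows: np.ndarray, metric: str,
                        band: BandSpec | None = None,
                        window_index: int = 0) -> ConnectivityMatrix:
    """All-pairs connectivity of one multichannel band-limited window.

    ``windows``: (n_channels, W) real samples or complex analytic samples.
    Real input is converted per channel with the Hilbert transform.
    """
    w = np.asarray(windows)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need a 2-D (channels x time) window, >= 2 channels")
    zw = w if np.iscomplexobj(w) else _sig.hilbert(w, axis=1)
    return ConnectivityMatrix(metric=metric, values=_window_metrics(zw, metric),
                              band=band, window_index=window_index)


def vectorize_upper(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Strict upper triangle in row-major (i < j) order; length n(n-1)/2."""
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else \
        np.asarray(matrix)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("need a square matrix")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def unvectorize_upper(vec: np.ndarray, n: int,
                      diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (symmetric fill)."""
    out = np.full((n, n), diagonal, dtype=np.float64)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def pair_index(n: int) -> list[tuple[int, int]]:
    """(i, j) channel-index pairs in the fixed vectorization order."""
    iu = np.triu_indices(n, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


@dataclass
class ConnectivityTensor:
    """Per-window, per-band connectivity for one subject.

    ``values`` has shape (n_windows, n_bands, n_channels, n_channels).
    """

    metric: str
    values: np.ndarray
    band_names: tuple[str, ...]
    channel_labels: tuple[str, ...]
    subject_id: str = "unknown"
    group_label: str | None = None
    grid: WindowGrid | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 4 or v.shape[2] != v.shape[3]:
            raise ValueError("values must be (windows, bands, n, n)")
        if v.shape[1] != len(self.band_names):
            raise ValueError("band_names length mismatch")
        if v.shape[2] != len(self.channel_labels):
            raise ValueError("channel_labels length mismatch")
        self.values = v

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def vectorized(self) -> np.ndarray:
        """(n_windows, n_bands * n_pairs) design rows, band-major."""
        K, B, n, _ = self.values.shape
        iu = np.triu_indices(n, k=1)
        return self.values[:, :, iu[0], iu[1]].reshape(K, B * len(iu[0]))

    def band_vectorized(self, band: str) -> np.ndarray:
        """(n_windows, n_pairs) rows for one band."""
        b = self.band_names.index(band)
        iu = np.triu_indices(self.values.shape[2], k=1)
        return self.values[:, b, iu[0], iu[1]]


def compute_tensor(band_signals: dict[str, np.ndarray], fs: float,
                   window_s: float, metric: str, overlap: float = 0.5,
                   K_target: int | None = None, edge_guard_s: float = 1.0,
                   channel_labels: tuple[str, ...] | None = None,
                   subject_id: str = "unknown",
                   group_label: str | None = None) -> ConnectivityTensor:
    """Full per-subject connectivity tensor from band-decomposed signals.

    The analytic signal is computed on each full band series; an
    ``edge_guard_s`` margin is then dropped from both ends (Hilbert edge
    transients) before windowing. If ``K_target`` is given the guarded series
    is truncated so every subject yields the same window count.
    """
    from .preprocess import truncate_to_count

    names = tuple(band_signals.keys())
    first = next(iter(band_signals.values()))
    n_ch = first.shape[0]
    if channel_labels is None:
        channel_labels = tuple(f"CH{i}" for i in range(n_ch))
    guard = int(round(edge_guard_s * fs))
    W = int(round(window_s * fs))
    S = int(round(W * (1.0 - overlap)))

    mats = []
    grid = None
    for name in names:
        x = np.asarray(band_signals[name])
        z = _sig.hilbert(x, axis=1)
        if guard > 0:
            z = z[:, guard:-guard]
        if K_target is not None:
            z = truncate_to_count(z, fs, window_s, overlap, K_target)
        grid = WindowGrid(W=W, S=S, T=z.shape[1])
        starts = grid.starts()
        band_mats = np.empty((grid.K, n_ch, n_ch))
        for k, t0 in enumerate(starts):
            band_mats[k] = _window_metrics(z[:, t0:t0 + W], metric)
        mats.append(band_mats)
    values = np.stack(mats, axis=1)  # (K, B, n, n)
    return ConnectivityTensor(metric=metric, values=values, band_names=names,
                              channel_labels=channel_labels,
                              subject_id=subject_id, group_label=group_label,
                              grid=grid)
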