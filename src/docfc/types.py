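"""Core containers shared across the pipeline.

A :class:`Recording` is the in-memory form of one subject's multichannel EEG;
a :class:`BandSpec` names one canonical frequency band; a :class:`WindowGrid`
describes a sliding-window segmentation with 50% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19 scalp electrodes of the 10-20 montage used throughout, in the fixed
#: order that also fixes connectivity-matrix row/column order.
CHANNELS_1020: tuple[str, ...] = (
    "F3", "F4", "C3", "C4", "F7", "F8", "P3", "P4", "T7", "T8",
    "P7", "P8", "O1", "O2", "Fp1", "Fp2", "Fz", "Pz", "Cz",
)

#: Fixed class order for the four consciousness states.
CLASS_ORDER: tuple[str, ...] = ("coma", "UWS", "MCS", "HC")


@dataclass(frozen=True)
class BandSpec:
    """One EEG frequency band: half-open interval (lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")

    @property
    def center(self) -> float:
        """Geometric-mean centre frequency of the band."""
        return float(np.sqrt(self.lo * self.hi))


#: Canonical band edges. The broadband front-end filter is 1-48 Hz, so gamma
#: is capped at 48 Hz.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 48.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)


@dataclass
class Recording:
    """Multichannel EEG samples with metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One 10-20 label per row of ``samples``.
    subject_id : str
    group_label : str or None
        One of ``CLASS_ORDER`` when known.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = "unknown"
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one channel label required per signal row")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def copy_with(self, samples: np.ndarray) -> "Recording":
        """Return a copy carrying new samples but the same metadata."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window segmentation bookkeeping (all quantities in samples)."""

    W: int            # window length
    S: int            # step (W // 2 for 50% overlap)
    T: int            # usable signal length
    K: int = field(init=False)  # number of windows

    def __post_init__(self) -> None:
        if self.W <= 0 or self.S <= 0:
            raise ValueError("window and step must be positive")
        if self.T < self.W:
            raise ValueError("signal shorter than one window")
        object.__setattr__(self, "K", (self.T - self.W) // self.S + 1)

    def starts(self) -> np.ndarray:
        """Start index t_k = k*S of each window."""
        return np.arange(self.K) * self.S
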