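"""Synthetic multichannel EEG with planted band-wise connectivity.

Each frequency band is driven by one latent oscillator at the band's
geometric-mean centre frequency. Channel *i*'s contribution in band *b* is

    x_ib(t) = A_ib(t) * cos(theta_b(t) + psi_bi + eps_bi(t))

where the amplitude envelopes A are positive transforms of <=1 Hz low-pass
Gaussian processes mixed through a one-factor model,

    e_i = a_i * s_shared + sqrt(1 - a_i^2) * u_i,   A_i = offset + e_i,

so that the envelope correlation of channels i and j is a_i * a_j, and the
phase jitter eps_bi consists of independent per-sample von Mises draws
(concentration kappa) smoothed with a band-adaptive moving average (100 ms
floor, longer for narrow low bands so modulation sidebands stay in-band) and
rescaled to the von Mises marginal scale, so the Hilbert transform can still
track the instantaneous phase while kappa governs the realized phase
consistency. Fixed per-channel phase
offsets psi plant consistent non-zero lags; band components are summed with
1/f-shaped broadband noise and 50 Hz mains interference.

Group presets encode the qualitative ordering of consciousness states
(coma < UWS < MCS < HC in both envelope coupling and phase consistency);
no quantitative clinical connectivity levels are claimed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .edf import write_edf
from .types import BAND_NAMES, CANONICAL_BANDS, CHANNELS_1020, CLASS_ORDER, \
    BandSpec, Recording

_ENVELOPE_OFFSET = 3.0     # envelope offset in envelope SDs (positivity)
_ENVELOPE_CUTOFF_HZ = 1.0  # low-pass cutoff of the envelope process
_JITTER_SMOOTH_S = 0.1     # moving-average length for phase jitter
_BAND_GAIN_UV = 2.0        # per-band carrier gain in microvolts


@dataclass
class GroupConnectivitySpec:
    """Planted connectivity for one group, parameterised per channel.

    ``loadings[b, i]`` are the one-factor envelope loadings (pairwise target
    envelope correlation is ``loadings[b,i] * loadings[b,j]``),
    ``kappa[b, i]`` the per-channel von Mises phase-jitter concentrations,
    and ``phase_offsets[b, i]`` the fixed per-channel phase lags in radians
    (pairwise mean lag is the difference of offsets).
    """

    group_label: str
    loadings: np.ndarray       # (n_bands, n_channels) in [0, 1]
    kappa: np.ndarray          # (n_bands, n_channels) >= 0
    phase_offsets: np.ndarray  # (n_bands, n_channels), radians
    noise_sd: float = 2.0
    line_amp: float = 1.0
    state_drift_sd: float = 0.05
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, float))
        self.kappa = np.atleast_2d(np.asarray(self.kappa, float))
        self.phase_offsets = np.atleast_2d(np.asarray(self.phase_offsets, float))
        if not (self.loadings.shape == self.kappa.shape
                == self.phase_offsets.shape):
            raise ValueError("loadings/kappa/phase_offsets shapes differ")
        if self.loadings.min() < 0 or self.loadings.max() > 1:
            raise ValueError("envelope loadings must lie in [0, 1]")
        if self.kappa.min() < 0:
            raise ValueError("kappa must be non-negative")
        if self.loadings.shape[0] != len(self.bands):
            raise ValueError("one parameter row required per band")

    @property
    def n_channels(self) -> int:
        return self.loadings.shape[1]

    def rho(self) -> np.ndarray:
        """Implied pairwise envelope correlations, (n_bands, n, n)."""
        r = np.einsum("bi,bj->bij", self.loadings, self.loadings)
        for b in range(r.shape[0]):
            np.fill_diagonal(r[b], 1.0)
        return r

    def delta(self) -> np.ndarray:
        """Implied pairwise mean phase lags (antisymmetric), radians."""
        return (self.phase_offsets[:, :, None]
                - self.phase_offsets[:, None, :])


@dataclass
class GroundTruth:
    """Planted parameters actually used for one subject."""

    rho: np.ndarray                 # (n_bands, n, n)
    kappa: np.ndarray               # (n_bands, n) per-channel concentrations
    delta: np.ndarray               # (n_bands, n, n)
    drifted_loadings: np.ndarray    # (n_blocks, n_bands, n)
    drifted_kappa: np.ndarray       # (n_blocks, n_bands, n)
    envelopes: np.ndarray = field(repr=False, default=None)  # (n_bands, n, T)

    def drifted_rho(self) -> np.ndarray:
        """Per-block implied pairwise envelope correlations, clipped to [0,1]."""
        r = np.einsum("wbi,wbj->wbij", self.drifted_loadings,
                      self.drifted_loadings)
        return np.clip(r, 0.0, 1.0)


def _lowpass_gaussian(rng: np.random.Generator, n: int, fs: float,
                      cutoff: float, size: int) -> np.ndarray:
    """`size` unit-variance Gaussian processes band-limited below `cutoff`."""
    white = rng.standard_normal((size, n))
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _jitter_smooth_s(band: BandSpec) -> float:
    """Phase-jitter averaging time for one band.

    The moving average must be long enough that phase-modulation sidebands
    stay inside the band (slow jitter), but short enough that phase
    consistency varies within an analysis window; 2 / (carrier margin to the
    nearer band edge) keeps >= 90% of a latent component's power in-band at
    the lowest preset concentration, with a 100 ms floor.
    """
    margin = min(band.center - band.lo, band.hi - band.center)
    return max(_JITTER_SMOOTH_S, 2.0 / margin)


def _smoothed_vonmises(rng: np.random.Generator, kappa: float, n: int,
                       fs: float, smooth_s: float) -> np.ndarray:
    """Slow phase jitter with a von Mises(kappa) marginal scale.

    Per-sample von Mises draws are smoothed with a moving average so the
    instantaneous phase stays extractable by the Hilbert transform, then
    rescaled to the raw draws' standard deviation so the planted
    concentration governs the realized jitter magnitude.
    """
    if kappa >= 1e8:
        return np.zeros(n)
    raw = rng.vonmises(0.0, max(kappa, 1e-12), size=n)
    m = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(m) / m
    smooth = signal.fftconvolve(np.pad(raw, (m, m), mode="wrap"),
                                kernel, mode="same")[m:m + n]
    s = smooth.std()
    if s > 0:
        smooth = smooth * (raw.std() / s)
    return smooth


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                fs: float) -> np.ndarray:
    """Unit-variance 1/f-shaped broadband noise."""
    nch, n = shape
    white = rng.standard_normal((nch, n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping[None, :], n=n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def generate_recording(spec: GroupConnectivitySpec, n_channels: int,
                       fs: float, duration_s: float, seed: int,
                       subject_id: str = "synthetic",
                       drift_block_s: float = 20.0,
                       keep_envelopes: bool = False,
                       ) -> tuple[Recording, GroundTruth]:
    """Simulate one subject's multichannel EEG with planted connectivity.

    Identical ``(spec, seed)`` always produce identical samples. The drift
    blocks (default 20 s) perturb the envelope loadings and phase
    concentrations block-wise with SD ``spec.state_drift_sd``, planting slow
    connectivity-state variability.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be at least 10 s")
    if n_channels < 2:
        raise ValueError("need at least two channels")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if n_channels != spec.n_channels:
        raise ValueError("spec is parameterised for a different channel count")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    n_bands = len(spec.bands)

    block_len = int(round(drift_block_s * fs))
    n_blocks = max(int(np.ceil(n / block_len)), 1)
    block_of = np.minimum(np.arange(n) // block_len, n_blocks - 1)

    drift_a = np.clip(
        spec.loadings[None, :, :]
        + spec.state_drift_sd * rng.standard_normal(
            (n_blocks, n_bands, n_channels)),
        0.0, 1.0)
    drift_k = spec.kappa[None, :, :] * np.exp(
        spec.state_drift_sd * rng.standard_normal(
            (n_blocks, n_bands, n_channels)))

    x = np.zeros((n_channels, n))
    envelopes = (np.empty((n_bands, n_channels, n))
                 if keep_envelopes else None)
    for b, band in enumerate(spec.bands):
        theta = 2 * np.pi * band.center * t + rng.uniform(0, 2 * np.pi)
        shared = _lowpass_gaussian(rng, n, fs, _ENVELOPE_CUTOFF_HZ, 1)[0]
        uniq = _lowpass_gaussian(rng, n, fs, _ENVELOPE_CUTOFF_HZ, n_channels)
        a_t = drift_a[block_of, b, :].T            # (n_channels, n)
        env = (_ENVELOPE_OFFSET + a_t * shared[None, :]
               + np.sqrt(1.0 - a_t ** 2) * uniq)
        env = np.maximum(env, 0.05)
        if keep_envelopes:
            envelopes[b] = env
        for i in range(n_channels):
            # blockwise-drifted concentration: draw jitter per block
            eps = np.empty(n)
            smooth_s = _jitter_smooth_s(band)
            for w in range(n_blocks):
                sl = slice(w * block_len, min((w + 1) * block_len, n))
                eps[sl] = _smoothed_vonmises(
                    rng, drift_k[w, b, i], sl.stop - sl.start, fs, smooth_s)
            phase = theta + spec.phase_offsets[b, i] + eps
            x[i] += _BAND_GAIN_UV * env[i] * np.cos(phase)

    if spec.noise_sd > 0:
        x += spec.noise_sd * _pink_noise(rng, (n_channels, n), fs)
    if spec.line_amp > 0:
        x += spec.line_amp * np.sin(2 * np.pi * 50.0 * t
                                    + rng.uniform(0, 2 * np.pi))

    labels = tuple(CHANNELS_1020[:n_channels]) if n_channels <= 19 else \
        tuple(f"CH{i}" for i in range(n_channels))
    rec = Recording(samples=x, fs=fs, channel_labels=labels,
                    subject_id=subject_id, group_label=spec.group_label)
    truth = GroundTruth(
        rho=spec.rho(), kappa=spec.kappa.copy(), delta=spec.delta(),
        drifted_loadings=drift_a, drifted_kappa=drift_k,
        envelopes=envelopes,
    )
    return rec, truth


def generate_cohort(specs: list[GroupConnectivitySpec],
                    n_subjects_per_group: int, fs: float, duration_s: float,
                    seed: int, **kwargs,
                    ) -> list[tuple[Recording, GroundTruth]]:
    """Simulate a cohort: ``len(specs) * n_subjects_per_group`` recordings.

    Subject seeds are spawned deterministically from the master seed with
    :class:`numpy.random.SeedSequence`, one child per subject, in group-major
    order.
    """
    if not specs:
        raise ValueError("need at least one group spec")
    if n_subjects_per_group < 1:
        raise ValueError("n_subjects_per_group must be >= 1")
    labels = [s.group_label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    children = np.random.SeedSequence(seed).spawn(
        len(specs) * n_subjects_per_group)
    out = []
    idx = 0
    for spec in specs:
        for s in range(n_subjects_per_group):
            child_seed = children[idx].generate_state(1)[0]
            idx += 1
            sid = f"{spec.group_label}-{s + 1:02d}"
            out.append(generate_recording(
                spec, spec.n_channels, fs, duration_s,
                seed=int(child_seed), subject_id=sid, **kwargs))
    return out


# ---------------------------------------------------------------------------
# Group presets

_PRESET_LEVELS = {
    # group -> (envelope-loading centre, kappa, drift SD)
    "coma": (0.40, 1.0, 0.10),
    "UWS": (0.55, 2.0, 0.08),
    "MCS": (0.67, 4.0, 0.06),
    "HC": (0.81, 8.0, 0.03),
}


def default_presets(n_channels: int = 19,
                    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
                    separation: float = 1.0,
                    ) -> list[GroupConnectivitySpec]:
    """Connectivity presets for the four consciousness states.

    Envelope coupling and phase concentration increase monotonically from
    coma to healthy controls. Per-channel loading profiles are spread around
    the group centre and permuted with a fixed group-specific permutation, so
    groups differ in both connectivity level and spatial pattern.
    ``separation`` scales the spread of group centres around their mean
    (1 = default presets; smaller values make groups harder to separate).
    """
    n_bands = len(bands)
    spread = np.linspace(-0.12, 0.12, n_channels)
    centre_mean = float(np.mean([v[0] for v in _PRESET_LEVELS.values()]))
    specs = []
    for g, (label, (centre, kappa, drift)) in enumerate(_PRESET_LEVELS.items()):
        centre = centre_mean + separation * (centre - centre_mean)
        perm_rng = np.random.default_rng(1000 + g)  # fixed spatial pattern
        loadings = np.empty((n_bands, n_channels))
        offsets = np.empty((n_bands, n_channels))
        for b in range(n_bands):
            profile = spread[perm_rng.permutation(n_channels)]
            loadings[b] = np.clip(centre + profile, 0.02, 0.98)
            offsets[b] = 0.12 * perm_rng.permutation(n_channels)
        specs.append(GroupConnectivitySpec(
            group_label=label,
            loadings=loadings,
            kappa=np.full((n_bands, n_channels), kappa),
            phase_offsets=offsets,
            noise_sd=2.0,
            line_amp=1.0,
            state_drift_sd=drift,
            bands=bands,
        ))
    return specs


# ---------------------------------------------------------------------------
# On-disk cohort layout: EDF per subject, JSON ground truth, CSV manifest

def write_cohort(cohort: list[tuple[Recording, GroundTruth]],
                 outdir: str | Path) -> Path:
    """Write EDF files, ground-truth JSON, and a manifest CSV.

    Returns the manifest path. Manifest columns: subject_id, group, file.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, truth in cohort:
        fname = f"{rec.subject_id}.edf"
        write_edf(rec, outdir / fname)
        gt = {
            "subject_id": rec.subject_id,
            "group": rec.group_label,
            "bands": list(BAND_NAMES[:truth.rho.shape[0]]),
            "rho": truth.rho.tolist(),
            "kappa": truth.kappa.tolist(),
            "delta": truth.delta.tolist(),
            "drifted_loadings": truth.drifted_loadings.tolist(),
        }
        with open(outdir / f"{rec.subject_id}_truth.json", "w") as fh:
            json.dump(gt, fh)
        rows.append({"subject_id": rec.subject_id, "group": rec.group_label,
                     "file": fname})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
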