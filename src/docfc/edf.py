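"""EDF import/export for recordings.

Reading goes through MNE's EDF reader. Writing uses a minimal EDF(+)-
compatible writer implemented here (16-bit samples, one-second data records),
sufficient for the synthetic cohorts this package produces; the MNE reader
serves as an independent round-trip check in the test suite.
"""

from __future__ import annotations

import datetime
import warnings
from pathlib import Path

import numpy as np

from .types import Recording

_HDR_DATE = datetime.datetime(2000, 1, 1, 0, 0, 0)


def _ascii(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording to an EDF file with 1-s data records.

    The sampling rate must be a positive integer; trailing samples that do not
    fill a whole data record are dropped.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per channel
    n_records = rec.n_times // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    data = rec.samples[:, : n_records * spr]
    nch = rec.n_channels

    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = bytearray()
    header += _ascii("0", 8)                                   # version
    header += _ascii(f"X X X {rec.subject_id}", 80)            # patient id
    header += _ascii(f"Startdate X X X X {rec.group_label or 'X'}", 80)
    header += _ascii(_HDR_DATE.strftime("%d.%m.%y"), 8)
    header += _ascii(_HDR_DATE.strftime("%H.%M.%S"), 8)
    header += _ascii(str(256 * (1 + nch)), 8)                  # header bytes
    header += _ascii("", 44)                                   # reserved
    header += _ascii(str(n_records), 8)
    header += _ascii("1", 8)                                   # record duration s
    header += _ascii(str(nch), 4)

    fields = [
        (16, [f"EEG {lab}" for lab in rec.channel_labels]),
        (80, ["" for _ in range(nch)]),                        # transducer
        (8, ["uV" for _ in range(nch)]),
        (8, [f"{v:.6g}"[:8] for v in phys_min]),
        (8, [f"{v:.6g}"[:8] for v in phys_max]),
        (8, [str(dig_min) for _ in range(nch)]),
        (8, [str(dig_max) for _ in range(nch)]),
        (80, ["" for _ in range(nch)]),                        # prefiltering
        (8, [str(spr) for _ in range(nch)]),
        (32, ["" for _ in range(nch)]),                        # reserved
    ]
    for width, values in fields:
        for v in values:
            header += _ascii(v, width)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # records: per record, all channels back to back
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Load an EDF file into a :class:`Recording` (microvolts)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(
        ch[4:] if ch.startswith("EEG ") else ch for ch in raw.ch_names
    )
    subject = "unknown"
    his = (raw.info.get("subject_info") or {}).get("his_id")
    if his:
        subject = his.split()[-1]
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        subject_id=subject,
        group_label=None,  # group assignment travels in the cohort manifest
    )
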