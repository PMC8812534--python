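"""Minimal European Data Format (EDF) serialization for multichannel EEG.

Implements the plain EDF container (16-bit integers with per-signal physical
scaling, 1-second data records): enough to round-trip a microvolt-scaled
scalp recording with channel labels and sampling rate.  Readers such as
``mne.io.read_raw_edf`` open the files produced here.

Limitations (deliberate): a single record duration of 1 s, identical
sampling rate across signals, no annotations/EDF+ events, and recordings are
truncated to a whole number of seconds.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .config import CHANNELS, SAMPLING_RATE_HZ, MAX_DURATION_S

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class Recording:
    """Multichannel EEG time series in µV.

    ``samples`` is ``(n_channels, n_samples)``; ``channels`` gives the scalp
    labels row by row.
    """

    channels: tuple[str, ...]
    fs: int
    samples: np.ndarray  # µV

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError("samples must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.duration_s > MAX_DURATION_S + 1e-9:
            raise ValueError(f"recording exceeds {MAX_DURATION_S:.0f} s cap")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)  # type: ignore[attr-defined]
        except (ValueError, AttributeError):
            pass
        try:
            return tuple(self.channels).index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self) -> "Recording":
        return Recording(tuple(self.channels), self.fs, self.samples.copy())


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str, *, patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write *rec* as plain EDF with 1-second data records.

    Trailing samples beyond the last whole second are dropped.  Physical
    min/max are set symmetrically per signal from the data range.
    """
    fs = int(rec.fs)
    n_rec = rec.samples.shape[1] // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one 1-s data record")
    data = rec.samples[:, : n_rec * fs]
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    scale = _DIG_MAX / phys_max
    digital = np.clip(np.rint(data * scale[:, None]), _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient_id, 80),
            _pad(recording_id, 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig = b"".join(_pad(lbl, 16) for lbl in rec.channels)
    sig += b"".join(_pad("AgAgCl electrode", 80) for _ in range(ns))
    sig += b"".join(_pad("uV", 8) for _ in range(ns))
    sig += b"".join(_pad(f"{-pm:.6g}"[:8], 8) for pm in phys_max)
    sig += b"".join(_pad(f"{pm:.6g}"[:8], 8) for pm in phys_max)
    sig += b"".join(_pad(str(_DIG_MIN), 8) for _ in range(ns))
    sig += b"".join(_pad(str(_DIG_MAX), 8) for _ in range(ns))
    sig += b"".join(_pad("", 80) for _ in range(ns))
    sig += b"".join(_pad(str(fs), 8) for _ in range(ns))
    sig += b"".join(_pad("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records: per record, each signal's fs samples contiguously
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path: str) -> Recording:
    """Read a plain EDF file written by :func:`write_edf` (or compatible)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig = fh.read(256 * ns)

        def field(offset: int, width: int) -> list[str]:
            block = sig[offset * ns : offset * ns + width * ns]
            return [block[i * width : (i + 1) * width].decode().strip() for i in range(ns)]

        labels = field(0, 16)
        phys_min = np.array([float(v) for v in field(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in field(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in field(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in field(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in field(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("mixed per-signal sampling rates not supported")
        n_per = spr[0]
        raw = np.frombuffer(fh.read(), dtype="<i2")

    raw = raw.reshape(n_rec, ns, n_per)
    digital = np.concatenate([raw[r] for r in range(n_rec)], axis=1).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    physical = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    fs = int(round(n_per / rec_dur))
    return Recording(tuple(labels), fs, physical)


def blank_recording(duration_s: float, fs: int = SAMPLING_RATE_HZ, channels: tuple[str, ...] = CHANNELS) -> Recording:
    """All-zero recording — convenient scaffold for tests."""
    n = int(round(duration_s * fs))
    return Recording(tuple(channels), fs, np.zeros((len(channels), n)))
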