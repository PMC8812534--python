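"""Single-hertz-bin and band power from artifact-free epochs.

Power spectral density is estimated per epoch and channel with a
Hann-windowed FFT (density scaling, so the PSD integral matches signal
variance), averaged over epochs (Welch-style) and then over the requested
scalp channels, and finally integrated into 48 one-hertz bins spanning
2–50 Hz.  Band power aggregates member bins; relative power divides each
band's absolute power by the summed power of the four bands, per child.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .config import (
    BAND_NAMES,
    BIN_EDGES_HZ,
    DEFAULT_BANDS,
    DEFAULT_REGIONS,
    N_BINS,
    REFERENCE_PAIR,
    BandDefinition,
    validate_band_tiling,
)
from .preprocess import EpochSet

BIN_COLUMNS: tuple[str, ...] = tuple(f"bin_{hz}" for hz in BIN_EDGES_HZ)


@dataclass
class BinSpectrum:
    """Absolute power (µV²) in each of the 48 single-hertz bins."""

    child_id: int
    power: np.ndarray  # shape (48,)
    n_epochs_used: int

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.power.shape}")
        if (self.power < 0).any():
            raise ValueError("bin powers must be non-negative")


@dataclass
class BandPower:
    """Per-child absolute (µV²) and relative band power, optionally by region."""

    child_id: int
    absolute: dict[str, float]
    relative: dict[str, float]
    region: dict[str, dict[str, float]] | None = None


def _mean_psd(epochs: EpochSet, channel_idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """PSD averaged over epochs then over the given channels.

    Returns ``(freqs, psd)`` with density scaling (µV²/Hz).
    """
    data = epochs.epochs[:, channel_idx, :]
    freqs, psd = signal.periodogram(data, fs=epochs.fs, window="hann", axis=-1, scaling="density")
    return freqs, psd.mean(axis=(0, 1))


def _integrate_bins(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Integrate a PSD into the 48 one-hertz bins [k, k+1), k = 2..49.

    Trapezoidal rule on the PSD grid, with the bin edges themselves added
    by linear interpolation so the result is exact for piecewise-linear
    spectra regardless of how the grid aligns with integer frequencies.
    """
    out = np.empty(N_BINS)
    for i, lo in enumerate(BIN_EDGES_HZ):
        hi = lo + 1
        inner = freqs[(freqs > lo) & (freqs < hi)]
        grid = np.concatenate(([lo], inner, [hi]))
        out[i] = np.trapezoid(np.interp(grid, freqs, psd), grid)
    return out


def _default_scalp(epochs: EpochSet) -> tuple[str, ...]:
    return tuple(c for c in epochs.channels if c not in REFERENCE_PAIR)


def bin_spectrum(
    epochs: EpochSet,
    channel_subset: tuple[str, ...] | None = None,
    child_id: int = -1,
) -> BinSpectrum:
    """Whole-scalp single-hertz-bin absolute power for one child.

    ``channel_subset`` defaults to all scalp channels except the reference
    pair.  Raises on an empty epoch set or unknown channel.
    """
    if epochs.n_usable < 1:
        raise ValueError("no usable epochs")
    subset = channel_subset if channel_subset is not None else _default_scalp(epochs)
    idx = epochs.channel_indices(tuple(subset))
    freqs, psd = _mean_psd(epochs, idx)
    return BinSpectrum(child_id=child_id, power=_integrate_bins(freqs, psd), n_epochs_used=epochs.n_usable)


def band_power(
    spec: BinSpectrum, bands: Sequence[BandDefinition] = DEFAULT_BANDS
) -> BandPower:
    """Aggregate bin powers into absolute and relative band power."""
    validate_band_tiling(bands)
    edges = {hz: i for i, hz in enumerate(BIN_EDGES_HZ)}
    absolute = {
        b.name: float(sum(spec.power[edges[hz]] for hz in b.bins)) for b in bands
    }
    total = sum(absolute.values())
    if total <= 0:
        raise ValueError("total band power is zero; relative power undefined")
    relative = {k: v / total for k, v in absolute.items()}
    return BandPower(child_id=spec.child_id, absolute=absolute, relative=relative)


def region_band_power(
    epochs: EpochSet,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    region_map: Mapping[str, tuple[str, ...]] = DEFAULT_REGIONS,
    child_id: int = -1,
) -> BandPower:
    """Whole-scalp band power plus per-region absolute band power.

    Each region's spectrum is averaged over that region's channels only.
    A channel assigned to more than one region is an error.
    """
    seen: dict[str, str] = {}
    for region, chans in region_map.items():
        for c in chans:
            if c in seen:
                raise ValueError(f"channel {c!r} mapped to both {seen[c]!r} and {region!r}")
            seen[c] = region

    whole = band_power(bin_spectrum(epochs, child_id=child_id), bands)
    regions: dict[str, dict[str, float]] = {}
    for region, chans in region_map.items():
        spec = bin_spectrum(epochs, channel_subset=tuple(chans), child_id=child_id)
        regions[region] = band_power(spec, bands).absolute
    whole.region = regions
    return whole


def channel_band_power(
    epochs: EpochSet, bands: Sequence[BandDefinition] = DEFAULT_BANDS
) -> pd.DataFrame:
    """Absolute band power per individual channel (long format: channel × band)."""
    validate_band_tiling(bands)
    rows = []
    for ch in epochs.channels:
        spec = bin_spectrum(epochs, channel_subset=(ch,))
        bp = band_power(spec, bands)
        for b in bands:
            rows.append({"channel": ch, "band": b.name, "power": bp.absolute[b.name]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-level containers
# ---------------------------------------------------------------------------

def spectra_to_frame(spectra: Iterable[BinSpectrum]) -> pd.DataFrame:
    """Stack per-child spectra into a DataFrame (one row per child)."""
    rows = []
    for s in spectra:
        row = {"id": s.child_id, "n_epochs_used": s.n_epochs_used}
        row.update(dict(zip(BIN_COLUMNS, s.power)))
        rows.append(row)
    return pd.DataFrame(rows)


def band_powers_to_frame(band_powers: Iterable[BandPower]) -> pd.DataFrame:
    """Stack per-child band powers: abs_<band>, rel_<band>, <region>_<band>."""
    rows = []
    for bp in band_powers:
        row: dict[str, float] = {"id": bp.child_id}
        for b, v in bp.absolute.items():
            row[f"abs_{b}"] = v
        for b, v in bp.relative.items():
            row[f"rel_{b}"] = v
        if bp.region:
            for region, per_band in bp.region.items():
                for b, v in per_band.items():
                    row[f"{region}_{b}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StandardizedSpectra:
    """Cohort-standardized single-hertz spectra.

    ``z``: per-child z-scores (rows = children, columns = bins), standardized
    with the full-sample mean and SD per bin.  ``group_mean``: mean z per
    arm.  ``difference``: high-arm minus low-arm mean z per bin.
    """

    z: pd.DataFrame
    group_mean: pd.DataFrame
    difference: pd.Series


def standardize_bins(spectra: pd.DataFrame, arms: pd.Series) -> StandardizedSpectra:
    """Z-score bin powers over the full sample and form group-mean curves.

    Because both arms are standardized against the pooled mean, the
    sample-size-weighted sum of the two arms' mean z-curves is identically
    zero per bin — the curves are mirror images of one another.

    Raises on fewer than 2 children or on a bin with zero SD (names the bin).
    """
    cols = [c for c in BIN_COLUMNS if c in spectra.columns]
    if len(cols) != N_BINS:
        raise ValueError("spectra frame must contain all 48 bin columns")
    if len(spectra) < 2:
        raise ValueError("need at least 2 children to standardize")
    X = spectra[cols].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero SD in bin(s): {[cols[i] for i in zero]}")
    z = pd.DataFrame((X - mu) / sd, columns=cols, index=spectra.index)
    arms = pd.Series(arms).reset_index(drop=True)
    z = z.reset_index(drop=True)
    group_mean = z.groupby(arms).mean()
    if not {"high", "low"} <= set(group_mean.index):
        raise ValueError("arms must contain both 'high' and 'low'")
    difference = group_mean.loc["high"] - group_mean.loc["low"]
    return StandardizedSpectra(z=z, group_mean=group_mean, difference=difference)
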