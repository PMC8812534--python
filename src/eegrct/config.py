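"""Shared configuration: montage, frequency-band grid, simulation parameters.

The defaults describe a four-site randomized cash-transfer cohort of 1,000
mother/infant dyads, 40% assigned to the high-cash arm, with resting EEG
collected at the age-1 visit on a 20-channel cap (19 scalp signals) at
500 Hz for up to 7 minutes.  Band-power means/SDs default to the low-cash
analytic-sample values (in µV²) and treatment effects are expressed as
standardized shifts (effect size × low-arm SD) on absolute band power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

#: 19 scalp signals of the 10-20 system carried by a 20-channel infant cap
#: (the 20th hardware channel is the DRL/CMS reference, not a scalp signal).
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Channels used as the offline reference; excluded from scalp averages.
REFERENCE_PAIR: tuple[str, str] = ("T7", "T8")

#: Frontal channels carry ocular (blink) artifact.
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")

#: Default scalp-region map (reference pair excluded).  Each scalp channel
#: belongs to exactly one region.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"),
    "central": ("C3", "C4", "Cz"),
    "parietal": ("P3", "P4", "P7", "P8", "Pz"),
    "occipital": ("O1", "O2"),
}

#: Approximate 2-D head-circle coordinates for the 19 channels (unit circle,
#: nose up) — enough to lay out a topographic map.
CHANNEL_COORDS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.51), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.51), "F8": (0.81, 0.59),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "P7": (-0.81, -0.59), "P3": (-0.40, -0.51), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.51), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

# ---------------------------------------------------------------------------
# Frequency grid
# ---------------------------------------------------------------------------

#: Lower edges of the 48 single-hertz analysis bins: [2,3), [3,4), ... [49,50).
BIN_EDGES_HZ: tuple[int, ...] = tuple(range(2, 50))
N_BINS: int = 48

BAND_NAMES: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    """Half-open single-hertz bin range ``[lo_hz, hi_hz)`` for one band."""

    name: str
    lo_hz: int
    hi_hz: int

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: lo_hz must be < hi_hz")

    @property
    def bins(self) -> range:
        return range(self.lo_hz, self.hi_hz)


#: Default band boundaries on the 48-bin grid.  Chosen so the four bands are
#: disjoint, ordered, and tile the full 2-50 Hz analysis range with the
#: mid-to-high bands (alpha, beta, gamma) covering everything above 6 Hz.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 2, 6),
    BandDefinition("alpha", 6, 10),
    BandDefinition("beta", 10, 20),
    BandDefinition("gamma", 20, 50),
)


def validate_band_tiling(bands: Sequence[BandDefinition]) -> None:
    """Raise if *bands* overlap or fail to tile the 48 analysis bins."""
    covered: list[int] = []
    for b in bands:
        covered.extend(b.bins)
    if len(covered) != len(set(covered)):
        raise ValueError("bands overlap")
    if sorted(covered) != list(BIN_EDGES_HZ):
        raise ValueError(
            f"bands must tile the {N_BINS} bins "
            f"[{BIN_EDGES_HZ[0]}, {BIN_EDGES_HZ[-1] + 1}) Hz"
        )


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

SAMPLING_RATE_HZ: int = 500
MAX_DURATION_S: float = 420.0  # 7-minute cap on a recording


@dataclass
class SimConfig:
    """Parameters of the synthetic randomized cohort and its EEG.

    Band-power means/SDs are the low-cash arm's absolute power in µV²;
    ``effect_sizes`` are standardized treatment effects — the high-cash
    latent mean for band *b* is ``mean[b] + effect_sizes[b] * sd[b]``.
    """

    n_dyads: int = 1000
    p_high: float = 0.40
    n_sites: int = 4
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"theta": 0.02, "alpha": 0.17, "beta": 0.26, "gamma": 0.23}
    )
    band_power_means: dict[str, float] = field(
        default_factory=lambda: {"theta": 40.268, "alpha": 7.441, "beta": 1.874, "gamma": 0.986}
    )
    band_power_sds: dict[str, float] = field(
        default_factory=lambda: {"theta": 23.317, "alpha": 4.213, "beta": 1.592, "gamma": 0.947}
    )
    #: Gaussian-copula correlation between latent band powers within a child.
    band_power_rho: float = 0.5
    #: Target EEG analytic-sample sizes (low arm, high arm).
    attrition: tuple[int, int] = (251, 184)
    missing_covariate_rate: float = 0.03
    #: Artifact rates, events per minute.
    blink_rate_per_min: float = 4.0
    movement_rate_per_min: float = 1.0
    blink_amplitude_uv: float = 250.0
    movement_amplitude_uv: float = 150.0
    #: Broadband 1/f background: exponent and total 2-50 Hz floor power as a
    #: fraction of the summed configured band means.
    one_over_f_exponent: float = 1.0
    floor_power_fraction: float = 0.01
    #: Half-width (Hz) of the linear density ramps joining adjacent bands at
    #: their interior boundaries (6, 10, 20 Hz).  Ramps keep the synthesized
    #: spectrum continuous so windowed PSD estimation stays unbiased at band
    #: edges; per-band integrals remain exact.
    band_edge_ramp_hz: float = 1.5
    #: Per-channel multiplicative gain jitter and independent sensor noise
    #: (fraction of total signal power).
    channel_gain_sd: float = 0.05
    channel_noise_fraction: float = 0.002
    duration_s: float = 300.0
    fs: int = SAMPLING_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_high < 1:
            raise ValueError("p_high must be in (0, 1)")
        if self.n_dyads < 1 or self.n_sites < 1:
            raise ValueError("n_dyads and n_sites must be positive")
        for band in BAND_NAMES:
            if self.band_power_sds.get(band, 0.0) <= 0:
                raise ValueError(f"band {band}: SD must be > 0")
            if self.band_power_means.get(band, 0.0) <= 0:
                raise ValueError(f"band {band}: mean power must be > 0")
            es = self.effect_sizes.get(band)
            if es is None or not abs(es) < 1e6:
                raise ValueError(f"band {band}: effect size must be finite")
        n_low, n_high = self.attrition
        if n_low < 0 or n_high < 0:
            raise ValueError("attrition targets must be non-negative")
        if n_low + n_high > self.n_dyads:
            raise ValueError("EEG sample cannot exceed cohort size")
        if not 0 <= self.missing_covariate_rate < 1:
            raise ValueError("missing_covariate_rate must be in [0, 1)")
        if not 0 < self.duration_s <= MAX_DURATION_S:
            raise ValueError(f"duration_s must be in (0, {MAX_DURATION_S}]")

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "attrition" in raw:
            raw["attrition"] = tuple(raw["attrition"])
        return cls(**raw)


def bands_as_frame_columns(bands: Sequence[BandDefinition] = DEFAULT_BANDS) -> dict[str, list[int]]:
    """Map band name → list of member bin lower edges (Hz)."""
    return {b.name: list(b.bins) for b in bands}
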