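"""Synthetic randomized cash-transfer cohort with infant EEG recordings.

The generator emulates the study conditions end to end so every downstream
stage is testable without restricted data:

* 1,000 mother/infant dyads randomized 40/60 to a high/low monthly cash
  gift across 4 recruitment sites, with baseline covariates drawn from
  documented marginal families;
* attrition to an EEG analytic sample with configurable per-arm counts
  (defaults 251 low / 184 high);
* per-child latent absolute band power (theta/alpha/beta/gamma, µV²) drawn
  from lognormal marginals matched to configured means/SDs, with the
  high-cash mean shifted by ``effect_size × SD`` per band;
* raw 19-channel, 500-Hz recordings whose expected band-integrated power
  spectral density equals the latent band power, over a 1/f background;
* optional blink and movement artifacts with a ground-truth sample mask.

Randomization is enforced by construction: treatment assignment is an
independent Bernoulli draw, so every baseline covariate is independent of
the arm.  All draws are pure functions of ``(config, seed, subject id)``;
per-subject streams are derived by seeding a generator with the
``(master seed, subject id, stream tag)`` entropy tuple.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    BAND_NAMES,
    CHANNELS,
    FRONTAL_CHANNELS,
    SimConfig,
)
from .edf import Recording

# Baseline covariates eligible for missingness and later mean imputation.
BASELINE_COVARIATES: tuple[str, ...] = (
    "mother_age",
    "mother_educ",
    "hh_income",
    "net_worth",
    "general_health",
    "mental_health",
    "race_ethnicity",
    "married",
    "n_adults",
    "n_other_children",
    "smoked_pregnancy",
    "alcohol_pregnancy",
    "father_in_home",
    "child_female",
    "birth_weight_g",
    "gestational_age_wk",
)

#: Covariates measured at the age-1 visit (never made missing).
VISIT_COVARIATES: tuple[str, ...] = ("child_age_months", "n_usable_epochs")

RACE_LEVELS: tuple[str, ...] = (
    "white_nh",
    "black_nh",
    "multiple_nh",
    "other_unknown",
    "hispanic",
)
_RACE_PROBS = np.array([0.092, 0.423, 0.044, 0.037, 0.404])
_RACE_PROBS = _RACE_PROBS / _RACE_PROBS.sum()

#: Column dictionary for the cohort CSV.
COLUMN_DICTIONARY: dict[str, str] = {
    "id": "dyad identifier, 0-based",
    "site": "recruitment metropolitan area, 1..n_sites",
    "arm": "randomized assignment: 'high' or 'low' cash gift",
    "mother_age": "mother's age at enrollment, years",
    "mother_educ": "completed maternal schooling, years",
    "hh_income": "household combined income at baseline, dollars/year",
    "net_worth": "household net-worth score (standardized continuous scale)",
    "general_health": "general maternal health score (standardized scale)",
    "mental_health": "maternal mental-health score (standardized scale)",
    "race_ethnicity": "maternal race/ethnicity, one of "
    + "/".join(RACE_LEVELS),
    "married": "mother married at baseline, 0/1",
    "n_adults": "number of adults in household",
    "n_other_children": "number of other children born to the mother",
    "smoked_pregnancy": "maternal smoking during pregnancy, 0/1",
    "alcohol_pregnancy": "maternal alcohol during pregnancy, 0/1",
    "father_in_home": "biological father living with mother, 0/1",
    "child_female": "child is female, 0/1",
    "birth_weight_g": "child birth weight, grams",
    "gestational_age_wk": "gestational age at birth, weeks",
    "child_age_months": "child age at the age-1 visit, months",
    "n_usable_epochs": "artifact-free EEG epochs contributed at the visit",
    "in_eeg_sample": "child is in the EEG analytic sample, 0/1",
}


def _rng(config_seed: int, *stream: int) -> np.random.Generator:
    """Deterministic per-stream generator from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), *map(int, stream)]))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate the randomized cohort table (one row per dyad).

    Treatment is an independent Bernoulli(``p_high``) draw per dyad; sites
    are assigned near-uniformly; covariate marginals are anchored on the
    analytic-sample descriptives (means/SDs or percentages).  A random
    subset of each arm is flagged ``in_eeg_sample`` to hit the configured
    per-arm analytic counts.

    Raises
    ------
    ValueError
        If a requested per-arm EEG count exceeds the realized arm size;
        the message names the offending arm.
    """
    n = config.n_dyads
    rng = _rng(config.seed, 1)

    arm = np.where(rng.random(n) < config.p_high, "high", "low")
    site = rng.integers(1, config.n_sites + 1, size=n)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "site": site,
            "arm": arm,
            "mother_age": _truncated_normal(rng, 27.0, 5.8, 18.0, 45.0, n),
            "mother_educ": _truncated_normal(rng, 12.0, 3.1, 4.0, 20.0, n),
            # moment-matched lognormal: mean ~$21k, heavy right tail
            "hh_income": np.round(rng.lognormal(np.log(21_000) - 0.5 * 0.70**2, 0.70, n), 0),
            "net_worth": rng.normal(0.0, 1.0, n),
            "general_health": rng.normal(0.0, 1.0, n),
            "mental_health": rng.normal(0.0, 1.0, n),
            "race_ethnicity": rng.choice(RACE_LEVELS, size=n, p=_RACE_PROBS),
            "married": (rng.random(n) < 0.25).astype(int),
            "n_adults": 1 + rng.poisson(0.9, n),
            "n_other_children": rng.poisson(1.4, n),
            "smoked_pregnancy": (rng.random(n) < 0.12).astype(int),
            "alcohol_pregnancy": (rng.random(n) < 0.07).astype(int),
            "father_in_home": (rng.random(n) < 0.45).astype(int),
            "child_female": (rng.random(n) < 0.47).astype(int),
            "birth_weight_g": _truncated_normal(rng, 3300.0, 450.0, 2500.0, 4800.0, n),
            "gestational_age_wk": _truncated_normal(rng, 39.3, 1.2, 37.0, 42.0, n),
            "child_age_months": _truncated_normal(rng, 12.8, 1.4, 10.5, 16.5, n),
            "n_usable_epochs": np.round(
                _truncated_normal(rng, 288.2, 183.7, 10.0, 840.0, n)
            ).astype(int),
        }
    )

    # EEG analytic sample: random per-arm subsets of the configured sizes
    df["in_eeg_sample"] = 0
    for arm_name, target in zip(("low", "high"), config.attrition):
        idx = df.index[df["arm"] == arm_name].to_numpy()
        if target > idx.size:
            raise ValueError(
                f"requested {target} EEG-sample children in the {arm_name!r} arm "
                f"but only {idx.size} dyads were randomized to it"
            )
        chosen = rng.choice(idx, size=target, replace=False)
        df.loc[chosen, "in_eeg_sample"] = 1

    # missingness in baseline covariates only
    if config.missing_covariate_rate > 0:
        for col in BASELINE_COVARIATES:
            mask = rng.random(n) < config.missing_covariate_rate
            if mask.any():
                if df[col].dtype == object:
                    df.loc[mask, col] = None
                else:
                    df[col] = df[col].astype(float)
                    df.loc[mask, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# Latent band power
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean/SD."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def floor_band_power(config: SimConfig) -> dict[str, float]:
    """Power (µV²) the 1/f background contributes inside each analysis band."""
    total = config.floor_power_fraction * sum(config.band_power_means[b] for b in BAND_NAMES)
    alpha = config.one_over_f_exponent
    lo_all, hi_all = 2.0, 50.0

    def integral(lo: float, hi: float) -> float:
        if abs(alpha - 1.0) < 1e-12:
            return np.log(hi / lo)
        return (hi ** (1 - alpha) - lo ** (1 - alpha)) / (1 - alpha)

    norm = total / integral(lo_all, hi_all)
    from .config import DEFAULT_BANDS

    return {b.name: norm * integral(float(b.lo_hz), float(b.hi_hz)) for b in DEFAULT_BANDS}


def draw_latent_band_powers(
    cohort: pd.DataFrame, config: SimConfig, family: str = "lognormal"
) -> pd.DataFrame:
    """Per-child latent absolute band power (µV²), one column per band.

    Default marginals are lognormal (the field's standard model for
    absolute EEG power), moment-matched to the configured low-arm mean/SD
    per band; the high-arm mean is shifted by ``effect_size × SD``.
    Cross-band dependence comes from a Gaussian copula with exchangeable
    correlation ``band_power_rho``.  Children whose draw in any band falls
    below the 1/f background contribution to that band (which would make
    the band-limited component non-positive) are redrawn, never clamped.

    ``family="normal"`` draws Gaussian marginals with the same means/SDs
    and correlation, without the positivity screen.  Normal draws can be
    negative and cannot feed signal synthesis; they exist for calibration
    studies of the estimation stages, where a symmetric light-tailed
    outcome isolates estimator behavior from distributional skew.
    """
    if family not in ("lognormal", "normal"):
        raise ValueError("family must be 'lognormal' or 'normal'")
    n = len(cohort)
    rng = _rng(config.seed, 2)
    rho = config.band_power_rho
    k = len(BAND_NAMES)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)

    is_high = (cohort["arm"] == "high").to_numpy()

    if family == "normal":
        sds = np.array([config.band_power_sds[b] for b in BAND_NAMES])
        means = np.empty((n, k))
        for j, band in enumerate(BAND_NAMES):
            m_lo = config.band_power_means[band]
            m_hi = m_lo + config.effect_sizes[band] * config.band_power_sds[band]
            means[:, j] = np.where(is_high, m_hi, m_lo)
        z = rng.standard_normal((n, k)) @ chol.T
        res = pd.DataFrame(means + z * sds, columns=list(BAND_NAMES))
        res.insert(0, "id", cohort["id"].to_numpy())
        return res

    mus = np.empty((n, k))
    sigmas = np.empty(k)
    for j, band in enumerate(BAND_NAMES):
        sd = config.band_power_sds[band]
        mean_low = config.band_power_means[band]
        mean_high = mean_low + config.effect_sizes[band] * sd
        mu_lo, sig = _lognormal_params(mean_low, sd)
        mu_hi, _sig_hi = _lognormal_params(mean_high, sd)
        mus[:, j] = np.where(is_high, mu_hi, mu_lo)
        # keep the low-arm sigma for both arms: the treatment shifts the
        # location, the spread stays (sig_hi would differ slightly because
        # the lognormal couples mean and variance)
        sigmas[j] = sig

    out = np.empty((n, k))
    todo = np.arange(n)
    for _ in range(200):
        z = rng.standard_normal((todo.size, k)) @ chol.T
        draw = np.exp(mus[todo] + z * sigmas)
        # keep only draws that synthesis can realize (positive band
        # component above the 1/f floor); resample the rest, never clamp
        ok = np.array(
            [
                band_component_levels(dict(zip(BAND_NAMES, row)), config) is not None
                for row in draw
            ]
        )
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            break
    else:  # pragma: no cover - would need pathological config
        raise RuntimeError("could not draw positive latent band powers")

    res = pd.DataFrame(out, columns=list(BAND_NAMES))
    res.insert(0, "id", cohort["id"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def band_component_levels(
    band_powers: dict[str, float], config: SimConfig
) -> tuple[dict[str, float], float] | None:
    """Plateau densities (µV²/Hz) of the band components and the ramp width.

    The synthesized band structure is piecewise linear: a plateau per band
    joined by linear ramps of half-width ``band_edge_ramp_hz`` at the three
    interior boundaries (continuity keeps windowed PSD estimation unbiased
    at band edges).  A ramp of half-width Δ at an interior edge shifts
    Δ/4·(neighbor − self) of power into each band, so the plateau levels
    solve a 4×4 linear system making every band's integral equal its latent
    power minus the 1/f floor contribution.

    A draw with one band far smaller than its neighbor may admit no
    positive solution at the configured Δ; the ramp is then halved until
    one exists (Δ = 0 reduces to sharp steps), so the latent marginals are
    never distorted by rejection.  Returns ``(levels, delta)``, or ``None``
    when even sharp steps fail — i.e. some band does not exceed its 1/f
    floor contribution (caller resamples or errors, never clamps).
    """
    from .config import DEFAULT_BANDS

    floors = floor_band_power(config)
    k = len(DEFAULT_BANDS)
    b = np.empty(k)
    for i, band in enumerate(DEFAULT_BANDS):
        excess = band_powers[band.name] - floors[band.name]
        if excess <= 0:
            return None
        b[i] = excess

    delta = config.band_edge_ramp_hz
    while True:
        A = np.zeros((k, k))
        for i, band in enumerate(DEFAULT_BANDS):
            A[i, i] = band.hi_hz - band.lo_hz
            for j_off in (-1, 1):  # interior neighbors
                j = i + j_off
                if 0 <= j < k:
                    A[i, i] -= delta / 4.0
                    A[i, j] += delta / 4.0
        levels = np.linalg.solve(A, b)
        if (levels > 0).all():
            return {bd.name: float(lv) for bd, lv in zip(DEFAULT_BANDS, levels)}, delta
        if delta < 1e-3:  # sharp steps and still non-positive: impossible,
            return None  # since A is then diagonal with positive rhs
        delta = 0.0 if delta < 0.1 else delta / 2.0


def _ramp_shape(freqs: np.ndarray, lo: float, hi: float, delta_lo: float, delta_hi: float) -> np.ndarray:
    """Trapezoid: 1 on the plateau, linear ramps of the given half-widths.

    A zero half-width makes the corresponding edge sharp (used at the outer
    2 Hz and 50 Hz edges of the analysis range).
    """
    out = np.zeros_like(freqs)
    if delta_lo > 0:
        rise = (freqs - (lo - delta_lo)) / (2 * delta_lo)
        out = np.clip(rise, 0.0, 1.0)
    else:
        out = (freqs >= lo).astype(float)
    if delta_hi > 0:
        fall = ((hi + delta_hi) - freqs) / (2 * delta_hi)
        out = np.minimum(out, np.clip(fall, 0.0, 1.0))
    else:
        out = np.where(freqs < hi, out, 0.0)
    return out


def _target_psd(freqs: np.ndarray, band_powers: dict[str, float], config: SimConfig) -> np.ndarray:
    """One-sided target PSD (µV²/Hz) on the rfft grid."""
    from .config import DEFAULT_BANDS

    alpha = config.one_over_f_exponent
    total_floor = config.floor_power_fraction * sum(config.band_power_means[b] for b in BAND_NAMES)

    def integral(lo: float, hi: float) -> float:
        if abs(alpha - 1.0) < 1e-12:
            return np.log(hi / lo)
        return (hi ** (1 - alpha) - lo ** (1 - alpha)) / (1 - alpha)

    norm = total_floor / integral(2.0, 50.0)
    f_eff = np.maximum(freqs, 1.0)  # flatten the background below 1 Hz
    psd = norm * f_eff ** (-alpha)
    psd[freqs == 0] = 0.0

    solved = band_component_levels(band_powers, config)
    if solved is None:
        raise ValueError(
            f"latent band powers {band_powers} admit no positive band "
            "component above the 1/f background; resample the latent draw"
        )
    levels, delta = solved
    lo_edge, hi_edge = DEFAULT_BANDS[0].lo_hz, DEFAULT_BANDS[-1].hi_hz
    for band in DEFAULT_BANDS:
        d_lo = delta if band.lo_hz != lo_edge else 0.0
        d_hi = delta if band.hi_hz != hi_edge else 0.0
        psd += levels[band.name] * _ramp_shape(freqs, band.lo_hz, band.hi_hz, d_lo, d_hi)
    return psd


def generate_recording(subject: pd.Series, config: SimConfig) -> Recording:
    """Synthesize one child's multichannel recording from latent band power.

    ``subject`` must carry ``id`` and the four latent band-power columns
    (``theta``/``alpha``/``beta``/``gamma``, µV²).  The signal is Gaussian
    with one-sided PSD equal to a 1/f background plus flat in-band
    components scaled so the expected PSD integral over each band equals the
    subject's latent power.  Channels are independent realizations of that
    subject-level PSD, modulated by a small per-channel gain jitter plus
    independent sensor noise — so per-channel band power is unbiased for the
    latent value and survives a within-scalp re-reference.  Bit-identical
    for the same ``(config.seed, id)``.
    """
    missing = [b for b in BAND_NAMES if b not in subject.index]
    if missing:
        raise ValueError(f"subject lacks latent band power for: {missing}")
    band_powers = {b: float(subject[b]) for b in BAND_NAMES}
    if any(not np.isfinite(v) or v <= 0 for v in band_powers.values()):
        raise ValueError("latent band powers must be positive and finite")

    fs = config.fs
    n = int(round(config.duration_s * fs))
    rng = _rng(config.seed, 3, int(subject["id"]))

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = _target_psd(freqs, band_powers, config)
    n_ch = len(CHANNELS)

    # per-channel complex Gaussian spectra with E[one-sided periodogram]=psd;
    # channels are independent realizations of the subject-level PSD (a
    # shared waveform would be nulled by the temporal-average re-reference)
    amp = np.sqrt(psd * fs * n / 2.0)
    spec = (
        amp[None, :]
        * (rng.standard_normal((n_ch, freqs.size)) + 1j * rng.standard_normal((n_ch, freqs.size)))
        / np.sqrt(2.0)
    )
    spec[:, 0] = 0.0
    if n % 2 == 0:
        spec[:, -1] = spec[:, -1].real * np.sqrt(2.0)
    base = np.fft.irfft(spec, n, axis=1)

    total_power = float(np.sum(psd) * (fs / n))
    gains = 1.0 + rng.normal(0.0, config.channel_gain_sd, n_ch)
    noise_sd = np.sqrt(config.channel_noise_fraction * total_power)
    samples = gains[:, None] * base + rng.normal(0.0, noise_sd, (n_ch, n))
    return Recording(CHANNELS, fs, samples)


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def inject_artifacts(
    rec: Recording, config: SimConfig, subject_id: int = 0
) -> tuple[Recording, np.ndarray]:
    """Add blink and movement artifacts; return the recording and a mask.

    Blinks are ~400-ms half-sine deflections of ``blink_amplitude_uv`` scale
    on frontal channels; movement artifacts are ~700-ms broadband bursts on
    all channels.  Event counts are Poisson with the configured per-minute
    rates.  The returned boolean mask marks contaminated samples; with both
    rates zero the input is returned unchanged (empty mask).
    """
    n = rec.samples.shape[1]
    fs = rec.fs
    mask = np.zeros(n, dtype=bool)
    if config.blink_rate_per_min <= 0 and config.movement_rate_per_min <= 0:
        return rec, mask

    rng = _rng(config.seed, 4, subject_id)
    out = rec.copy()
    minutes = n / fs / 60.0
    frontal_idx = [rec.channel_index(c) for c in FRONTAL_CHANNELS]

    n_blinks = rng.poisson(config.blink_rate_per_min * minutes)
    width = int(0.4 * fs)
    for _ in range(n_blinks):
        start = rng.integers(0, max(1, n - width))
        t = np.sin(np.pi * np.arange(width) / width)  # half-sine pulse
        amp = config.blink_amplitude_uv * (0.8 + 0.4 * rng.random())
        for ch in frontal_idx:
            out.samples[ch, start : start + width] += amp * t * (0.7 + 0.3 * rng.random())
        mask[start : start + width] = True

    n_moves = rng.poisson(config.movement_rate_per_min * minutes)
    width = int(0.7 * fs)
    smooth = np.ones(int(0.05 * fs)) / int(0.05 * fs)  # ~10 Hz low-pass
    for _ in range(n_moves):
        start = rng.integers(0, max(1, n - width))
        burst = rng.normal(0.0, 1.0, (out.n_channels, width))
        # movement artifact energy sits at low frequencies: smooth the
        # noise, then rescale to the configured amplitude
        burst = np.apply_along_axis(lambda r: np.convolve(r, smooth, mode="same"), 1, burst)
        burst *= config.movement_amplitude_uv / 2.0 / burst.std()
        taper = np.hanning(width)
        out.samples[:, start : start + width] += burst * taper[None, :]
        mask[start : start + width] = True

    return out, mask


# ---------------------------------------------------------------------------
# Direct band-power simulation (no signal synthesis)
# ---------------------------------------------------------------------------

def simulate_band_power_table(config: SimConfig, family: str = "lognormal") -> pd.DataFrame:
    """Cohort restricted to the EEG analytic sample, with latent band powers
    attached as outcome columns.

    Skips signal synthesis entirely: the latent powers stand in for the
    measured band powers.  This is the fast route for Monte-Carlo studies
    of the estimation stages (the spectral stage is unbiased for the latent
    values, so the estimators see the same data-generating process).
    ``family`` is passed to :func:`draw_latent_band_powers`.
    """
    cohort = generate_cohort(config)
    latent = draw_latent_band_powers(cohort, config, family=family)
    merged = cohort.merge(latent, on="id")
    return merged[merged["in_eeg_sample"] == 1].reset_index(drop=True)


def write_cohort_csv(cohort: pd.DataFrame, path: str) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
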