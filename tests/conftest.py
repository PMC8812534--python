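"""Shared fixtures: small synthetic cohorts and recordings.

Everything is generated in-process from seeds; no data files.  The
session-scoped study run keeps the expensive signal pipeline to one
execution shared by the report/acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eegrct
from eegrct.preprocess import epoch_and_reject

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> eegrct.SimConfig:
    """Compact cohort with short recordings for signal-level tests."""
    return eegrct.SimConfig(n_dyads=120, attrition=(35, 25), seed=7, duration_s=30.0)


@pytest.fixture(scope="session")
def clean_config() -> eegrct.SimConfig:
    """Artifact-free variant with longer recordings for recovery checks."""
    return eegrct.SimConfig(
        n_dyads=60,
        attrition=(15, 15),
        seed=5,
        duration_s=120.0,
        blink_rate_per_min=0.0,
        movement_rate_per_min=0.0,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    return eegrct.generate_cohort(small_config)


@pytest.fixture(scope="session")
def subject_with_latents(clean_config):
    """One EEG-sample child with latent band powers attached."""
    co = eegrct.generate_cohort(clean_config)
    lat = eegrct.draw_latent_band_powers(co, clean_config)
    merged = co.merge(lat, on="id")
    return merged[merged["in_eeg_sample"] == 1].iloc[0]


@pytest.fixture(scope="session")
def clean_recording(subject_with_latents, clean_config):
    return eegrct.generate_recording(subject_with_latents, clean_config)


@pytest.fixture(scope="session")
def study_run(small_config):
    """One full end-to-end study on the small cohort (signals included)."""
    return eegrct.run_study(small_config, n_resamples=200, artifacts=True)


@pytest.fixture(scope="session")
def band_power_table():
    """Direct (no-signal) analytic band-power table at the full sample sizes."""
    cfg = eegrct.SimConfig(seed=11)
    from eegrct.itt import impute_covariates

    df = eegrct.simulate_band_power_table(cfg)
    return impute_covariates(df, df["id"])


def sinusoid_epochs(freq_hz: float, epoch_s: float = 4.0, n_epochs: int = 30, fs: int = 500, amplitude: float = np.sqrt(2)):
    """EpochSet carrying a pure sinusoid on every scalp channel."""
    n = int(epoch_s * fs * n_epochs)
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    rec = eegrct.Recording(eegrct.CHANNELS, fs, np.tile(x, (len(eegrct.CHANNELS), 1)))
    return epoch_and_reject(rec, epoch_s=epoch_s, amp_uv=np.inf, overlap=0.0)
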