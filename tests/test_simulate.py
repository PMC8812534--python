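"""Generator contracts: randomization, attrition, determinism, signal model."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

import eegrct
from eegrct.simulate import (
    BASELINE_COVARIATES,
    band_component_levels,
    draw_latent_band_powers,
    floor_band_power,
    generate_cohort,
    generate_recording,
    inject_artifacts,
)


class TestCohort:
    def test_randomization_contract(self):
        cfg = eegrct.SimConfig(n_dyads=1000, seed=7)
        co = generate_cohort(cfg)
        assert len(co) == 1000
        share = (co["arm"] == "high").mean()
        # binomial noise around 0.40 at n=1000: 4 sigma ~ 0.062
        assert abs(share - 0.40) < 0.065
        assert set(co["site"]) == {1, 2, 3, 4}

    def test_attrition_counts_exact(self, cohort):
        sample = cohort[cohort["in_eeg_sample"] == 1]
        assert (sample["arm"] == "low").sum() == 35
        assert (sample["arm"] == "high").sum() == 25

    def test_default_attrition_targets(self):
        co = generate_cohort(eegrct.SimConfig(seed=1))
        sample = co[co["in_eeg_sample"] == 1]
        assert (sample["arm"] == "low").sum() == 251
        assert (sample["arm"] == "high").sum() == 184

    def test_zero_missing_rate_leaves_no_gaps(self):
        cfg = eegrct.SimConfig(n_dyads=200, attrition=(40, 30), missing_covariate_rate=0.0, seed=2)
        co = generate_cohort(cfg)
        assert not co[list(BASELINE_COVARIATES)].isna().any().any()

    def test_missingness_hits_configured_rate(self):
        cfg = eegrct.SimConfig(n_dyads=2000, attrition=(100, 80), missing_covariate_rate=0.05, seed=3)
        co = generate_cohort(cfg)
        rate = co[list(BASELINE_COVARIATES)].isna().to_numpy().mean()
        assert 0.03 < rate < 0.07

    def test_infeasible_attrition_names_arm(self):
        cfg = eegrct.SimConfig(n_dyads=100, attrition=(30, 60), seed=4)
        with pytest.raises(ValueError, match="high"):
            generate_cohort(cfg)

    def test_deterministic_given_seed(self):
        cfg = eegrct.SimConfig(n_dyads=150, attrition=(30, 20), seed=9)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_randomization_independent_of_covariates(self):
        """Arm is assigned before covariates exist: regressing arm on any
        baseline covariate across many cohorts yields uniform p-values."""
        pvals = []
        for s in range(200):
            cfg = eegrct.SimConfig(n_dyads=300, attrition=(60, 40), seed=1000 + s)
            co = generate_cohort(cfg)
            y = (co["arm"] == "high").astype(float)
            x = co["mother_educ"].fillna(co["mother_educ"].mean())
            r = stats.pearsonr(x, y)
            pvals.append(r.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_age_range_plausible(self, cohort):
        age = cohort["child_age_months"].dropna()
        assert age.between(10, 17).all()
        assert 12.0 < age.mean() < 13.5


class TestLatentPowers:
    def test_marginal_moments_match_config(self):
        cfg = eegrct.SimConfig(n_dyads=20000, attrition=(100, 50), seed=6)
        co = generate_cohort(cfg)
        lat = draw_latent_band_powers(co, cfg)
        merged = co[["id", "arm"]].merge(lat, on="id")
        low = merged[merged["arm"] == "low"]
        for band in eegrct.BAND_NAMES:
            m, s = cfg.band_power_means[band], cfg.band_power_sds[band]
            assert abs(low[band].mean() - m) / m < 0.05
            assert abs(low[band].std() - s) / s < 0.15  # heavy-tailed SD

    def test_high_arm_mean_shift(self):
        cfg = eegrct.SimConfig(n_dyads=40000, attrition=(100, 50), seed=8)
        co = generate_cohort(cfg)
        lat = draw_latent_band_powers(co, cfg, family="normal")
        merged = co[["id", "arm"]].merge(lat, on="id")
        for band in ("alpha", "beta", "gamma"):
            shift = merged.groupby("arm")[band].mean().diff().dropna().abs().iloc[0]
            injected = cfg.effect_sizes[band] * cfg.band_power_sds[band]
            assert abs(shift - injected) < 3 * cfg.band_power_sds[band] / np.sqrt(10000)

    def test_positivity_above_floor(self):
        cfg = eegrct.SimConfig(n_dyads=5000, attrition=(100, 50), seed=10)
        co = generate_cohort(cfg)
        lat = draw_latent_band_powers(co, cfg)
        for _, row in lat.head(200).iterrows():
            solved = band_component_levels({b: row[b] for b in eegrct.BAND_NAMES}, cfg)
            assert solved is not None
            levels, delta = solved
            assert all(v > 0 for v in levels.values()) and delta >= 0


class TestRecording:
    def test_band_power_recovery_periodogram_oracle(self, clean_recording, subject_with_latents, clean_config):
        """Whole-recording periodogram integral per band within 10% of the
        latent value (oracle computed directly with scipy, not the spectral
        module)."""
        fs = clean_config.fs
        freqs, psd = signal.periodogram(clean_recording.samples, fs=fs, axis=1)
        psd = psd.mean(axis=0)
        for name, lo, hi in (("theta", 2, 6), ("alpha", 6, 10), ("beta", 10, 20), ("gamma", 20, 50)):
            sel = (freqs >= lo) & (freqs < hi)
            est = np.trapezoid(psd[sel], freqs[sel])
            assert abs(est / subject_with_latents[name] - 1) < 0.10

    def test_single_band_spectrum_is_floor_elsewhere(self, clean_config):
        """With only theta power, recovered alpha/beta/gamma power is the
        broadband floor's share, far below theta."""
        sub = pd.Series({"id": 0, "theta": 40.0, "alpha": 1.0, "beta": 0.5, "gamma": 0.4})
        # shrink the other bands toward the floor rather than zero (zero is
        # rejected by construction); theta dominates 40:1
        rec = generate_recording(sub, clean_config)
        freqs, psd = signal.periodogram(rec.samples, fs=clean_config.fs, axis=1)
        psd = psd.mean(axis=0)
        theta = np.trapezoid(psd[(freqs >= 2) & (freqs < 6)], freqs[(freqs >= 2) & (freqs < 6)])
        gamma = np.trapezoid(psd[(freqs >= 20) & (freqs < 50)], freqs[(freqs >= 20) & (freqs < 50)])
        assert theta > 30 and gamma < 1.0

    def test_nonpositive_latent_power_rejected(self, clean_config):
        sub = pd.Series({"id": 0, "theta": 40.0, "alpha": 7.0, "beta": -1.0, "gamma": 1.0})
        with pytest.raises(ValueError):
            generate_recording(sub, clean_config)

    def test_bit_identical_given_seed(self, subject_with_latents, clean_config):
        a = generate_recording(subject_with_latents, clean_config)
        b = generate_recording(subject_with_latents, clean_config)
        assert np.array_equal(a.samples, b.samples)

    def test_recording_shape_and_units(self, clean_recording, clean_config):
        assert clean_recording.samples.shape == (19, int(clean_config.duration_s * 500))
        assert clean_recording.fs == 500
        # µV scale: resting scalp EEG RMS in single-digit microvolts range
        rms = clean_recording.samples.std()
        assert 1 < rms < 50


class TestArtifacts:
    def test_zero_rates_identity(self, clean_recording, clean_config):
        out, mask = inject_artifacts(clean_recording, clean_config, subject_id=3)
        assert np.array_equal(out.samples, clean_recording.samples)
        assert not mask.any()

    def test_blinks_present_at_high_rate(self, clean_recording, clean_config):
        import dataclasses

        cfg = dataclasses.replace(clean_config, blink_rate_per_min=10.0, movement_rate_per_min=0.0)
        out, mask = inject_artifacts(clean_recording, cfg, subject_id=3)
        assert mask.any()

    def test_masked_spans_have_higher_amplitude(self, clean_recording, small_config):
        out, mask = inject_artifacts(clean_recording, small_config, subject_id=3)
        assert mask.any() and (~mask).any()
        inside = np.abs(out.samples[:, mask]).mean()
        outside = np.abs(out.samples[:, ~mask]).mean()
        assert inside > outside


def test_floor_power_sums_to_configured_fraction():
    cfg = eegrct.SimConfig()
    total = sum(floor_band_power(cfg).values())
    expected = cfg.floor_power_fraction * sum(cfg.band_power_means.values())
    assert abs(total - expected) < 1e-9
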