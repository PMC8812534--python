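# Methods

This note documents the generative model behind `eegrct.simulate`, the
estimators in the analysis stages, the defaults and why they were chosen,
and what the synthetic-data tests do and do not establish about real data.

## Study design being emulated

A randomized cash-transfer cohort: `n_dyads = 1000` mother/infant dyads
enrolled across 4 metropolitan recruitment sites, with 40% randomized to a
large monthly cash gift ($333/mo) and 60% to a nominal gift ($20/mo) —
$3,756/yr apart. Resting EEG is collected at the age-1 home visit with a
20-channel cap (19 scalp signals of the 10–20 system; the 20th hardware
channel is the amplifier reference) at 500 Hz for at most 7 minutes.
Attrition reduces the cohort to an EEG analytic sample of 251 low-arm and
184 high-arm children (both configurable).

## Cohort generator

Treatment assignment is an independent Bernoulli(0.40) draw per dyad and
sites are assigned uniformly, so randomization holds by construction:
every baseline covariate is independent of the arm, and across repeated
cohorts the arm-vs-covariate association p-values are uniform (tested).

Baseline covariates are drawn from simple parametric families anchored on
the analytic-sample descriptives: maternal age (truncated normal 27 ± 5.8
y), schooling (12 ± 3.1 y), household income (lognormal, mean ≈ $21k,
heavy right tail), race/ethnicity (five categories ≈ 9/42/4/4/41%),
child sex (47% female), birth weight (≥ 2500 g, healthy-at-birth design),
gestational age (37–42 wk), age at visit (12.8 ± 1.4 mo), usable epoch
count (truncated normal 288 ± 184). Net worth and the maternal
general-health and mental-health scales are generic standardized
continuous scores — the underlying survey instruments are not modeled.
**The joint distribution of covariates is independence**; nothing here is
a claim about the real cohort's joint structure. Missing values are
inserted completely at random at `missing_covariate_rate` (default 3%) in
baseline covariates only.

## Latent band power and the treatment effect

Each child has a latent absolute-power vector over the four bands. The
low-arm marginals are lognormal (the standard model for absolute EEG
power), moment-matched to configurable means/SDs in µV² — defaults
theta 40.268 (23.317), alpha 7.441 (4.213), beta 1.874 (1.592), gamma
0.986 (0.947). The high-arm mean is shifted by `effect_size × SD` per
band — defaults 0.02 / 0.17 / 0.26 / 0.23 for theta/alpha/beta/gamma —
with the low-arm log-scale spread retained. Cross-band dependence is a
Gaussian copula with exchangeable correlation ρ = 0.5, a middle-ground
choice (within-subject band powers correlate strongly in real EEG; the
true correlation structure is not modeled from data). A
`family="normal"` option draws Gaussian marginals instead; it exists for
estimator-calibration studies, where a light-tailed symmetric outcome
separates estimator behavior from distributional skew, and cannot feed
signal synthesis (draws may be negative).

## Signal synthesis

A recording is Gaussian noise with a target one-sided PSD built from:

1. a 1/f background (exponent 1.0, flattened below 1 Hz) whose 2–50 Hz
   integral is `floor_power_fraction` (default 1%) of the summed band
   means, and
2. four band components with piecewise-linear densities: a plateau per
   band joined by linear ramps of half-width 1.5 Hz at the interior
   boundaries (6, 10, 20 Hz). Plateau levels solve a small linear system
   so each band's PSD integral equals the child's latent power exactly
   (the 1/f contribution subtracted). Continuity matters: windowed PSD
   estimators are unbiased where the spectrum is locally linear, so sharp
   steps would leak power across band edges. When a draw has one band far
   below its neighbor the ramp is halved until the system has a positive
   solution (sharp steps in the limit) — draws are never clamped, and only
   draws below the 1/f floor itself are resampled.

The spectrum is realized in the frequency domain (complex Gaussian
coefficients with the target expected periodogram), per channel
*independently*: channels share the subject-level PSD, not the waveform,
modulated by a ±5% per-channel gain jitter plus a small independent
sensor-noise floor (0.2% of total power, ≈ 0.4 µV RMS). A shared waveform
would be nulled by the temporal-average re-reference; independent
realizations keep per-channel band power unbiased for the latent value.
After the T7/T8 re-reference, every scalp channel's power is inflated by a
known factor 1.5 (it gains half the reference pair's independent power);
this common factor cancels in standardized effect sizes, relative power,
z-scored spectra and every between-arm contrast, so recovery-against-
latent tests are run on raw epochs while the analysis chain runs
re-referenced.

Artifacts: blink-like 400-ms half-sine transients (≈ 250 µV) on the seven
frontal channels at 4/min, and 700-ms low-frequency-weighted broadband
bursts (≈ 75 µV RMS before tapering) on all channels at 1/min, with a
ground-truth sample mask. Every generator is a pure function of
`(config, master seed, subject id)`; per-subject streams come from seeding
a PCG64 with the `(seed, id, stream-tag)` entropy tuple.

## Preprocessing

Re-reference to the T7/T8 average (common-mode signals cancel exactly);
zero-phase order-4 Butterworth band-pass 0.3–50 Hz (applied forward and
backward, so the effective response is the squared one-pass response);
segmentation into 1-s epochs with 50% overlap; rejection of any epoch
where any screened scalp channel exceeds ±100 µV (one bad channel kills
the epoch; the degenerate reference pair is not screened). All four
parameters are per-call configuration; the defaults are this package's
choices, not a claim about any particular study's preregistered settings.
Tail segments shorter than one epoch are dropped; a recording shorter
than one epoch yields an empty epoch set rather than an error.

## Spectral reduction

Per epoch and channel, a Hann-windowed FFT with density scaling; PSDs are
averaged over epochs (Welch-style) and then over the included scalp
channels (power averaging, never amplitude averaging), and integrated into
48 one-hertz bins [k, k+1) for k = 2…49 by the trapezoidal rule with
interpolated bin edges (exact for piecewise-linear spectra on any grid
alignment). Band boundaries default to theta [2,6), alpha [6,10),
beta [10,20), gamma [20,50) — disjoint, ordered, tiling all 48 bins, with
everything above 6 Hz belonging to the mid-to-high bands; boundaries are
configuration. Relative power divides each band by the four-band sum per
child, so the four shares sum to 1 to machine precision. Regional power
repeats the reduction over standard 10–20 groupings (frontal
Fp1/Fp2/F3/F4/F7/F8/Fz, central C3/C4/Cz, parietal P3/P4/P7/P8/Pz,
occipital O1/O2). Cohort-standardized spectra z-score each bin with the
full-sample mean/SD (ddof = 1); because both arms are standardized against
the pooled mean, the sample-size-weighted sum of the two arms' mean
z-curves is identically zero — the mirror-image identity the reporting
stage exposes.

With 1-s epochs the spectral resolution is 1 Hz and the Hann main lobe
spans ±2 Hz, so single-bin quantities are smoothed; band aggregates are
insensitive to this, and bin-level tests use 4-s epochs where the kernel
is narrower than the synthesized band-edge ramps.

## Estimation

Outcomes are regressed on the treatment indicator, site indicators, and
(in the adjusted model) the baseline covariate list — maternal age,
schooling, income, net worth, general and mental health, race/ethnicity
(one-hot, first level as reference, explicit `missing` level), marital
status, adults in household, other children, smoking and alcohol during
pregnancy, father in household, child sex, birth weight, gestational
age — plus child age at visit and the usable epoch count. Missing
covariates are mean-imputed *from the analytic sample* (this differs from
the full-cohort mean whenever attrition is covariate-dependent; tested);
outcomes are never imputed. Covariates with no variation in the estimation
sample are dropped; genuinely collinear designs raise an error naming the
offending columns (pivoted QR).

Standard errors are HC1 by default; p-values use the normal approximation
to the robust t (a residual-df t option exists). The standardized effect
size is the adjusted coefficient over the low-arm outcome SD (ddof = 1) —
undefined (NaN) when that SD is zero. The production fit goes through
statsmodels OLS; the permutation engine re-derives the same treatment
t-statistic via Frisch–Waugh–Lovell residualization with the sandwich
reduced to the treatment column, verified against statsmodels to 1e-8.

The balance table reports per-arm means (SD) or percentages with
unadjusted two-sided tests: Welch t for continuous variables, pooled
two-proportion z for binaries.

## Multiplicity

Westfall–Young free stepdown per outcome family (defaults: one family of
the four absolute-power bands, one of the four relative-power bands).
Resampling permutes treatment labels within site strata — valid under
randomization and preserving the site structure — with covariates held
fixed (the null is "no treatment effect conditional on covariates"); a
residual bootstrap under the no-effect null is available behind
configuration. Observed and resampled |t| are the robust treatment
statistics; the stepdown orders observed |t| descending, compares each
member against the successive maxima over itself and all *less*
significant members, and enforces monotone adjusted p down the ordering.
Permutation p-values use the add-one convention `(count+1)/(B+1)`, which
makes the test exactly valid at finite B (the complete-null FWER of the
stepdown is exactly ⌊α(B+1)⌋/(B+1) by rank uniformity — 25/501 ≈ 0.0499
at the B = 500 used in checks). Production default is B = 10,000 with a
mandatory seed.

## Composite index

The mid-to-high summary index is, by default, the mean of the z-scores of
absolute alpha, beta and gamma power over the analytic sample
(Anderson/Kling-style index: sample mean 0, invariant to rescaling any
component); a raw sum option exists. The index is analyzed like any band
outcome. No particular published index value is targeted — summary-index
constructions differ in ways that change the coefficient's scale while
leaving the standardized effect size comparable.

## Problem sizes used in checks

The test-suite and acceptance-script simulations use: 30–120 s recordings
for signal-level checks (power estimates at 30 s are noisier than at the
full 5–7 min but unbiased, which is what the checks assert); 200
replicated cohorts at the full 251/184 analytic sizes for effect-size
recovery (band powers simulated directly, normal family, so the
Monte-Carlo mean is an unbiased estimate of the injected effect); and
1000–3000 null datasets × 500 resamples for the FWER calibration.

## Known limitations

* Real EEG microstructure — nonstationarity, topographic gradients,
  oscillatory bursts, line noise — is not modeled; the signal model is
  exactly "band-integrals + 1/f + artifacts", which is what makes latent
  recovery testable.
* Channels are spatially exchangeable (up to gain jitter), so regional
  analyses on synthetic cohorts have no true regional contrast unless one
  is injected channel-wise.
* Attrition is completely random within arm; covariate-dependent attrition
  (and hence any reweighting analysis) is out of scope.
* Covariates are mutually independent, so covariate adjustment changes
  precision only trivially in simulation; on real data its role is larger.
* Passing tests certify the pipeline's statistical machinery under this
  generative model — not that the model reproduces any real cohort's
  distributions beyond the anchored marginal moments.
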