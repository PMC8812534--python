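# eegrct

Intent-to-treat (ITT) analysis of infant EEG band power in a randomized
cash-transfer trial — as a reusable, fully tested pipeline with a synthetic
data generator, so every stage runs and is verifiable without access to any
restricted participant data.

## The scientific problem

Randomized unconditional cash-transfer trials ask whether reducing family
poverty changes infant brain activity. The outcome of interest is resting
EEG power: for each child, multichannel scalp recordings are reduced to
absolute power (µV²) in the theta, alpha, beta and gamma bands, and to
relative power (each band's share of the summed four-band power). The
estimand is the ITT effect of randomized assignment (high vs. low monthly
cash gift) on each outcome,

```
y_i = β·T_i + site_i·γ + x_i'δ + ε_i
```

estimated by OLS with site fixed effects, baseline covariates,
heteroskedasticity-consistent (HC1) standard errors, and standardized
effect sizes `β / SD(y | low-cash arm)`. Because eight band outcomes are
tested jointly, family-wise error is controlled with Westfall–Young free
stepdown resampling (treatment labels permuted within site strata, max-|t|
stepdown over each outcome family).

The package is aimed at trialists and developmental-neuroscience
methodologists who want to study, extend, or power-calculate this design:
simulation of the cohort and raw signals, preprocessing, spectral
reduction, estimation, multiplicity correction and reporting are separate,
composable modules.

## What's inside

| module | role |
| --- | --- |
| `eegrct.simulate` | randomized cohort (covariates, attrition) + raw 19-channel 500-Hz EEG with band-structured power, 1/f background and artifacts |
| `eegrct.preprocess` | T7/T8-average re-reference, zero-phase 0.3–50 Hz band-pass, 1-s epochs, ±100 µV rejection |
| `eegrct.spectral` | 48 single-hertz-bin spectra, absolute/relative band power, regional power, cohort z-scored spectra |
| `eegrct.itt` | mean imputation, robust OLS with site fixed effects, standardized effects, balance table |
| `eegrct.multiplicity` | Westfall–Young free stepdown over outcome families |
| `eegrct.composite` | mid-to-high-frequency summary index (z-mean or raw sum) |
| `eegrct.report` | treatment-effect table, spectra curves, topographic map data |
| `eegrct.edf` | plain-EDF serialization of recordings |

## Worked example

```python
import eegrct

cfg = eegrct.SimConfig(n_dyads=120, attrition=(35, 25), duration_s=30.0, seed=7)
res = eegrct.run_study(cfg, n_resamples=500)
print(res["table2"][["coef_adj", "effect_size", "p_unadjusted", "p_wy", "n"]].round(3))
```

prints (synthetic cohort, 60 analytic children, 30-s recordings):

```
           coef_adj  effect_size  p_unadjusted   p_wy   n
outcome
abs_alpha     0.479        0.057         0.864  0.978  60
abs_beta     -0.104       -0.025         0.943  0.978  60
abs_gamma     0.289        0.223         0.414  0.850  60
abs_theta    11.943        0.401         0.511  0.872  60
rel_alpha    -0.008       -0.122         0.719  0.860  60
rel_beta     -0.010       -0.235         0.539  0.860  60
rel_gamma     0.003        0.212         0.461  0.860  60
rel_theta     0.015        0.167         0.675  0.860  60
```

Each row is one EEG outcome: the covariate-adjusted treatment coefficient
(µV² for absolute rows, share for relative rows), the standardized effect
size (coefficient over the low-arm SD), the robust-OLS p-value, and the
Westfall–Young adjusted p-value within its four-band family. At this
deliberately small demo size nothing is significant — the injected effects
(0.02/0.17/0.26/0.23 SD for theta/alpha/beta/gamma) are only detectable at
the full trial's sample sizes, which `eegrct.pipeline.recovery_study`
verifies by replication.

A shell interface mirrors the stages:

```bash
eegrct simulate --out sim/ --seed 3 --n-recordings 5      # cohort CSV + EDFs
eegrct preprocess --in sim/sub-0007.edf --out epochs.npz
eegrct analyze --cohort sim/cohort.csv --power power.csv --out table2.csv
```

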