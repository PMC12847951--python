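# megprog

Longitudinal MEG spectral biostatistics for Parkinson's disease (PD) cohorts:
from region-wise resting-state power spectra to medication-adjusted clinical
progression statistics and an externally validated prediction of future motor
decline.

The package is aimed at clinical neurophysiology groups running two-visit
MEG/EEG studies: it implements the full analysis chain downstream of source
reconstruction (which is out of scope — inputs are parcellated region time
series or precomputed spectra over the 68 Desikan-Killiany cortical regions),
plus a synthetic cohort generator with known ground truth so every stage has a
parameter-recovery test surface.

## What it computes

**Spectral parameterization.** Region power spectra (Welch, 5 s segments, 50%
overlap, 1–47 Hz) are decomposed in log10 power into an aperiodic power law
and Gaussian oscillatory peaks:

    log10 P(f) = b − χ·log10 f + Σ_k h_k · exp(−(f − cf_k)² / 2σ_k²)

with offset *b*, exponent *χ* ≥ 0, and per-peak center frequency (CF),
power above the aperiodic component (PW) and bandwidth (BW = 2σ). Fitting is
robust (two-pass aperiodic fit that excludes peak-dominated bins) with up to
six peaks, a minimum peak height of 0.15 and a relative threshold of 2 SD of
the flattened spectrum. Band features are extracted for theta (4–8 Hz), alpha
(8–12 Hz), extended alpha (4–12 Hz) and beta (13–30 Hz).

**Medication-adjusted progression.** The motor-scale change confounds disease
progression with levodopa dose adjustments. An empirical coefficient α is
fitted by OLS,

    Δscore = α · ΔLEDD_rel + ε,      rate = (Δscore − α·ΔLEDD_rel) / years,

where ΔLEDD_rel is the relative change in levodopa equivalent daily dose.
Progressors are classified by rate > 0 or by a clinically meaningful decline
(> 4.6 points on the motor scale).

**Region-wise statistics.** Baseline group comparisons (feature ~ group +
age + sex), brain-behavior models within patients (symptom ~ feature + LEDD),
random-intercept mixed models for the group × time interaction with months as
the time variable, post-hoc within-group contrasts at 48 months, and a
progression ANCOVA — all with Benjamini-Hochberg FDR across regions and a
region-inclusion rule of ≥ 10 observations per group.

**Prediction.** Per region, the four spectral features (exponent, offset,
peak beta power, peak alpha frequency) are compressed to their first
principal component with dynamic feature selection under missingness; the
region PC1 scores enter a PLS1 (NIPALS) regression of the adjusted annual
progression rate, with leave-one-out component selection, VIP variable
importance, and a label-permutation test of the external-validation R².

## Worked example

```python
import numpy as np
from megprog import (SpectralGroundTruth, fit_spectral_model, welch_psd)
from megprog.synth import generate_roi_timeseries

truth = SpectralGroundTruth("postcentral-lh", offset_true=0.8,
                            exponent_true=1.1,
                            peaks_true=((10.0, 0.7, 1.2), (22.0, 0.3, 2.0)))
ts = generate_roi_timeseries(truth, duration_s=300, fs=1000, seed=1)
fit = fit_spectral_model(welch_psd(ts, fs=1000))
print(f"offset={fit.offset:.3f} exponent={fit.exponent:.3f} r2={fit.r_squared:.3f}")
for p in fit.peaks:
    print(f"  peak CF={p.cf:.2f} Hz PW={p.pw:.3f} BW={p.bw:.2f} Hz")
```

prints

```
offset=0.790 exponent=1.102 r2=0.993
  peak CF=10.03 Hz PW=0.683 BW=2.53 Hz
  peak CF=22.01 Hz PW=0.296 BW=4.26 Hz
```

i.e. from five minutes of synthesized data the aperiodic exponent is
recovered within ~0.002 and both oscillatory peaks within ~0.03 Hz of their
planted values.

The full pipeline runs from a single config:

```
megprog run --seed 1 --out run1           # synthetic end-to-end run
megprog synth --out cohort --seed 1       # or stage by stage
megprog progress --clinical cohort/clinical.csv --out rates.csv
```

`run` writes flat CSV/JSON artifacts (features, rates, baseline and
longitudinal statistics, PC1 summaries, predictions) plus a manifest with
checksums; reruns with the same config are bit-identical.

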