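# Methods

This note documents the models implemented in `megprog`, the defaults and the
reasoning behind the genuinely open design choices, and what the synthetic
cohort generator does and does not emulate.

## Spectral model and fitting

A region's power spectral density over 1–47 Hz is modeled in log10 power as a
fixed (knee-free) aperiodic power law plus up to six Gaussian peaks. The
fitting procedure in `megprog.spectral`:

1. **Welch PSD**: Hann window, mean-detrended 5 s segments, 50% overlap,
   giving a 0.2 Hz grid; the spectrum is truncated to the fit range
   (default 1–47 Hz, configurable because the low edge of usable bins depends
   on the acquisition high-pass).
2. **Robust aperiodic fit**: an ordinary log-log regression, then a refit
   excluding bins whose positive residual exceeds the 2.5th percentile of
   positive residuals — these are the peak-dominated bins that otherwise
   flatten the slope. On a power law with a planted 0.8-log-unit peak this
   two-pass scheme keeps the exponent error below 0.05 where single-pass OLS
   errs by ~0.14.
3. **Peak detection**: iteratively take the maximum of the flattened
   spectrum (ties resolve toward lower frequency), stop when the height falls
   below max(0.15, 2·SD of the flattened spectrum), guess the width from the
   half-height crossing, subtract, repeat up to six times.
4. **Joint refinement**: all Gaussians are refit together by bounded least
   squares (CF bounded to ±2 BW of the detected maximum, σ bounded to
   [0.5, 5] Hz i.e. BW ∈ [1, 10] Hz), then aperiodic and peaks are polished
   in a single simultaneous bounded least-squares problem. Reporting a true
   joint optimum makes the fit idempotent: refitting a model reconstruction
   reproduces the parameters to ~1e-14, and parameters transform correctly
   under power rescaling (offset shifts by log10 c, everything else
   invariant).
5. Peaks whose final height falls below 0.15 are dropped and the model
   re-polished. R² is computed between the model and the log10 spectrum.

The "peak threshold of 2" is interpreted as 2 SD of the flattened spectrum
(a relative threshold), matching the conventional semantics of spectral
parameterization tools. The beta band is 13–30 Hz for analysis; extending to
35 Hz is a plotting convention only and available as a band definition
override. Extended alpha (4–12 Hz) merges theta and alpha to capture slowed
alpha peaks.

## Synthetic cohort generator

`megprog.synth` emulates a two-group, two-visit resting-state study: 30
controls and 27 patients by default, follow-up 48.8 ± 7.3 months, 68
cortical regions. Ground truth per subject × visit × region is a
`SpectralGroundTruth` (offset, exponent, peak list); observations are either
shaped-noise time series (rFFT amplitude shaping of white noise, so the
spectral estimator sees realistic chi-square amplitude statistics and
Gaussian-shaped peaks rather than deterministic sinusoids) or, by default for
speed, Welch-like spectra obtained by multiplying the analytic PSD with
Gamma(k, 1/k) noise where k is the number of averaged segments.

Planted effects (defaults chosen as a plausible effect scale for
parameterized MEG spectra; the study they emulate does not publish effect
magnitudes, so these are generator conditions, not claims about the disease):

- patient-group elevation of exponent (+0.12), offset (+0.10) and peak beta
  power (+0.15 log10 units) in posterior regions;
- a patient-specific exponent increase of +0.10 per 48 months in the
  sensorimotor strip, scaled by each subject's actual follow-up interval;
- alpha peak slowing of −0.8 Hz in patients.

Subject traits (stable random intercepts) are shared across visits; the truth
tables carry no independent per-visit noise, so planted longitudinal effects
are stored exactly and estimation noise enters only through the spectra.

Clinical scores couple linearly to neural summaries: baseline bradykinesia
decreases with posterior beta power (coefficient −8 points per log10 unit),
rigidity increases with the sensorimotor exponent, and the follow-up change
contains a planted progression plus a medication term α_true·ΔLEDD_rel with
α_true = −4 points per unit relative LEDD change, so the downstream
adjustment stage has a recoverable truth. Item scores are integer,
clipped to their ordinal ranges, and distributed over the motor-exam items so
that subscore sums are consistent by construction. Controls score near zero
and take no medication.

What the generator does **not** emulate: source leakage and cross-region
correlation structure, head movement, sensor noise, cognitive decline
(the emulated cohort is cognitively stable), non-linear clinical
trajectories, and any within-region covariance between offset/exponent/peak
power beyond what the shared subject trait induces — real data's
cross-feature correlation is unknown, so passing tests demonstrate correct
recovery of the generator's conditions, not performance on real cohorts.

## Clinical progression

α is fitted separately per score (total and each of the bradykinesia,
rigidity, tremor, axial subscores); a shared-α mode exists for sensitivity
analysis. The α regression includes an intercept by default (standard OLS; a
through-origin option is exposed since the defining equation carries no
explicit intercept term). Subjects with zero baseline LEDD are excluded from
α fitting and flagged — relative dose change is undefined for them, and
controls are unmedicated by design. Years are computed per subject as
months/12, never from the cohort mean. Progressor rules use strict
inequalities (> 4.6 points; rate > 0).

## Region-wise statistics

- Two-sample demographic tests use pooled variance (the published df of 55
  for 30 + 27 subjects identifies the pooled, not Welch, test); the sex test
  is a continuity-corrected 2×2 chi-square (the uncorrected statistic on the
  published counts would be ~0.18, the corrected one 0.02, matching print).
- Sex enters models as a binary indicator; age in years, uncentered.
- ROI inclusion requires ≥ 10 non-missing observations per group (strict
  `< 10` excludes).
- FDR is Benjamini-Hochberg, applied per feature × model across regions by
  default; the family boundary is configurable because "across all models"
  is ambiguous — neither option is asserted as the published one.

## Longitudinal models

The group × time model is a random-intercept LMM estimated by REML with time
in months since baseline (0 at baseline). Fixed-effect t tests use
between-within (containment) degrees of freedom: design columns that vary
within subject are tested on n_obs − n_subjects − n_within df, purely
between-subject columns on n_subjects − n_between df. In the balanced
two-visit design this reproduces the exact df (55 for 57 subjects); it is
the documented fallback for the fractional Satterthwaite approximation,
which the Python mixed-model stack does not provide. When the residual
variance degenerates (noise-free fixtures), fixed effects fall back to OLS —
in balanced designs the GLS estimate coincides with OLS for any
random-intercept variance, and the interaction estimate is exactly the
difference-in-differences of cell means.

Post-hoc contrasts are evaluated at time = 48 months regardless of
per-subject jitter. The progression ANCOVA regresses the adjusted annual
rate on the feature change, baseline motor score and baseline feature value
as printed; medication change and follow-up time already enter through the
rate's construction, and a variant adding them as explicit covariates is
available because the prose covariate list and the printed formula differ.
No hemisphere flipping is performed for symptom laterality (the handling is
undescribed in the source analysis).

## Prediction pipeline

Region-wise PC1 uses the correlation matrix of the standardized features over
complete cases; features entirely missing in a region are dropped, and a
subject missing one retained feature is scored by projecting the available
standardized features onto the renormalized loading sub-vector (the
"dynamic feature selection without imputation" rule — the exact scoring of
partially missing subjects is underdetermined, and the renormalized
projection is this package's documented choice). The PC1 sign is fixed by a
non-negative exponent loading, since an arbitrary sign would scramble PLS
weights across resamples.

PLS1 is implemented as NIPALS on column-standardized predictors and a
centered outcome; standardization statistics from training are reused on the
validation cohort. VIP follows
`VIP_j = sqrt(p Σ_k SSY_k (w_jk/||w_k||)² / Σ_k SSY_k)` with
`SSY_k = q_k² t_kᵀt_k`, so squared VIPs average to one. Component count is
the leave-one-out minimum-RMSEP choice with ties resolved toward fewer
components (a one-SE rule is a config option). The permutation test shuffles
the training outcome, refits, and evaluates on the untouched validation
pair; the p-value is the plain fraction (#null ≥ observed)/n_perm, matching
the printed arithmetic of the quantity it emulates (the (b+1)/(n+1)
estimator is exposed as an option). Whether component selection is re-run
inside each permutation is a config switch (off by default for speed).

## Numerical choices and problem sizes

- Aperiodic exponents are clamped to ≥ 0 at report time.
- `curve_fit` failures fall back to the detection-stage guesses rather than
  erroring, so batch parameterization never aborts on a pathological region.
- Monte-Carlo suites use sizes chosen for tight-but-fast checks: 200 spectra
  at 300 s / 1 kHz for parameter recovery, 100 cohorts of 57 subjects for
  interaction coverage, 200 repetitions × 99 permutations for calibration of
  the permutation p, 50 cohorts for the medication-adjustment and
  signal-recovery suites (the latter at 50 training / 40 validation subjects,
  where the permutation test has adequate power for an 0.4 predictable
  fraction).

## Known limitations

- Fractional (Satterthwaite) df are approximated by containment df; for
  strongly unbalanced missingness the reported df will be coarser than a
  dedicated mixed-model df machinery would give.
- The linear annualized progression rate inherits the linearity assumption;
  non-linear trajectories are out of scope.
- Knee-mode aperiodic fits and time-resolved (burst) features are not
  implemented.
- The synthetic generator's cross-feature covariance is a free parameter of
  convenience, not an empirical claim.
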