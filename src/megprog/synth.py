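"""Synthetic longitudinal cohort generator with known spectral ground truth.

Emulates a two-group (healthy control / Parkinson's disease), two-timepoint
resting-state study: each subject contributes, at each visit, one power
spectrum per cortical region plus a clinical record (MDS-UPDRS III motor items,
LEDD, MoCA, demographics).  Every neural observation is backed by a stored
:class:`SpectralGroundTruth` so downstream estimators have a parameter-recovery
oracle.

The spectral model is the standard parameterization of neural power spectra:
in log10 power, an aperiodic power-law component ``offset - exponent*log10(f)``
plus up to six Gaussian oscillatory peaks.  Planted effects:

* a cross-sectional group effect on the aperiodic exponent/offset and on peak
  beta power (patients higher, posterior accent),
* a disease-specific longitudinal increase of the exponent in sensorimotor
  regions (scaled by each subject's actual months to follow-up),
* a slowing of the alpha peak frequency in patients,
* clinical subscores linearly coupled to the planted neural features, with a
  medication (LEDD) term so that the downstream medication-adjustment stage
  has a recoverable true coefficient.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import DK68, POSTERIOR, SENSORIMOTOR

__all__ = [
    "SpectralGroundTruth",
    "CohortConfig",
    "SyntheticCohort",
    "analytic_log_psd",
    "generate_roi_timeseries",
    "generate_cohort",
    "generate_clinical_table",
]

#: MDS-UPDRS III item ids (laterality sub-items pre-summed) by subscore.
BRADYKINESIA_ITEMS = ("3.2", "3.4", "3.5", "3.6", "3.7", "3.8", "3.14")
RIGIDITY_ITEMS = ("3.3a", "3.3b", "3.3c", "3.3d", "3.3e")
TREMOR_ITEMS = ("3.15", "3.16", "3.17", "3.18")
AXIAL_ITEMS = ("3.1", "3.9", "3.10", "3.11", "3.12", "3.13")
ALL_ITEMS = BRADYKINESIA_ITEMS + RIGIDITY_ITEMS + TREMOR_ITEMS + AXIAL_ITEMS

SUBSCORE_ITEMS: Mapping[str, tuple[str, ...]] = {
    "bradykinesia": BRADYKINESIA_ITEMS,
    "rigidity": RIGIDITY_ITEMS,
    "tremor": TREMOR_ITEMS,
    "axial": AXIAL_ITEMS,
}


@dataclass(frozen=True)
class SpectralGroundTruth:
    """True spectral parameters for one region observation.

    ``peaks_true`` holds ``(center_freq_hz, height_log10, sd_hz)`` triplets;
    heights are in log10-power units above the aperiodic component.
    """

    region_label: str
    offset_true: float
    exponent_true: float
    peaks_true: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.exponent_true < 0:
            raise ValueError("exponent_true must be >= 0")
        if len(self.peaks_true) > 6:
            raise ValueError("at most 6 peaks supported")
        for cf, height, sd in self.peaks_true:
            if not (1.0 <= cf <= 47.0):
                raise ValueError(f"peak center {cf} outside [1, 47] Hz")
            if height <= 0:
                raise ValueError("peak height must be > 0")
            if sd <= 0:
                raise ValueError("peak sd must be > 0")


@dataclass
class CohortConfig:
    """Study-condition parameters for :func:`generate_cohort`.

    Defaults mirror the emulated cohort: 30 controls and 27 patients measured
    twice roughly four years apart over 68 cortical regions, with posterior
    beta-power elevation and sensorimotor aperiodic steepening in the patient
    group, and clinical motor scores coupled to those neural features.
    """

    n_hc: int = 30
    n_pd: int = 27
    n_regions: int = 68
    seed: int = 0

    followup_months_mean: float = 48.8
    followup_months_sd: float = 7.3

    # planted neural effects (native units of the spectral parameters)
    group_effect_exponent: float = 0.12
    group_effect_offset: float = 0.10
    #: exponent increase in patients per 48 months of follow-up
    time_effect_exponent_pd: float = 0.10
    beta_power_group_effect: float = 0.15
    alpha_freq_group_effect: float = -0.8

    exponent_time_regions: tuple[str, ...] = SENSORIMOTOR
    group_effect_regions: tuple[str, ...] = POSTERIOR

    # population spread of the spectral parameters
    exponent_base_mean: float = 1.0
    exponent_region_sd: float = 0.12
    offset_base_mean: float = 0.5
    offset_region_sd: float = 0.15
    subject_sd: float = 0.08  # stable subject trait added to exponent & offset

    # oscillatory peaks: presence probability and parameter spread
    p_alpha_peak: float = 0.75
    p_beta_peak: float = 0.85
    p_theta_peak: float = 0.2

    # clinical coupling: subscore = const + coef * centered neural summary + noise
    # keys: (subscore, neural summary); see generate_clinical_table
    clinical_coupling: dict = field(
        default_factory=lambda: {
            "bradykinesia": {"const": 8.4, "feature": "beta_power", "coef": -8.0, "noise_sd": 3.0},
            "rigidity": {"const": 3.0, "feature": "exponent", "coef": 4.0, "noise_sd": 2.0},
            "tremor": {"const": 3.6, "feature": None, "coef": 0.0, "noise_sd": 3.0},
            "axial": {"const": 2.7, "feature": None, "coef": 0.0, "noise_sd": 2.0},
        }
    )
    #: coupling of the *change* in rigidity to the planted exponent change
    rigidity_progression_coef: float = 10.0
    #: annual progression of bradykinesia planted in patients (points/year)
    bradykinesia_progression_rate: float = 0.4

    # medication schedule: baseline dose distribution and relative increase
    ledd_schedule: dict = field(
        default_factory=lambda: {
            "baseline_mean": 469.6,
            "baseline_sd": 270.2,
            "rel_change_mean": 0.85,
            "rel_change_sd": 0.45,
        }
    )
    #: true medication coefficient: score points per unit relative LEDD change
    ledd_alpha_true: float = -4.0

    age_mean_hc: float = 69.5
    age_sd_hc: float = 8.7
    age_mean_pd: float = 66.1
    age_sd_pd: float = 10.2

    #: "spectra" synthesizes noisy Welch-like spectra directly (fast);
    #: "timeseries" synthesizes region time series to be Welch'd downstream.
    mode: Literal["spectra", "timeseries"] = "spectra"
    duration_s: float = 300.0
    fs: float = 1000.0
    segment_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_hc <= 0 or self.n_pd <= 0 or self.n_regions <= 0:
            raise ValueError("subject and region counts must be positive")
        if self.followup_months_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_regions > len(DK68):
            raise ValueError(f"n_regions may not exceed {len(DK68)}")


@dataclass
class SyntheticCohort:
    """Generated cohort: neural observations, clinical table, and ground truth."""

    spectra: pd.DataFrame | None
    timeseries: dict[tuple[str, str, str], np.ndarray] | None
    clinical: pd.DataFrame
    truth: pd.DataFrame
    freqs: np.ndarray | None
    config: CohortConfig

    def write(self, outdir: str | Path) -> None:
        """Write clinical and spectra CSVs plus a JSON ground-truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.clinical.to_csv(outdir / "clinical.csv", index=False)
        if self.spectra is not None:
            self.spectra.to_csv(outdir / "spectra.csv", index=False)
        truth = self.truth.copy()
        truth["peaks_true"] = truth["peaks_true"].map(json.dumps)
        truth.to_csv(outdir / "truth.csv", index=False)
        meta = {"config": _config_to_jsonable(self.config)}
        if self.freqs is not None:
            meta["freqs"] = self.freqs.tolist()
        (outdir / "cohort.json").write_text(json.dumps(meta, indent=2))


def _config_to_jsonable(config: CohortConfig) -> dict:
    out = dataclasses.asdict(config)
    for key, val in out.items():
        if isinstance(val, tuple):
            out[key] = list(val)
    return out


def analytic_log_psd(freqs: np.ndarray, truth: SpectralGroundTruth) -> np.ndarray:
    """Noise-free log10 PSD of the spectral model at the given frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    log_psd = truth.offset_true - truth.exponent_true * np.log10(freqs)
    for cf, height, sd in truth.peaks_true:
        log_psd = log_psd + height * np.exp(-0.5 * ((freqs - cf) / sd) ** 2)
    return log_psd


def generate_roi_timeseries(
    truth: SpectralGroundTruth,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthesize a region time series whose expected PSD follows *truth*.

    White Gaussian noise is shaped in the frequency domain: the rFFT of the
    noise is multiplied by the square root of the target one-sided PSD, which
    preserves the randomized phases and chi-square amplitude statistics a
    spectral estimator sees on real data.  Below 1 Hz the power law is clamped
    at its 1 Hz value to keep the series finite.
    """
    if duration_s < 30:
        raise ValueError("duration_s must be >= 30 s")
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = np.zeros_like(freqs)
    pos = freqs > 0
    clamped = np.maximum(freqs[pos], 1.0)
    log_psd = truth.offset_true - truth.exponent_true * np.log10(clamped)
    for cf, height, sd in truth.peaks_true:
        log_psd = log_psd + height * np.exp(-0.5 * ((freqs[pos] - cf) / sd) ** 2)
    target[pos] = 10.0 ** log_psd

    white = rng.standard_normal(n)
    coef = np.fft.rfft(white)
    coef[0] = 0.0
    # scale so that the one-sided periodogram 2|X_k|^2/(fs*n) has mean target
    coef[pos] *= np.sqrt(target[pos] * fs / 2.0)
    return np.fft.irfft(coef, n=n)


def _welch_noise_dof(duration_s: float, segment_s: float) -> int:
    """Effective number of averaged segments for 50%-overlap Welch."""
    n_seg = int(np.floor((duration_s - segment_s) / (segment_s / 2.0))) + 1
    return max(n_seg, 1)


def _draw_truths(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Draw per-region population parameters and per-subject traits."""
    regions = list(DK68[: config.n_regions])
    region_params = {}
    for region in regions:
        region_params[region] = {
            "offset": rng.normal(config.offset_base_mean, config.offset_region_sd),
            "exponent": max(rng.normal(config.exponent_base_mean, config.exponent_region_sd), 0.2),
        }
    return {"regions": regions, "region_params": region_params}


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (deterministic given ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    layout = _draw_truths(config, rng)
    regions = layout["regions"]
    region_params = layout["region_params"]

    subjects = [f"hc{i:03d}" for i in range(config.n_hc)] + [
        f"pd{i:03d}" for i in range(config.n_pd)
    ]
    groups = ["HC"] * config.n_hc + ["PD"] * config.n_pd

    followup_months = np.maximum(
        rng.normal(config.followup_months_mean, config.followup_months_sd, len(subjects)), 12.0
    )
    ages = np.where(
        np.asarray(groups) == "HC",
        rng.normal(config.age_mean_hc, config.age_sd_hc, len(subjects)),
        rng.normal(config.age_mean_pd, config.age_sd_pd, len(subjects)),
    )
    sexes = rng.choice(["F", "M"], size=len(subjects))

    truth_rows = []
    for subj, group in zip(subjects, groups):
        subj_trait_exp = rng.normal(0.0, config.subject_sd)
        subj_trait_off = rng.normal(0.0, config.subject_sd)
        months = followup_months[subjects.index(subj)]
        for region in regions:
            base = region_params[region]
            is_pd = group == "PD"
            in_group_set = region in config.group_effect_regions
            in_time_set = region in config.exponent_time_regions

            exp_base = base["exponent"] + subj_trait_exp + rng.normal(0, 0.05)
            off_base = base["offset"] + subj_trait_off + rng.normal(0, 0.06)
            if is_pd and in_group_set:
                exp_base += config.group_effect_exponent
                off_base += config.group_effect_offset

            # stable peak structure per subject x region
            peaks_base: list[tuple[float, float, float]] = []
            peaks_fu: list[tuple[float, float, float]] = []
            if rng.uniform() < config.p_theta_peak:
                cf = float(np.clip(rng.normal(6.0, 0.7), 4.5, 7.5))
                h = float(np.clip(rng.normal(0.35, 0.08), 0.18, 0.8))
                sd = float(np.clip(rng.normal(1.0, 0.2), 0.6, 2.0))
                peaks_base.append((cf, h, sd))
                peaks_fu.append((cf, h, sd))
            if rng.uniform() < config.p_alpha_peak:
                cf = rng.normal(10.0, 1.0)
                if is_pd:
                    cf += config.alpha_freq_group_effect
                cf = float(np.clip(cf, 7.0, 12.0))
                h = float(np.clip(rng.normal(0.5, 0.12), 0.2, 1.0))
                sd = float(np.clip(rng.normal(1.2, 0.2), 0.6, 2.5))
                peaks_base.append((cf, h, sd))
                peaks_fu.append((cf, h, sd))
            if rng.uniform() < config.p_beta_peak:
                cf = float(np.clip(rng.normal(20.0, 2.5), 14.0, 28.0))
                h = rng.normal(0.35, 0.1)
                if is_pd and in_group_set:
                    h += config.beta_power_group_effect
                h = float(np.clip(h, 0.18, 1.2))
                sd = float(np.clip(rng.normal(2.0, 0.4), 1.0, 4.0))
                peaks_base.append((cf, h, sd))
                peaks_fu.append((cf, h, sd))

            exp_fu = exp_base
            if is_pd and in_time_set:
                exp_fu = exp_base + config.time_effect_exponent_pd * months / 48.0

            truth_rows.append(
                {
                    "subject_id": subj,
                    "group": group,
                    "timepoint": "baseline",
                    "region_label": region,
                    "offset_true": off_base,
                    "exponent_true": exp_base,
                    "peaks_true": peaks_base,
                }
            )
            truth_rows.append(
                {
                    "subject_id": subj,
                    "group": group,
                    "timepoint": "followup",
                    "region_label": region,
                    "offset_true": off_base,
                    "exponent_true": exp_fu,
                    "peaks_true": peaks_fu,
                }
            )
    truth = pd.DataFrame(truth_rows)

    clinical = generate_clinical_table(
        config, truth, followup_months=dict(zip(subjects, followup_months)),
        groups=dict(zip(subjects, groups)), ages=dict(zip(subjects, ages)),
        sexes=dict(zip(subjects, sexes)), rng=rng,
    )

    spectra = None
    timeseries = None
    freqs = None
    if config.mode == "spectra":
        freqs = np.arange(1.0, 47.0 + 1e-9, 1.0 / config.segment_s)
        dof = _welch_noise_dof(config.duration_s, config.segment_s)
        rows = []
        for row in truth.itertuples(index=False):
            gt = SpectralGroundTruth(
                region_label=row.region_label,
                offset_true=row.offset_true,
                exponent_true=max(row.exponent_true, 0.0),
                peaks_true=tuple(row.peaks_true),
            )
            psd = 10.0 ** analytic_log_psd(freqs, gt)
            noisy = psd * rng.gamma(shape=dof, scale=1.0 / dof, size=psd.size)
            rows.append(
                [row.subject_id, row.timepoint, row.region_label, *noisy]
            )
        spectra = pd.DataFrame(
            rows, columns=["subject_id", "timepoint", "region_label", *[f"f_{f:.1f}" for f in freqs]]
        )
    else:
        timeseries = {}
        for row in truth.itertuples(index=False):
            gt = SpectralGroundTruth(
                region_label=row.region_label,
                offset_true=row.offset_true,
                exponent_true=max(row.exponent_true, 0.0),
                peaks_true=tuple(row.peaks_true),
            )
            timeseries[(row.subject_id, row.timepoint, row.region_label)] = generate_roi_timeseries(
                gt, config.duration_s, config.fs, seed=rng
            )

    return SyntheticCohort(
        spectra=spectra, timeseries=timeseries, clinical=clinical, truth=truth,
        freqs=freqs, config=config,
    )


def _distribute_items(total: int, items: Sequence[str], rng: np.random.Generator,
                      cap: int = 4) -> dict[str, int]:
    """Randomly spread an integer subscore across its items (each 0..cap)."""
    scores = dict.fromkeys(items, 0)
    remaining = int(total)
    order = list(items)
    while remaining > 0:
        rng.shuffle(order)
        placed = False
        for item in order:
            if remaining == 0:
                break
            if scores[item] < cap:
                scores[item] += 1
                remaining -= 1
                placed = True
        if not placed:  # all items saturated
            break
    return scores


def _neural_summary(truth: pd.DataFrame, subject: str, timepoint: str,
                    feature: str, regions: Sequence[str]) -> float:
    rows = truth[(truth.subject_id == subject) & (truth.timepoint == timepoint)
                 & truth.region_label.isin(list(regions))]
    if rows.empty:  # small-region configs may not cover the planted set
        rows = truth[(truth.subject_id == subject) & (truth.timepoint == timepoint)]
    if feature == "exponent":
        return float(rows["exponent_true"].mean())
    if feature == "offset":
        return float(rows["offset_true"].mean())
    if feature == "beta_power":
        vals = []
        for peaks in rows["peaks_true"]:
            beta = [h for cf, h, sd in peaks if 13.0 <= cf <= 30.0]
            if beta:
                vals.append(max(beta))
        return float(np.mean(vals)) if vals else 0.0
    raise ValueError(f"unknown neural summary feature {feature!r}")


def generate_clinical_table(
    config: CohortConfig,
    truth: pd.DataFrame,
    followup_months: Mapping[str, float],
    groups: Mapping[str, str],
    ages: Mapping[str, float],
    sexes: Mapping[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical records coupled to the neural ground truth.

    Patients' baseline subscores are linear in centered neural summaries; the
    follow-up change contains a planted annual progression, a medication term
    ``alpha_true * relative LEDD change``, and noise, so the medication
    adjustment downstream has a recoverable truth.  Controls score (near) zero
    and take no medication.
    """
    for sub in config.clinical_coupling.values():
        feat = sub.get("feature")
        if feat not in (None, "exponent", "offset", "beta_power"):
            raise ValueError(f"unknown coupling feature {feat!r}")

    summaries: dict[str, dict[str, float]] = {}
    feat_regions = {
        "beta_power": config.group_effect_regions,
        "exponent": config.exponent_time_regions,
        "offset": config.group_effect_regions,
    }
    pd_subjects = [s for s, g in groups.items() if g == "PD"]
    for feat in ("beta_power", "exponent", "offset"):
        vals = {s: _neural_summary(truth, s, "baseline", feat, feat_regions[feat])
                for s in pd_subjects}
        mean = float(np.mean(list(vals.values()))) if vals else 0.0
        summaries[feat] = {s: v - mean for s, v in vals.items()}

    exp_change = {
        s: _neural_summary(truth, s, "followup", "exponent", config.exponent_time_regions)
        - _neural_summary(truth, s, "baseline", "exponent", config.exponent_time_regions)
        for s in pd_subjects
    }

    sched = config.ledd_schedule
    rows = []
    for subj, group in groups.items():
        months = float(followup_months[subj])
        years = months / 12.0
        if group == "HC":
            ledd_b = ledd_f = 0.0
            base_sub = dict.fromkeys(SUBSCORE_ITEMS, 0)
            fu_total_target = max(int(round(rng.normal(1.1, 2.8))), 0)
            fu_sub = dict.fromkeys(SUBSCORE_ITEMS, 0)
            # sprinkle mild follow-up signs across bradykinesia/axial items
            fu_sub["bradykinesia"] = min(fu_total_target, 4)
            fu_sub["axial"] = max(fu_total_target - fu_sub["bradykinesia"], 0)
        else:
            ledd_b = max(rng.normal(sched["baseline_mean"], sched["baseline_sd"]), 50.0)
            rel = max(rng.normal(sched["rel_change_mean"], sched["rel_change_sd"]), -0.5)
            ledd_f = max(ledd_b * (1.0 + rel), 0.0)
            delta_ledd_rel = (ledd_f - ledd_b) / ledd_b

            base_sub = {}
            for name, spec_ in config.clinical_coupling.items():
                val = spec_["const"]
                if spec_["feature"] is not None:
                    val += spec_["coef"] * summaries[spec_["feature"]][subj]
                val += rng.normal(0, spec_["noise_sd"])
                base_sub[name] = int(np.clip(round(val), 0, 4 * len(SUBSCORE_ITEMS[name])))

            fu_sub = {}
            for name, spec_ in config.clinical_coupling.items():
                delta = config.ledd_alpha_true * delta_ledd_rel / 4.0  # spread over subscores
                if name == "bradykinesia":
                    delta += config.bradykinesia_progression_rate * years
                if name == "rigidity":
                    delta += config.rigidity_progression_coef * exp_change[subj]
                delta += rng.normal(0, spec_["noise_sd"] / 2.0)
                fu_sub[name] = int(
                    np.clip(round(base_sub[name] + delta), 0, 4 * len(SUBSCORE_ITEMS[name]))
                )

        for timepoint, sub, ledd, m in (
            ("baseline", base_sub, ledd_b, 0.0),
            ("followup", fu_sub, ledd_f, months),
        ):
            items: dict[str, int] = {}
            for name, item_ids in SUBSCORE_ITEMS.items():
                items.update(_distribute_items(sub[name], item_ids, rng))
            row = {
                "subject_id": subj,
                "group": group,
                "timepoint": timepoint,
                "months_since_baseline": m,
                "age": float(ages[subj]),
                "sex": sexes[subj],
                "moca": int(np.clip(round(rng.normal(26.7, 2.1)), 0, 30)),
                "ledd": ledd,
            }
            row.update({f"item_{iid}": items[iid] for iid in ALL_ITEMS})
            for name in SUBSCORE_ITEMS:
                row[name] = sum(items[iid] for iid in SUBSCORE_ITEMS[name])
            row["updrs3_total"] = sum(items.values())
            rows.append(row)

    return pd.DataFrame(rows)
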