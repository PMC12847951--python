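"""End-to-end orchestration: synth -> parameterize -> progress -> xsec -> longit -> predict.

All stage outputs are flat CSV/JSON so any stage can be rerun independently;
a manifest records the package version, seeds, row counts and SHA-256
checksums of every artifact for reproducibility audits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import DK68
from .cross_sectional import regionwise_baseline_stats
from .longitudinal import regionwise_longitudinal_stats
from .prediction import (
    PLSProgression,
    RegionwisePC1Reducer,
    evaluate,
    loo_select_components,
    permutation_test,
)
from .progression import progression_table
from .spectral import FitSettings, parameterize_cohort
from .synth import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]

STAGES = ("synth", "parameterize", "progress", "xsec", "longit", "predict")


@dataclass
class PipelineConfig:
    """Single configuration object for a full pipeline run."""

    outdir: str = "megprog_run"
    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_validation_pd: int = 18
    clinical_path: str | None = None
    spectra_path: str | None = None
    fit_settings: FitSettings = field(default_factory=FitSettings)
    features: tuple[str, ...] = ("exponent", "offset", "peak_beta_power", "peak_alpha_freq")
    min_per_group: int = 10
    max_components: int = 5
    n_perm: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        fit = FitSettings(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in raw.pop("fit_settings", {}).items()})
        if "features" in raw:
            raw["features"] = tuple(raw["features"])
        return cls(cohort=cohort, fit_settings=fit, **raw)


def validate_inputs(clinical: pd.DataFrame | None = None,
                    spectra: pd.DataFrame | None = None) -> list[str]:
    """Schema and coding checks; returns a list of violation messages."""
    violations: list[str] = []
    if clinical is not None:
        required = {"subject_id", "group", "timepoint", "months_since_baseline",
                    "ledd", "updrs3_total"}
        missing = required - set(clinical.columns)
        if missing:
            violations.append(f"clinical table missing columns: {sorted(missing)}")
        else:
            bad_tp = set(clinical["timepoint"]) - {"baseline", "followup"}
            if bad_tp:
                violations.append(f"unknown timepoint coding: {sorted(bad_tp)}")
            if (clinical["months_since_baseline"] < 0).any():
                violations.append("negative months_since_baseline present")
            if (clinical["ledd"] < 0).any():
                violations.append("negative LEDD present")
            bad_grp = set(clinical["group"]) - {"HC", "PD"}
            if bad_grp:
                violations.append(f"unknown group labels: {sorted(bad_grp)}")
    if spectra is not None:
        required = {"subject_id", "timepoint", "region_label"}
        missing = required - set(spectra.columns)
        if missing:
            violations.append(f"spectra table missing columns: {sorted(missing)}")
        else:
            unknown = set(spectra["region_label"]) - set(DK68)
            if unknown:
                violations.append(f"unknown region labels: {sorted(unknown)[:5]}")
            if not any(c.startswith("f_") for c in spectra.columns):
                violations.append("spectra table has no f_<freq> power columns")
    return violations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["artifacts"][path.name] = {"rows": int(len(df)), "sha256": _sha256(path)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": [], "artifacts": {}}

    def fail(stage: str, exc: Exception) -> RuntimeError:
        err = RuntimeError(f"stage {stage!r} failed: {exc}")
        err.__cause__ = exc
        return err

    # -- synth / load -----------------------------------------------------
    try:
        if config.synthetic:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            cohort = generate_cohort(cohort_cfg)
            clinical, spectra = cohort.clinical, cohort.spectra
            val_cfg = dataclasses.replace(
                cohort_cfg, n_hc=1, n_pd=config.n_validation_pd,
                seed=config.seed + 10_000,
            )
            val_cohort = generate_cohort(val_cfg)
            _write(clinical, outdir / "clinical.csv", manifest)
            _write(spectra, outdir / "spectra.csv", manifest)
            manifest["stages"].append("synth")
        else:
            if not config.clinical_path or not config.spectra_path:
                raise ValueError("clinical_path and spectra_path are required "
                                 "when synthetic=False")
            clinical = pd.read_csv(config.clinical_path)
            spectra = pd.read_csv(config.spectra_path)
            val_cohort = None
            manifest["stages"].append("load")
        violations = validate_inputs(clinical, spectra)
        if violations:
            raise ValueError("; ".join(violations))
    except Exception as exc:  # noqa: BLE001 - aborts with stage name
        raise fail("synth", exc)

    # -- parameterize ------------------------------------------------------
    try:
        features = parameterize_cohort(spectra, config.fit_settings)
        _write(features, outdir / "features.csv", manifest)
        manifest["stages"].append("parameterize")
    except Exception as exc:
        raise fail("parameterize", exc)

    # -- progression rates -------------------------------------------------
    try:
        rates = progression_table(clinical)
        _write(rates, outdir / "rates.csv", manifest)
        manifest["stages"].append("progress")
    except Exception as exc:
        raise fail("progress", exc)

    # -- cross-sectional ---------------------------------------------------
    try:
        xsec_frames = []
        for feat in config.features:
            res = regionwise_baseline_stats(
                features, clinical, feat, model="group",
                min_per_group=config.min_per_group,
            )
            res["feature"] = feat
            res["model"] = "group"
            xsec_frames.append(res)
        sym = regionwise_baseline_stats(
            features, clinical, "peak_beta_power", model="symptom",
            symptom="bradykinesia", min_per_group=config.min_per_group,
        )
        sym["feature"] = "peak_beta_power"
        sym["model"] = "symptom_bradykinesia"
        xsec_frames.append(sym)
        _write(pd.concat(xsec_frames, ignore_index=True),
               outdir / "baseline_stats.csv", manifest)
        manifest["stages"].append("xsec")
    except Exception as exc:
        raise fail("xsec", exc)

    # -- longitudinal ------------------------------------------------------
    try:
        longit_frames = []
        for feat in config.features:
            res = regionwise_longitudinal_stats(
                features, clinical, feat, min_per_group=config.min_per_group,
            )
            res["feature"] = feat
            longit_frames.append(res)
        _write(pd.concat(longit_frames, ignore_index=True),
               outdir / "longitudinal_stats.csv", manifest)
        manifest["stages"].append("longit")
    except Exception as exc:
        raise fail("longit", exc)

    # -- prediction --------------------------------------------------------
    try:
        pred_report = _predict_stage(features, rates, val_cohort, config, outdir,
                                     manifest)
        manifest["prediction"] = pred_report
        manifest["stages"].append("predict")
    except Exception as exc:
        raise fail("predict", exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _predict_stage(features: pd.DataFrame, rates: pd.DataFrame,
                   val_cohort, config: PipelineConfig, outdir: Path,
                   manifest: dict) -> dict:
    base = features[(features.timepoint == "baseline")
                    & features.subject_id.str.startswith("pd")]
    reducer = RegionwisePC1Reducer().fit(base)
    X = reducer.transform(base)
    total_rates = rates[rates.score_name == "updrs3_total"].set_index("subject_id")
    common = [s for s in X.index if s in total_rates.index
              and np.isfinite(total_rates.loc[s, "rate"])]
    X = X.loc[common]
    y = total_rates.loc[common, "rate"].to_numpy()
    X_filled = X.fillna(0.0)  # PC1 of a region missing for a subject -> mean score

    k = loo_select_components(X_filled.to_numpy(), y, config.max_components)
    model = PLSProgression(n_components=k).fit(X_filled.to_numpy(), y)
    r2_train, rmse_train = evaluate(y, model.predict(X_filled.to_numpy()))

    pred_df = pd.DataFrame({"subject_id": common, "rate": y,
                            "predicted_rate": model.predict(X_filled.to_numpy())})
    _write(pred_df, outdir / "predictions.csv", manifest)
    summary = reducer.summary_frame_()
    vip = pd.DataFrame({"region_label": X.columns, "vip": model.vip_})
    _write(summary.merge(vip, on="region_label", how="left"),
           outdir / "pc1_summary.csv", manifest)

    report = {"n_components": int(k), "r2_train": float(r2_train),
              "rmse_train": float(rmse_train),
              "mean_pc1_explained_variance":
                  float(summary["explained_variance_fraction"].mean())}

    if val_cohort is not None:
        val_features = parameterize_cohort(val_cohort.spectra, config.fit_settings)
        val_rates = progression_table(val_cohort.clinical)
        vbase = val_features[(val_features.timepoint == "baseline")
                             & val_features.subject_id.str.startswith("pd")]
        Xv = reducer.transform(vbase)
        vtot = val_rates[val_rates.score_name == "updrs3_total"].set_index("subject_id")
        vcommon = [s for s in Xv.index if s in vtot.index
                   and np.isfinite(vtot.loc[s, "rate"])]
        Xv = Xv.loc[vcommon].fillna(0.0)
        yv = vtot.loc[vcommon, "rate"].to_numpy()
        vrep = permutation_test(
            X_filled.to_numpy(), y, Xv.to_numpy(), yv, n_components=k,
            n_perm=config.n_perm, seed=config.seed,
        )
        report.update({
            "r2_validation": vrep.r2_validation,
            "rmse_validation": vrep.rmse_validation,
            "permutation_p": vrep.permutation_p,
            "n_permutations": vrep.n_permutations,
        })
        (outdir / "validation_report.json").write_text(
            json.dumps(dataclasses.asdict(vrep), indent=2)
        )
    model_json = {
        "n_components": int(k),
        "regions": list(X.columns),
        "coef": model.coef_.tolist(),
        "vip": model.vip_.tolist(),
        "x_mean": model.x_mean_.tolist(),
        "x_std": model.x_std_.tolist(),
        "y_mean": model.y_mean_,
    }
    (outdir / "model.json").write_text(json.dumps(model_json, indent=2))
    return report
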