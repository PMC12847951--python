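"""Longitudinal mixed-effects models per region and progression ANCOVA.

The group x time model per region is a random-intercept linear mixed model

    value_ij = b0 + b1 (group x time)_ij + b2 group_i + b3 time_ij
               + b4 age_i + b5 sex_i + gamma_i + eps_ij

with time coded in months since baseline (0 at baseline) and REML estimation.
Degrees of freedom for the fixed-effect t tests use the between-within
(containment) rule: terms that vary within subject are tested on
``n_obs - n_subjects - n_within_terms`` df, purely between-subject terms on
``n_subjects - n_between_terms`` df; in balanced two-visit designs this
coincides with the exact df.  When the residual variance degenerates (e.g.
noise-free fixtures) the fixed effects are estimated by OLS, which in balanced
designs coincides with the GLS estimate for any random-intercept variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cross_sectional import RegionStatResult, fdr_adjust

__all__ = [
    "LongitudinalFitResult",
    "ContrastResult",
    "fit_lmm_interaction",
    "posthoc_within_group_change",
    "ancova_progression",
    "symptom_beta_interaction_model",
    "slope_contrast_by_progressor",
    "regionwise_longitudinal_stats",
]


@dataclass
class LongitudinalFitResult:
    region_label: str
    model_name: str
    terms: pd.DataFrame  # term, estimate, se, t_value, df, p_value
    random_intercept_var: float
    residual_var: float
    converged: bool
    params: pd.Series = field(repr=False)
    cov: pd.DataFrame = field(repr=False)
    df_map: dict = field(repr=False)
    data: pd.DataFrame = field(repr=False)

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms.term == name]
        if row.empty:
            raise KeyError(f"no term {name!r} in model {self.model_name}")
        return row.iloc[0]


@dataclass(frozen=True)
class ContrastResult:
    label: str
    contrast: str
    estimate: float
    se: float
    df: float
    p_value: float


def _containment_df(data: pd.DataFrame, exog: pd.DataFrame,
                    groups: pd.Series) -> dict[str, float]:
    """Between-within df per design column (within-subject if it varies within
    any subject)."""
    n_obs = len(exog)
    n_subj = groups.nunique()
    within_cols = []
    for col in exog.columns:
        spread = exog.groupby(groups.values, observed=True)[col].transform(
            lambda x: x.max() - x.min()
        )
        if np.any(spread.to_numpy() > 1e-10):
            within_cols.append(col)
    n_w = len(within_cols)
    n_b = exog.shape[1] - n_w
    df_w = max(n_obs - n_subj - n_w, 1)
    df_b = max(n_subj - n_b, 1)
    return {col: float(df_w if col in within_cols else df_b) for col in exog.columns}


def _fit_random_intercept(formula: str, data: pd.DataFrame,
                          group_col: str = "subject_id"):
    """REML random-intercept fit with OLS fallback for degenerate residuals."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data, groups=data[group_col])
            res = model.fit(reml=True)
            fe = res.fe_params
            cov = res.cov_params().loc[fe.index, fe.index]
            if res.converged and np.all(np.isfinite(fe)) \
                    and np.all(np.isfinite(np.diag(cov))):
                exog = pd.DataFrame(model.exog, columns=model.exog_names,
                                    index=data.index)
                return fe, cov, float(res.cov_re.iloc[0, 0]), float(res.scale), \
                    bool(res.converged), exog
        except (np.linalg.LinAlgError, ValueError):
            pass
        # degenerate path: fixed effects by OLS (coincides with GLS when the
        # residual variance vanishes or the design is balanced)
        model = smf.ols(formula, data)
        res = model.fit()
        exog = pd.DataFrame(model.exog, columns=model.exog_names, index=data.index)
        return res.params, res.cov_params(), 0.0, float(res.scale), True, exog


def _terms_table(params: pd.Series, cov: pd.DataFrame,
                 df_map: dict[str, float]) -> pd.DataFrame:
    rows = []
    for name in params.index:
        est = float(params[name])
        se = float(np.sqrt(max(cov.loc[name, name], 0.0)))
        df = df_map[name]
        t = est / se if se > 0 else np.inf * np.sign(est) if est != 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        rows.append({"term": name, "estimate": est, "se": se, "t_value": t,
                     "df": df, "p_value": p})
    return pd.DataFrame(rows)


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    d = data.copy()
    if "group_num" not in d:
        d["group_num"] = d["group"].map({"HC": 0.0, "PD": 1.0})
    if "sex_num" not in d and "sex" in d:
        s = d["sex"]
        d["sex_num"] = s.map({"F": 1.0, "M": 0.0}) if s.dtype.kind in "OUS" else s
    if "time" not in d:
        d["time"] = d["months_since_baseline"].astype(float)
    return d


def fit_lmm_interaction(data: pd.DataFrame, value_col: str = "value",
                        region_label: str = "") -> LongitudinalFitResult:
    """Group x time random-intercept model for one region.

    *data* needs one row per subject x visit with columns ``subject_id``,
    ``group`` (HC/PD), ``months_since_baseline``, ``age``, ``sex`` and the
    feature in *value_col*.  The interaction coefficient is in feature units
    per month of extra change in the patient group.
    """
    d = _prepare(data).dropna(subset=[value_col, "age", "sex_num"])
    visits = d.groupby("subject_id")["time"].nunique()
    if not (visits >= 2).any():
        raise ValueError("no subject has more than one visit; cannot fit the model")
    formula = f"{value_col} ~ group_num * time + age + sex_num"
    params, cov, re_var, resid_var, converged, exog = _fit_random_intercept(formula, d)
    df_map = _containment_df(d, exog, d["subject_id"])
    terms = _terms_table(params, cov, df_map)
    return LongitudinalFitResult(
        region_label=region_label, model_name="group_x_time",
        terms=terms, random_intercept_var=re_var, residual_var=resid_var,
        converged=converged, params=params, cov=cov, df_map=df_map, data=d,
    )


def posthoc_within_group_change(fit: LongitudinalFitResult,
                                followup_months: float = 48.0) -> list[ContrastResult]:
    """Within-group follow-up minus baseline contrasts from marginal means.

    Marginal means are evaluated at the covariate means and at time 0 versus
    ``followup_months`` (48 months by default, regardless of per-subject
    jitter); the contrast for controls is ``b_time * t`` and for patients
    ``(b_time + b_interaction) * t``.
    """
    if not fit.converged:
        raise ValueError("cannot compute contrasts from a non-converged fit")
    names = list(fit.params.index)
    out = []
    for label, grp in (("HC", 0.0), ("PD", 1.0)):
        c = np.zeros(len(names))
        c[names.index("time")] = followup_months
        inter = "group_num:time"
        if inter in names:
            c[names.index(inter)] = followup_months * grp
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(max(c @ fit.cov.to_numpy() @ c, 0.0)))
        df = fit.df_map.get("time", 1.0)
        t = est / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df) if se > 0 else 1.0
        out.append(ContrastResult(label=label, contrast="followup-baseline",
                                  estimate=est, se=se, df=df, p_value=p))
    return out


def ancova_progression(
    rate: pd.Series | np.ndarray,
    change_in_feature: pd.Series | np.ndarray,
    baseline_updrs: pd.Series | np.ndarray,
    baseline_feature: pd.Series | np.ndarray,
    region_label: str = "",
    delta_ledd_rel: pd.Series | np.ndarray | None = None,
    months: pd.Series | np.ndarray | None = None,
) -> RegionStatResult:
    """ANCOVA of the adjusted annual rate on the change in a spectral feature.

    The printed model regresses the rate on the feature change, baseline motor
    score and baseline feature; medication change and follow-up time already
    enter through the rate's construction.  Passing ``delta_ledd_rel`` and/or
    ``months`` adds them as explicit covariates (prose variant).
    """
    df = pd.DataFrame({
        "rate": np.asarray(rate, dtype=float),
        "change": np.asarray(change_in_feature, dtype=float),
        "baseline_updrs": np.asarray(baseline_updrs, dtype=float),
        "baseline_feature": np.asarray(baseline_feature, dtype=float),
    })
    cols = ["change", "baseline_updrs", "baseline_feature"]
    if delta_ledd_rel is not None:
        df["delta_ledd_rel"] = np.asarray(delta_ledd_rel, dtype=float)
        cols.append("delta_ledd_rel")
    if months is not None:
        df["months"] = np.asarray(months, dtype=float)
        cols.append("months")
    df = df.dropna()
    X = sm.add_constant(df[cols], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient ANCOVA design for region {region_label!r}")
    res = sm.OLS(df["rate"].to_numpy(), X).fit()
    return RegionStatResult(
        region_label=region_label, term="change",
        estimate=float(res.params["change"]), t_value=float(res.tvalues["change"]),
        df=float(res.df_resid), p_value=float(res.pvalues["change"]),
        n_used=int(res.nobs),
    )


def symptom_beta_interaction_model(data: pd.DataFrame,
                                   region_label: str = "") -> LongitudinalFitResult:
    """Bradykinesia ~ peak beta power x time + LEDD, random subject intercept.

    *data*: patient rows for one region at both visits with columns
    ``subject_id``, ``months_since_baseline``, ``beta_power``, ``bradykinesia``
    and ``ledd``.  The ``beta_power:time`` coefficient measures how the
    beta-bradykinesia slope changes per month.
    """
    d = _prepare(data).dropna(subset=["beta_power", "bradykinesia", "ledd"])
    visits = d.groupby("subject_id")["time"].nunique()
    if not (visits >= 2).any():
        raise ValueError("no subject has more than one visit; cannot fit the model")
    formula = "bradykinesia ~ beta_power * time + ledd"
    params, cov, re_var, resid_var, converged, exog = _fit_random_intercept(formula, d)
    df_map = _containment_df(d, exog, d["subject_id"])
    terms = _terms_table(params, cov, df_map)
    return LongitudinalFitResult(
        region_label=region_label, model_name="beta_x_time_bradykinesia",
        terms=terms, random_intercept_var=re_var, residual_var=resid_var,
        converged=converged, params=params, cov=cov, df_map=df_map, data=d,
    )


def slope_contrast_by_progressor(
    data: pd.DataFrame,
    progressor: pd.Series | dict,
    region_label: str = "",
    followup_months: float = 48.0,
) -> tuple[ContrastResult, pd.DataFrame]:
    """Compare beta-bradykinesia slope trajectories between progressors and
    stable patients.

    Fits bradykinesia ~ beta_power x time x subgroup + LEDD with a random
    subject intercept and returns the three-way interaction (positive values:
    the slope weakens faster in progressors) plus per-subgroup slopes at
    baseline and follow-up.
    """
    d = _prepare(data)
    prog = pd.Series(progressor)
    d["subgroup"] = d["subject_id"].map(prog).astype(float)
    if d["subgroup"].isna().any():
        raise ValueError("progressor label missing for some subjects")
    for val, name in ((0.0, "stable"), (1.0, "progressor")):
        if not (d["subgroup"] == val).any():
            raise ValueError(f"subgroup {name!r} is empty")
    d = d.dropna(subset=["beta_power", "bradykinesia", "ledd"])
    formula = "bradykinesia ~ beta_power * time * subgroup + ledd"
    params, cov, re_var, resid_var, converged, exog = _fit_random_intercept(formula, d)
    df_map = _containment_df(d, exog, d["subject_id"])
    terms = _terms_table(params, cov, df_map)
    three_way = terms[terms.term == "beta_power:time:subgroup"].iloc[0]
    contrast = ContrastResult(
        label="progressor-vs-stable", contrast="beta_slope_change",
        estimate=float(three_way.estimate), se=float(three_way.se),
        df=float(three_way.df), p_value=float(three_way.p_value),
    )
    slopes = []
    get = lambda n: float(params[n]) if n in params.index else 0.0
    for sub, subname in ((0.0, "stable"), (1.0, "progressor")):
        for t, tname in ((0.0, "baseline"), (followup_months, "followup")):
            slope = (get("beta_power") + get("beta_power:time") * t
                     + get("beta_power:subgroup") * sub
                     + get("beta_power:time:subgroup") * t * sub)
            slopes.append({"subgroup": subname, "timepoint": tname, "slope": slope})
    return contrast, pd.DataFrame(slopes)


def regionwise_longitudinal_stats(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    feature: str,
    min_per_group: int = 10,
) -> pd.DataFrame:
    """Group x time model per region with FDR over the interaction p-values."""
    merged = features.merge(
        clinical[["subject_id", "timepoint", "group", "age", "sex",
                  "months_since_baseline"]],
        on=["subject_id", "timepoint"], how="left",
    ).rename(columns={feature: "value"})
    from .cross_sectional import roi_inclusion_filter

    regions = roi_inclusion_filter(merged, "value", min_per_group=min_per_group)
    rows = []
    for region in regions:
        sub = merged[merged.region_label == region]
        try:
            fit = fit_lmm_interaction(sub, value_col="value", region_label=region)
        except ValueError:
            continue
        inter = fit.term("group_num:time")
        rows.append({
            "region_label": region, "term": "group_x_time",
            "estimate": inter.estimate, "se": inter.se, "t_value": inter.t_value,
            "df": inter.df, "p_value": inter.p_value,
            "random_intercept_var": fit.random_intercept_var,
            "residual_var": fit.residual_var,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_fdr"] = fdr_adjust(out["p_value"].to_numpy())
    return out
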