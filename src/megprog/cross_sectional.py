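"""Region-wise baseline statistics: group models, symptom models, FDR, demographics.

Baseline group differences per region are ordinary least squares fits of the
spectral feature on group with age and sex as covariates; brain-behavior
associations within the patient group regress the motor score on the feature
with LEDD as covariate.  Regions are included only if every group contributes
at least ``min_per_group`` non-missing observations.  Multiple comparisons are
controlled with Benjamini-Hochberg FDR across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegionStatResult",
    "roi_inclusion_filter",
    "baseline_group_model",
    "baseline_symptom_model",
    "fdr_adjust",
    "pooled_t_from_summary",
    "yates_chi2_2x2",
    "demographics_table",
    "regionwise_baseline_stats",
]

FEATURE_NAMES = (
    "offset", "exponent", "peak_alpha_freq", "peak_alpha_power",
    "peak_beta_freq", "peak_beta_power",
)


@dataclass(frozen=True)
class RegionStatResult:
    region_label: str
    term: str
    estimate: float
    t_value: float
    df: float
    p_value: float
    n_used: int
    p_fdr: float | None = None


def roi_inclusion_filter(
    table: pd.DataFrame,
    feature: str,
    min_per_group: int = 10,
) -> list[str]:
    """Regions where every group has >= *min_per_group* non-missing values.

    The exclusion rule is strict: a region with exactly ``min_per_group``
    observations per group is kept (only ``< min_per_group`` excludes).
    """
    if table.empty:
        raise ValueError("empty feature table")
    counts = (
        table.dropna(subset=[feature])
        .groupby(["region_label", "group"], observed=True)[feature]
        .size()
        .unstack(fill_value=0)
    )
    groups = table["group"].unique()
    for g in groups:
        if g not in counts.columns:
            counts[g] = 0
    keep = counts[(counts[list(groups)] >= min_per_group).all(axis=1)].index
    return sorted(keep)


def _ols_term(y: np.ndarray, X: pd.DataFrame, term: str,
              region_label: str) -> RegionStatResult:
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError(f"rank-deficient design for region {region_label!r}")
    res = sm.OLS(y, X).fit()
    return RegionStatResult(
        region_label=region_label, term=term,
        estimate=float(res.params[term]), t_value=float(res.tvalues[term]),
        df=float(res.df_resid), p_value=float(res.pvalues[term]),
        n_used=int(res.nobs),
    )


def baseline_group_model(
    feature_values: pd.Series | np.ndarray,
    group: pd.Series | np.ndarray,
    age: pd.Series | np.ndarray,
    sex: pd.Series | np.ndarray,
    region_label: str = "",
) -> RegionStatResult:
    """Feature ~ group + age + sex; returns the group term.

    ``group`` may be labels ("HC"/"PD", patients coded 1) or numeric.
    """
    garr = np.asarray(group)
    if garr.dtype.kind in "OUS":
        g = pd.Series(list(group)).map({"HC": 0.0, "PD": 1.0})
        if g.isna().any():
            raise ValueError("group labels must be 'HC'/'PD' or numeric")
    else:
        g = pd.Series(garr.astype(float))
    sarr = np.asarray(sex)
    if sarr.dtype.kind in "OUS":
        s = pd.Series(list(sex)).map({"F": 1.0, "M": 0.0})
    else:
        s = pd.Series(sarr.astype(float))
    df = pd.DataFrame({
        "y": np.asarray(feature_values, dtype=float),
        "group": g.to_numpy(dtype=float),
        "age": np.asarray(age, dtype=float),
        "sex": s.to_numpy(dtype=float),
    }).dropna()
    return _ols_term(df["y"].to_numpy(), df[["group", "age", "sex"]], "group", region_label)


def baseline_symptom_model(
    symptom: pd.Series | np.ndarray,
    feature_values: pd.Series | np.ndarray,
    ledd: pd.Series | np.ndarray,
    region_label: str = "",
) -> RegionStatResult:
    """Symptom ~ feature + LEDD within the patient group; returns the feature term."""
    df = pd.DataFrame({
        "y": np.asarray(symptom, dtype=float),
        "feature": np.asarray(feature_values, dtype=float),
        "ledd": np.asarray(ledd, dtype=float),
    }).dropna()
    return _ols_term(df["y"].to_numpy(), df[["feature", "ledd"]], "feature", region_label)


def fdr_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order independent)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pooled_t_from_summary(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic from summary statistics.

    Returns ``(t, df)`` with ``df = n1 + n2 - 2``.
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def yates_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Continuity-corrected Pearson chi-square for a 2x2 table [[a, b], [c, d]]."""
    chi2, _, _, _ = stats.chi2_contingency(np.array([[a, b], [c, d]]), correction=True)
    return float(chi2)


def demographics_table(hc: pd.DataFrame, pd_group: pd.DataFrame,
                       continuous: tuple[str, ...] = ("age",),
                       sex_col: str = "sex") -> pd.DataFrame:
    """Cohort-characteristics tests: pooled t per continuous variable and a
    continuity-corrected sex chi-square."""
    if hc.empty or pd_group.empty:
        raise ValueError("both groups must be non-empty")
    rows = []
    for var in continuous:
        x1 = hc[var].dropna().to_numpy(dtype=float)
        x2 = pd_group[var].dropna().to_numpy(dtype=float)
        t, df = pooled_t_from_summary(x1.mean(), x1.std(ddof=1), x1.size,
                                      x2.mean(), x2.std(ddof=1), x2.size)
        p = 2 * stats.t.sf(abs(t), df)
        rows.append({"variable": var, "statistic": t, "df": df, "p_value": p,
                     "test": "pooled_t"})
    f1 = int((hc[sex_col] == "F").sum())
    f2 = int((pd_group[sex_col] == "F").sum())
    chi2 = yates_chi2_2x2(f1, len(hc) - f1, f2, len(pd_group) - f2)
    rows.append({"variable": sex_col, "statistic": chi2, "df": 1,
                 "p_value": float(stats.chi2.sf(chi2, 1)), "test": "chi2_yates"})
    return pd.DataFrame(rows)


def regionwise_baseline_stats(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    feature: str,
    model: str = "group",
    symptom: str = "bradykinesia",
    min_per_group: int = 10,
) -> pd.DataFrame:
    """Run the baseline model over all included regions with FDR correction.

    ``model="group"`` compares groups controlling for age/sex on all subjects;
    ``model="symptom"`` regresses the symptom on the feature plus LEDD within
    the patient group.  FDR is applied across regions (one family per
    feature x model, the default family).
    """
    base = features[features.timepoint == "baseline"].merge(
        clinical[clinical.timepoint == "baseline"][
            ["subject_id", "group", "age", "sex", "ledd", symptom]
        ],
        on="subject_id", how="left",
    )
    if model == "symptom":
        base = base[base.group == "PD"]
        # inclusion still requires enough patients with data
        counts_frame = base.assign(group="PD")
    else:
        counts_frame = base
    regions = roi_inclusion_filter(counts_frame, feature, min_per_group=min_per_group)

    results = []
    for region in regions:
        sub = base[base.region_label == region]
        try:
            if model == "group":
                res = baseline_group_model(sub[feature], sub["group"], sub["age"],
                                           sub["sex"], region_label=region)
            elif model == "symptom":
                res = baseline_symptom_model(sub[symptom], sub[feature], sub["ledd"],
                                             region_label=region)
            else:
                raise ValueError(f"unknown model {model!r}")
        except ValueError:
            continue
        results.append(res)
    if not results:
        return pd.DataFrame(columns=["region_label", "term", "estimate", "t_value",
                                     "df", "p_value", "p_fdr", "n_used"])
    out = pd.DataFrame([r.__dict__ for r in results])
    out["p_fdr"] = fdr_adjust(out["p_value"].to_numpy())
    return out[["region_label", "term", "estimate", "t_value", "df", "p_value",
                "p_fdr", "n_used"]]
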