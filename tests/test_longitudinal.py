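"""Mixed-effects group x time models, contrasts, progression ANCOVA."""

import numpy as np
import pandas as pd
import pytest

from megprog.longitudinal import (
    ancova_progression,
    fit_lmm_interaction,
    posthoc_within_group_change,
    slope_contrast_by_progressor,
    symptom_beta_interaction_model,
)


def _balanced_fixture(pd_change=0.1, hc_change=0.0, months=48.0, n_per_group=6,
                      noise_sd=0.0, subj_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_group):
        g = "HC" if i < n_per_group else "PD"
        b = rng.normal(0, subj_sd)
        for tp, m in (("baseline", 0.0), ("followup", months)):
            change = (pd_change if g == "PD" else hc_change) * (m / months)
            rows.append({
                "subject_id": f"s{i}", "group": g, "timepoint": tp,
                "months_since_baseline": m, "age": 60.0 + (i % 5),
                "sex": "F" if i % 2 else "M",
                "value": 1.0 + b + change + rng.normal(0, noise_sd),
            })
    return pd.DataFrame(rows)


class TestInteractionModel:
    def test_no_differential_change_gives_zero_interaction(self):
        fit = fit_lmm_interaction(_balanced_fixture(pd_change=0.0))
        assert fit.term("group_num:time").estimate == pytest.approx(0.0, abs=1e-10)

    def test_interaction_equals_difference_in_differences(self):
        fit = fit_lmm_interaction(_balanced_fixture(pd_change=0.1))
        assert fit.term("group_num:time").estimate == pytest.approx(0.1 / 48, abs=1e-10)

    def test_containment_df_matches_balanced_case(self):
        data = _balanced_fixture(noise_sd=0.05, subj_sd=0.1, n_per_group=10, seed=1)
        fit = fit_lmm_interaction(data)
        # 40 obs - 20 subjects - 2 within-subject terms
        assert fit.term("group_num:time").df == 18

    def test_interaction_coverage_on_stochastic_fixtures(self):
        from scipy import stats

        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            data = _balanced_fixture(pd_change=0.002 * 48, noise_sd=0.05,
                                     subj_sd=0.1, n_per_group=28, seed=seed)
            t = fit_lmm_interaction(data).term("group_num:time")
            crit = stats.t.ppf(0.975, t.df)
            hits += abs(t.estimate - 0.002) <= crit * t.se
        assert hits / n_rep >= 0.90

    def test_single_visit_data_rejected(self):
        data = _balanced_fixture()
        data = data[data.timepoint == "baseline"]
        with pytest.raises(ValueError, match="visit"):
            fit_lmm_interaction(data)

    def test_matches_ols_when_no_subject_effect(self):
        """With independent observations the GLS and OLS estimates agree."""
        import statsmodels.formula.api as smf

        data = _balanced_fixture(pd_change=0.1, noise_sd=0.3, subj_sd=0.0,
                                 n_per_group=25, seed=5)
        fit = fit_lmm_interaction(data)
        d = data.copy()
        d["group_num"] = (d.group == "PD").astype(float)
        d["sex_num"] = (d.sex == "F").astype(float)
        d["time"] = d.months_since_baseline
        ols = smf.ols("value ~ group_num * time + age + sex_num", d).fit()
        assert fit.term("group_num:time").estimate == pytest.approx(
            ols.params["group_num:time"], abs=5e-3
        )


class TestPosthocContrasts:
    def test_noise_free_group_changes_recovered(self):
        fit = fit_lmm_interaction(_balanced_fixture(pd_change=0.1))
        contrasts = {c.label: c for c in posthoc_within_group_change(fit)}
        assert contrasts["PD"].estimate == pytest.approx(0.1, abs=1e-9)
        assert contrasts["HC"].estimate == pytest.approx(0.0, abs=1e-9)

    def test_contrast_matches_prediction_oracle(self):
        """Contrast equals the difference of model-predicted cell means."""
        data = _balanced_fixture(pd_change=0.1, noise_sd=0.05, subj_sd=0.1,
                                 n_per_group=15, seed=2)
        fit = fit_lmm_interaction(data)
        contrasts = {c.label: c for c in posthoc_within_group_change(fit)}
        p = fit.params
        for grp, label in ((1.0, "PD"), (0.0, "HC")):
            pred = p["time"] * 48 + p["group_num:time"] * 48 * grp
            assert contrasts[label].estimate == pytest.approx(pred, abs=1e-8)


class TestAncova:
    def test_independent_feature_change_gives_zero(self, rng):
        n = 25
        base_updrs = rng.uniform(5, 35, n)
        rate = 0.1 * base_updrs
        res = ancova_progression(rate, rng.normal(size=n), base_updrs,
                                 rng.normal(size=n))
        assert res.estimate == pytest.approx(0.0, abs=1e-8)

    def test_exact_coefficients_recovered(self, rng):
        n = 25
        change = rng.normal(size=n)
        base_updrs = rng.uniform(5, 35, n)
        rate = 1.5 * change + 0.1 * base_updrs
        res = ancova_progression(rate, change, base_updrs, rng.normal(size=n))
        assert res.estimate == pytest.approx(1.5, abs=1e-8)

    def test_matches_normal_equations(self, rng):
        n = 30
        change = rng.normal(size=n)
        base_updrs = rng.uniform(5, 35, n)
        base_feat = rng.normal(size=n)
        rate = rng.normal(size=n)
        res = ancova_progression(rate, change, base_updrs, base_feat)
        X = np.column_stack([np.ones(n), change, base_updrs, base_feat])
        beta = np.linalg.solve(X.T @ X, X.T @ rate)
        assert res.estimate == pytest.approx(beta[1], abs=1e-8)

    def test_explicit_covariate_variant(self, rng):
        n = 30
        change = rng.normal(size=n)
        res = ancova_progression(
            rng.normal(size=n), change, rng.uniform(5, 35, n), rng.normal(size=n),
            delta_ledd_rel=rng.uniform(0, 1, n), months=rng.normal(48, 5, n),
        )
        assert res.n_used == n


def _beta_fixture(slope_base=-2.0, slope_change_per_month=2 / 48, months=48.0,
                  n=12, seed=1, subgroup=None, subgroup_extra=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sub = subgroup[f"p{i}"] if subgroup else 0.0
        for tp, m in (("baseline", 0.0), ("followup", months)):
            bp = float(rng.normal(0.5, 0.2))
            slope = slope_base + (slope_change_per_month + subgroup_extra * sub) * m
            rows.append({
                "subject_id": f"p{i}", "group": "PD", "timepoint": tp,
                "months_since_baseline": m, "beta_power": bp,
                "bradykinesia": 10.0 + slope * bp, "ledd": 500.0,
            })
    return pd.DataFrame(rows)


class TestBetaBradykinesiaModel:
    def test_independent_outcome_gives_zero_interaction(self):
        data = _beta_fixture(slope_base=0.0, slope_change_per_month=0.0)
        fit = symptom_beta_interaction_model(data)
        assert fit.term("beta_power:time").estimate == pytest.approx(0.0, abs=1e-9)

    def test_weakening_slope_recovered(self):
        # slope -2 at baseline, 0 at 48 months -> +2/48 per month
        fit = symptom_beta_interaction_model(_beta_fixture())
        assert fit.term("beta_power:time").estimate == pytest.approx(2 / 48, abs=1e-8)

    def test_interaction_within_two_se_on_stochastic_fixtures(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            data = _beta_fixture(seed=seed, n=27)
            data["bradykinesia"] += rng.normal(0, 0.5, len(data))
            t = symptom_beta_interaction_model(data).term("beta_power:time")
            hits += abs(t.estimate - 2 / 48) <= 2 * t.se
        assert hits / 30 >= 0.9


class TestProgressorSlopes:
    def test_identical_trajectories_give_zero_three_way(self):
        sub = {f"p{i}": float(i < 6) for i in range(12)}
        data = _beta_fixture(subgroup=sub, subgroup_extra=0.0)
        contrast, _ = slope_contrast_by_progressor(data, sub)
        assert contrast.estimate == pytest.approx(0.0, abs=1e-9)

    def test_greater_weakening_in_progressors_is_positive(self):
        sub = {f"p{i}": float(i < 6) for i in range(12)}
        data = _beta_fixture(subgroup=sub, subgroup_extra=1 / 48)
        contrast, slopes = slope_contrast_by_progressor(data, sub)
        assert contrast.estimate == pytest.approx(1 / 48, abs=1e-8)
        assert contrast.estimate > 0  # weakening accentuated in progressors
        fu = slopes.set_index(["subgroup", "timepoint"]).slope
        assert fu["progressor", "followup"] > fu["stable", "followup"]

    def test_empty_subgroup_rejected(self):
        sub = {f"p{i}": 1.0 for i in range(12)}
        data = _beta_fixture(subgroup=sub)
        with pytest.raises(ValueError, match="empty"):
            slope_contrast_by_progressor(data, sub)
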