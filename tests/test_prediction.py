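"""Region PC1 reduction, PLS, VIP, model selection, permutation inference."""

import numpy as np
import pandas as pd
import pytest

from megprog.prediction import (
    PLSProgression,
    RegionwisePC1Reducer,
    augment_covariates,
    evaluate,
    loo_select_components,
    permutation_p,
    permutation_test,
    regionwise_pc1,
    vip_scores,
)


class TestRegionPC1:
    def test_single_feature_is_standardized_feature(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"exponent": x, "offset": np.nan})
        s = regionwise_pc1(X, "r")
        assert s.features_used == ("exponent",)
        assert s.explained_variance_fraction == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(s.pc1_scores, z)

    def test_perfectly_correlated_features(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"exponent": x, "offset": 3 * x + 1})
        s = regionwise_pc1(X, "r")
        assert s.explained_variance_fraction == pytest.approx(1.0)
        assert s.loadings["exponent"] == pytest.approx(1 / np.sqrt(2))
        assert s.loadings["offset"] == pytest.approx(1 / np.sqrt(2))

    def test_squared_loadings_sum_to_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)),
                         columns=["exponent", "offset", "peak_beta_power",
                                  "peak_alpha_freq"])
        s = regionwise_pc1(X, "r")
        assert sum(s.squared_loadings.values()) == pytest.approx(1.0)

    def test_entirely_missing_feature_dropped(self, rng):
        X = pd.DataFrame({
            "exponent": rng.normal(size=20), "offset": rng.normal(size=20),
            "peak_beta_power": rng.normal(size=20),
            "peak_alpha_freq": np.full(20, np.nan),
        })
        s = regionwise_pc1(X, "r")
        assert s.features_used == ("exponent", "offset", "peak_beta_power")

    def test_partial_missingness_scored_by_renormalized_projection(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"exponent": x, "offset": x + rng.normal(0, 0.1, 20)})
        X_missing = X.copy()
        X_missing.loc[3, "offset"] = np.nan
        s = regionwise_pc1(X_missing, "r")
        assert np.isfinite(s.pc1_scores).all()

    def test_sign_fixed_by_exponent_loading(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"exponent": -x, "offset": x})
        s = regionwise_pc1(X, "r")
        assert s.loadings["exponent"] >= 0

    def test_too_few_complete_subjects_rejected(self):
        X = pd.DataFrame({"exponent": [1.0, np.nan, np.nan],
                          "offset": [np.nan, 2.0, 3.0]})
        with pytest.raises(ValueError):
            regionwise_pc1(X, "r")


class TestPLS:
    def test_single_predictor_perfect_fit(self):
        x = np.linspace(-1, 1, 10).reshape(-1, 1)
        y = 3.0 * x.ravel()
        m = PLSProgression(n_components=1).fit(x, y)
        assert m.r2_train_ == pytest.approx(1.0)
        assert m.rmse_train_ == pytest.approx(0.0, abs=1e-10)

    def test_first_weight_proportional_to_covariance(self, rng):
        X = rng.normal(size=(30, 8))
        y = X[:, 0] * 2 + rng.normal(0, 0.5, 30)
        m = PLSProgression(n_components=2).fit(X, y)
        Xs = (X - m.x_mean_) / m.x_std_
        w = Xs.T @ (y - m.y_mean_)
        w /= np.linalg.norm(w)
        assert np.allclose(w, m.x_weights_[:, 0], atol=1e-8)

    def test_component_scores_orthogonal(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        m = PLSProgression(n_components=3).fit(X, y)
        G = m.x_scores_.T @ m.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_predictions_match_reference_implementation(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(30, 8))
        y = X[:, 0] * 2 + X[:, 1] + rng.normal(0, 0.5, 30)
        mine = PLSProgression(n_components=2).fit(X, y)
        ref = PLSRegression(n_components=2, scale=True).fit(X, y.reshape(-1, 1))
        assert np.allclose(mine.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            PLSProgression(n_components=1).fit(X, np.arange(3.0))

    def test_components_beyond_rank_rejected(self):
        X = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="rank"):
            PLSProgression(n_components=2).fit(X, np.arange(5.0))


class TestVip:
    def test_single_predictor_vip_is_one(self):
        x = np.linspace(-1, 1, 12).reshape(-1, 1)
        m = PLSProgression(n_components=1).fit(x, 2 * x.ravel())
        assert m.vip_[0] == pytest.approx(1.0)

    def test_mean_squared_vip_is_one(self, rng):
        X = rng.normal(size=(30, 7))
        y = rng.normal(size=30)
        m = PLSProgression(n_components=3).fit(X, y)
        assert np.mean(m.vip_**2) == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_three_predictor_example(self):
        class Fake:
            x_weights_ = np.array([[0.8], [0.6], [0.0]])
            y_loadings_ = np.array([1.5])
            x_scores_ = np.ones((6, 1))

        vip = vip_scores(Fake())
        assert np.allclose(vip, np.sqrt(3) * np.array([0.8, 0.6, 0.0]))

    def test_uninformative_predictors_stay_below_one(self):
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 6))
            y = 2 * X[:, 0] + X[:, 1] + rng.normal(0, 0.3, 30)
            m = PLSProgression(n_components=2).fit(X, y)
            hits += np.all(m.vip_[2:] < 1.0)
        assert hits / n_rep >= 0.9


class TestEvaluate:
    def test_perfect_prediction(self):
        r2, rmse = evaluate([1.0, 2, 3], [1.0, 2, 3])
        assert r2 == 1.0 and rmse == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2, 3])
        r2, _ = evaluate(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        r2, rmse = evaluate([1.0, 2, 3], [1.0, 2, 4])
        assert rmse == pytest.approx(np.sqrt(1 / 3))
        assert r2 == pytest.approx(0.5)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            evaluate([2.0, 2.0], [1.0, 3.0])


def _latent_fixture(seed, n=25, p=10, k=1, noise=0.1):
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(n, k))
    load = rng.normal(size=(k, p // 2))
    X = np.concatenate([T @ load + rng.normal(0, 0.05, (n, p // 2)),
                        rng.normal(size=(n, p - p // 2))], axis=1)
    y = T.sum(axis=1) + rng.normal(0, noise, n)
    return X, y


class TestComponentSelection:
    def test_single_latent_direction_selects_one_component(self):
        # outcome noise dominates once the single factor is extracted, so
        # extra components can only fit noise and inflate the LOO error
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            X, y = _latent_fixture(seed, n=40, p=8, k=1, noise=1.0)
            hits += loo_select_components(X, y, max_components=4) == 1
        assert hits / n_rep >= 0.9

    def test_two_informative_directions_select_two(self):
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            T = rng.normal(size=(40, 2))
            X = np.concatenate([np.outer(T[:, 0], rng.normal(size=4)),
                                np.outer(T[:, 1], rng.normal(size=4))], axis=1)
            y = T[:, 0] + T[:, 1] + rng.normal(0, 0.05, 40)
            chosen.append(loo_select_components(X, y, max_components=4))
        assert np.median(chosen) == 2

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            loo_select_components(np.eye(2), np.arange(2.0), 2)


class TestPermutation:
    def test_fraction_rule_reproduces_published_arithmetic(self):
        # observed exceeds 9,310 of 10,000 null values -> p = 0.069
        null = np.concatenate([np.full(9310, -0.5), np.full(690, 0.9)])
        assert permutation_p(null, 0.2) == pytest.approx(0.069)

    def test_observed_above_all_null_gives_zero(self):
        assert permutation_p(np.full(100, -1.0), 0.5) == 0.0

    def test_add_one_estimator_option(self):
        null = np.full(99, -1.0)
        assert permutation_p(null, 0.5, estimator="add_one") == pytest.approx(1 / 100)

    def test_signal_detected_with_small_p(self):
        rng = np.random.default_rng(0)
        load = rng.normal(size=5)

        def draw(n):
            t = rng.normal(size=n)
            X = np.concatenate([np.outer(t, load) + rng.normal(0, 0.05, (n, 5)),
                                rng.normal(size=(n, 5))], axis=1)
            return X, t + rng.normal(0, 0.1, n)

        X, y = draw(30)
        Xv, yv = draw(20)
        rep = permutation_test(X, y, Xv, yv, n_components=1, n_perm=99, seed=0)
        assert rep.r2_validation > 0.2
        assert rep.permutation_p < 0.05

    def test_deterministic_given_seed(self):
        X, y = _latent_fixture(2, n=20)
        Xv, yv = _latent_fixture(3, n=15)
        a = permutation_test(X, y, Xv, yv, n_components=1, n_perm=50, seed=9)
        b = permutation_test(X, y, Xv, yv, n_components=1, n_perm=50, seed=9)
        assert a == b

    def test_planted_signal_recovered_with_detection(self):
        """With a true predictable fraction near 0.4, the median validation
        R2 lands in [0.2, 0.5] and the permutation test detects the signal in
        at least 80% of cohorts."""
        r2s, detections = [], []
        for i in range(20):
            rng = np.random.default_rng(i)
            load = rng.normal(size=6)

            def draw(n):
                t = rng.normal(size=n)
                X = np.concatenate(
                    [np.outer(t, load) + rng.normal(0, 0.3, (n, 6)),
                     rng.normal(size=(n, 6))], axis=1)
                return X, t + rng.normal(0, np.sqrt(1.5), n)

            X, y = draw(50)
            Xv, yv = draw(40)
            rep = permutation_test(X, y, Xv, yv, n_components=1, n_perm=99,
                                   seed=i)
            r2s.append(rep.r2_validation)
            detections.append(rep.permutation_p < 0.05)
        assert 0.2 <= np.median(r2s) <= 0.5
        assert np.mean(detections) >= 0.8

    def test_null_outcome_gives_large_p_and_poor_r2(self):
        r2s, ps = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(25, 8))
            y = rng.normal(size=25)
            Xv = rng.normal(size=(15, 8))
            yv = rng.normal(size=15)
            rep = permutation_test(X, y, Xv, yv, n_components=1, n_perm=49,
                                   seed=seed)
            r2s.append(rep.r2_validation)
            ps.append(rep.permutation_p)
        assert np.median(r2s) <= 0.0
        assert np.median(ps) > 0.2


class TestCovariateAugmentation:
    def test_three_covariates_appended(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 68)))
        Xa, stats = augment_covariates(X, rng.normal(68, 8, 20),
                                       rng.integers(0, 2, 20).astype(float),
                                       rng.uniform(5, 35, 20))
        assert Xa.shape[1] == 71

    def test_training_statistics_reused_for_validation(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)))
        age = rng.normal(68, 8, 20)
        sex = rng.integers(0, 2, 20).astype(float)
        updrs = rng.uniform(5, 35, 20)
        _, stats = augment_covariates(X, age, sex, updrs)
        Xv = pd.DataFrame(rng.normal(size=(10, 5)))
        Xa_v, _ = augment_covariates(Xv, age[:10], sex[:10], updrs[:10],
                                     train_stats=stats)
        expected = (age[:10] - stats["age"][0]) / stats["age"][1]
        assert np.allclose(Xa_v["age"], expected)

    def test_missing_covariate_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 3)))
        age = np.array([60.0, np.nan, 70, 65, 62])
        with pytest.raises(ValueError, match="age"):
            augment_covariates(X, age, np.zeros(5), np.ones(5))

    def test_informative_covariate_improves_validation(self):
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(30, 6)))
            updrs = rng.uniform(5, 35, 30)
            y = 0.1 * updrs + rng.normal(0, 0.3, 30)
            Xv = pd.DataFrame(rng.normal(size=(20, 6)))
            updrs_v = rng.uniform(5, 35, 20)
            yv = 0.1 * updrs_v + rng.normal(0, 0.3, 20)
            plain = PLSProgression(1).fit(X.to_numpy(), y)
            r2_plain, _ = evaluate(yv, plain.predict(Xv.to_numpy()))
            age, sex = rng.normal(68, 8, 30), rng.integers(0, 2, 30).astype(float)
            Xa, stats = augment_covariates(X, age, sex, updrs)
            Xa_v, _ = augment_covariates(Xv, rng.normal(68, 8, 20),
                                         rng.integers(0, 2, 20).astype(float),
                                         updrs_v, train_stats=stats)
            aug = PLSProgression(1).fit(Xa.to_numpy(), y)
            r2_aug, _ = evaluate(yv, aug.predict(Xa_v.to_numpy()))
            wins += r2_aug > r2_plain
        assert wins / n_rep >= 0.8


def test_reducer_round_trip_on_cohort_features(small_features):
    base = small_features[small_features.timepoint == "baseline"].copy()
    reducer = RegionwisePC1Reducer().fit(base)
    X = reducer.transform(base)
    assert set(X.columns) == set(reducer.regions_)
    summary = reducer.summary_frame_()
    assert ((summary.explained_variance_fraction > 0)
            & (summary.explained_variance_fraction <= 1)).all()
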