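"""Prediction of motor progression from baseline spectral features.

Pipeline: per-region PCA over the four spectral features (aperiodic exponent
and offset, peak beta power, peak alpha frequency) compresses each region to
its first principal component; the region PC1 scores feed a PLS1 (NIPALS)
regression of the medication-adjusted annual motor progression rate; model
size is chosen by leave-one-out cross-validation; variable importance in
projection (VIP) summarizes each region's contribution; generalization is
assessed on an external cohort with a label-permutation null.

Missing band features are handled by dynamic feature selection without
imputation: features entirely absent in a region are dropped, and a subject
missing one retained feature is scored by projecting the available features
on the renormalized loading sub-vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PCASummary",
    "RegionPC1",
    "RegionwisePC1Reducer",
    "PLSProgression",
    "ValidationReport",
    "regionwise_pc1",
    "fit_pls",
    "loo_select_components",
    "vip_scores",
    "evaluate",
    "permutation_p",
    "permutation_test",
    "augment_covariates",
]

PREDICTOR_FEATURES = ("exponent", "offset", "peak_beta_power", "peak_alpha_freq")


@dataclass(frozen=True)
class PCASummary:
    region_label: str
    features_used: tuple[str, ...]
    loadings: dict
    squared_loadings: dict
    explained_variance_fraction: float
    pc1_scores: np.ndarray = field(repr=False)


class RegionPC1(BaseEstimator, TransformerMixin):
    """First principal component of one region's standardized features.

    The PC1 sign is fixed so the loading on ``sign_feature`` (or the first
    available feature) is non-negative; subjects missing a retained feature
    are projected on the renormalized loading sub-vector of their available
    features.
    """

    def __init__(self, sign_feature: str = "exponent"):
        self.sign_feature = sign_feature

    def fit(self, X: pd.DataFrame, y: None = None) -> "RegionPC1":
        X = pd.DataFrame(X)
        used = [c for c in X.columns if X[c].notna().any()]
        if not used:
            raise ValueError("no feature has any observed values")
        Xu = X[used]
        self.mean_ = Xu.mean(skipna=True)
        std = Xu.std(skipna=True, ddof=1)
        self.std_ = std.replace(0.0, 1.0).fillna(1.0)
        Z = (Xu - self.mean_) / self.std_
        complete = Z.dropna()
        if len(complete) < 2:
            raise ValueError("fewer than 2 subjects with complete features")
        C = np.cov(complete.to_numpy(), rowvar=False, ddof=1)
        C = np.atleast_2d(C)
        evals, evecs = np.linalg.eigh(C)
        v = evecs[:, -1]
        sign_col = self.sign_feature if self.sign_feature in used else used[0]
        if v[used.index(sign_col)] < 0:
            v = -v
        self.features_used_ = tuple(used)
        self.loadings_ = pd.Series(v, index=used)
        self.explained_variance_fraction_ = float(evals[-1] / evals.sum())
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)
        Z = (X[list(self.features_used_)] - self.mean_) / self.std_
        v = self.loadings_.to_numpy()
        scores = np.full(len(Z), np.nan)
        Zv = Z.to_numpy()
        for i in range(len(Z)):
            avail = ~np.isnan(Zv[i])
            if not avail.any():
                continue
            sub = v[avail]
            scores[i] = Zv[i, avail] @ (sub / np.linalg.norm(sub))
        return scores

    def summary_(self, region_label: str = "", scores: np.ndarray | None = None) -> PCASummary:
        return PCASummary(
            region_label=region_label, features_used=self.features_used_,
            loadings=dict(self.loadings_),
            squared_loadings={k: float(v**2) for k, v in self.loadings_.items()},
            explained_variance_fraction=self.explained_variance_fraction_,
            pc1_scores=scores if scores is not None else np.array([]),
        )


def regionwise_pc1(X: pd.DataFrame, region_label: str = "",
                   sign_feature: str = "exponent") -> PCASummary:
    """Functional wrapper: PC1 summary for one region's feature matrix."""
    model = RegionPC1(sign_feature=sign_feature).fit(X)
    return model.summary_(region_label=region_label, scores=model.transform(X))


class RegionwisePC1Reducer(BaseEstimator, TransformerMixin):
    """Reduce a long per-region feature table to a subjects x regions PC1 matrix.

    Input tables need columns ``subject_id``, ``region_label`` and the feature
    columns; regions where PC1 cannot be computed (too few complete subjects)
    are dropped.
    """

    def __init__(self, features: tuple[str, ...] = PREDICTOR_FEATURES,
                 sign_feature: str = "exponent"):
        self.features = features
        self.sign_feature = sign_feature

    def _pivot(self, table: pd.DataFrame) -> dict[str, pd.DataFrame]:
        out = {}
        for region, sub in table.groupby("region_label", observed=True):
            out[region] = sub.set_index("subject_id")[list(self.features)]
        return out

    def fit(self, table: pd.DataFrame, y: None = None) -> "RegionwisePC1Reducer":
        self.models_ = {}
        self.summaries_ = []
        for region, X in self._pivot(table).items():
            try:
                model = RegionPC1(sign_feature=self.sign_feature).fit(X)
            except ValueError:
                continue
            self.models_[region] = model
            self.summaries_.append(model.summary_(region_label=region))
        if not self.models_:
            raise ValueError("no region yielded a valid PC1")
        self.regions_ = sorted(self.models_)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "models_")
        pivots = self._pivot(table)
        subjects = sorted(table["subject_id"].unique())
        out = pd.DataFrame(index=subjects, columns=self.regions_, dtype=float)
        for region in self.regions_:
            if region not in pivots:
                continue
            X = pivots[region].reindex(subjects)
            out[region] = self.models_[region].transform(X)
        return out

    def summary_frame_(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries_:
            row = {"region_label": s.region_label,
                   "explained_variance_fraction": s.explained_variance_fraction}
            for feat in self.features:
                row[f"loading_{feat}"] = s.loadings.get(feat, np.nan)
                row[f"sq_loading_{feat}"] = s.squared_loadings.get(feat, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


class PLSProgression(BaseEstimator, RegressorMixin):
    """PLS1 (NIPALS) regression of a progression rate on predictor scores.

    Predictors are column-standardized and the outcome centered with training
    statistics.  Fitted attributes: ``x_weights_`` (p x k, unit columns),
    ``x_loadings_``, ``y_loadings_``, ``x_scores_``, ``coef_`` (standardized
    predictor scale), ``vip_``, ``r2_train_``, ``rmse_train_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: np.ndarray | pd.DataFrame, y: np.ndarray) -> "PLSProgression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if np.isnan(X).any():
            raise ValueError("predictor matrix contains missing values")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.x_mean_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=1)
        self.x_std_ = np.where(std > 0, std, 1.0)
        self.y_mean_ = float(y.mean())
        Xs = (X - self.x_mean_) / self.x_std_
        if self.n_components > np.linalg.matrix_rank(Xs):
            raise ValueError(
                f"n_components={self.n_components} exceeds predictor rank "
                f"{np.linalg.matrix_rank(Xs)}"
            )
        yc = y - self.y_mean_

        n, p = Xs.shape
        k = self.n_components
        W = np.zeros((p, k))
        P = np.zeros((p, k))
        q = np.zeros(k)
        T = np.zeros((n, k))
        Xd, yd = Xs.copy(), yc.copy()
        for a in range(k):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("zero covariance between predictors and outcome")
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            p_a = Xd.T @ t / tt
            q_a = float(yd @ t / tt)
            W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
            Xd = Xd - np.outer(t, p_a)
            yd = yd - q_a * t

        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, q, T
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        self.vip_ = vip_scores(self)
        pred = self.y_mean_ + Xs @ self.coef_
        self.r2_train_, self.rmse_train_ = evaluate(y, pred)
        return self

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xs = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_std_
        return self.y_mean_ + Xs @ self.coef_


def fit_pls(X: np.ndarray | pd.DataFrame, y: np.ndarray,
            n_components: int = 2) -> PLSProgression:
    """Functional wrapper over :class:`PLSProgression`."""
    return PLSProgression(n_components=n_components).fit(X, y)


def vip_scores(fit: PLSProgression) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt(p * sum_k SSY_k (w_jk/||w_k||)^2 / sum_k SSY_k)`` where
    ``SSY_k = q_k^2 t_k't_k`` is the outcome variance captured by component k.
    Squared VIPs average to 1 over predictors.
    """
    W, q, T = fit.x_weights_, fit.y_loadings_, fit.x_scores_
    p = W.shape[0]
    ssy = q**2 * np.sum(T**2, axis=0)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("zero explained outcome variance; VIP undefined")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ssy) / total)


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """R-squared about the evaluation-set mean, and RMSE (points/year)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant outcome: R-squared undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return 1.0 - ss_res / ss_tot, rmse


def loo_select_components(X: np.ndarray | pd.DataFrame, y: np.ndarray,
                          max_components: int = 5) -> int:
    """Number of PLS components minimizing leave-one-out RMSEP (ties -> fewer)."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out selection")
    kmax = min(max_components, n - 2, np.linalg.matrix_rank(X - X.mean(axis=0)))
    press = np.zeros(kmax)
    for i in range(n):
        mask = np.arange(n) != i
        for k in range(1, kmax + 1):
            model = PLSProgression(n_components=k).fit(X[mask], y[mask])
            press[k - 1] += float((y[i] - model.predict(X[i : i + 1])[0]) ** 2)
    return int(np.argmin(press)) + 1  # argmin returns the first (smallest k) tie


def permutation_p(null_values: np.ndarray, observed: float,
                  estimator: str = "fraction") -> float:
    """P-value from a permutation null distribution.

    The default plain-fraction rule is ``(#null >= observed) / n``; the
    ``"add_one"`` estimator uses ``(#null >= observed + 1) / (n + 1)``.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 1:
        raise ValueError("need at least one permutation")
    exceed = int(np.sum(null_values >= observed))
    if estimator == "add_one":
        return (exceed + 1) / (null_values.size + 1)
    if estimator == "fraction":
        return exceed / null_values.size
    raise ValueError(f"unknown p estimator {estimator!r}")


@dataclass(frozen=True)
class ValidationReport:
    r2_validation: float
    rmse_validation: float
    permutation_p: float
    n_permutations: int
    null_r2_mean: float
    null_r2_q95: float
    seed: int
    n_components: int


def permutation_test(
    X_train: np.ndarray | pd.DataFrame,
    y_train: np.ndarray,
    X_val: np.ndarray | pd.DataFrame,
    y_val: np.ndarray,
    n_components: int | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    reselect_components: bool = False,
    max_components: int = 5,
    p_estimator: str = "fraction",
) -> ValidationReport:
    """Label-permutation null for the external-validation R-squared.

    For each permutation the training outcome is shuffled, the pipeline refit
    (optionally re-running leave-one-out component selection) and evaluated on
    the untouched validation pair; ``p`` is the plain fraction of null R2
    values at or above the observed one (set ``p_estimator="add_one"`` for the
    (b+1)/(n+1) variant).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    if n_components is None:
        n_components = loo_select_components(X_train, y_train, max_components)
    model = PLSProgression(n_components=n_components).fit(X_train, y_train)
    r2_obs, rmse_obs = evaluate(y_val, model.predict(X_val))

    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y_train)
        k = (loo_select_components(X_train, y_perm, max_components)
             if reselect_components else n_components)
        try:
            m = PLSProgression(n_components=k).fit(X_train, y_perm)
            null[b], _ = evaluate(y_val, m.predict(X_val))
        except ValueError:
            null[b] = -np.inf
    p = permutation_p(null, r2_obs, estimator=p_estimator)
    finite = null[np.isfinite(null)]
    return ValidationReport(
        r2_validation=r2_obs, rmse_validation=rmse_obs, permutation_p=float(p),
        n_permutations=n_perm,
        null_r2_mean=float(finite.mean()) if finite.size else float("nan"),
        null_r2_q95=float(np.quantile(finite, 0.95)) if finite.size else float("nan"),
        seed=seed, n_components=n_components,
    )


def augment_covariates(
    X: pd.DataFrame | np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    baseline_updrs: np.ndarray,
    train_stats: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Append standardized age/sex/baseline-score columns to the PC1 matrix.

    Standardization statistics come from *train_stats* when given (so the
    validation cohort reuses the training scaling); otherwise they are
    computed here and returned for later reuse.
    """
    X = pd.DataFrame(X).copy()
    sex = np.asarray(sex)
    if sex.dtype.kind in "OUS":
        sex = pd.Series(list(sex)).map({"F": 1.0, "M": 0.0}).to_numpy()
    cov = {"age": np.asarray(age, dtype=float),
           "sex": np.asarray(sex, dtype=float),
           "baseline_updrs": np.asarray(baseline_updrs, dtype=float)}
    for name, vals in cov.items():
        if np.isnan(vals).any():
            raise ValueError(f"missing values in covariate {name!r}")
    if train_stats is None:
        train_stats = {name: (float(v.mean()), float(v.std(ddof=1)) or 1.0)
                       for name, v in cov.items()}
    for name, vals in cov.items():
        mean, std = train_stats[name]
        X[name] = (vals - mean) / (std if std > 0 else 1.0)
    return X, train_stats
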