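"""Linear and non-linear regression suite over the perturbation features.

Seven methods mirror the modelling study: multiple linear regression (LM),
stepwise-selected linear model (GLM), partial least squares (PLS), Lasso,
Elastic Net (ENET), a single-hidden-layer neural network (NN) and random
forest (RF).  OLS carries a full inference block (R, R^2, residual SS,
F and per-coefficient t/p); the other learners are scikit-learn estimators
tuned by seeded repeated cross-validation minimizing RMSE.  Model quality is
reported as RMSE / R^2 / R per subset, and models are compared pairwise on
resampled RMSEs with Student's t tests under Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold
from sklearn.neural_network import MLPRegressor

from .study_data import SchemaError, ValidationError

__all__ = [
    "METHODS",
    "FitResult",
    "EvalResult",
    "ComparisonTable",
    "fit_ols",
    "stepwise_select",
    "fit_suite",
    "evaluate",
    "feature_importance",
    "compare_models",
    "resample_rmse",
    "default_grids",
]

METHODS = ("LM", "GLM", "PLS", "Lasso", "ENET", "NN", "RF")


@dataclass
class FitResult:
    """A fitted model plus everything needed to report and reuse it."""

    method: str
    features: list[str]
    estimator: object
    hyperparams: dict = field(default_factory=dict)
    coefficients: dict | None = None  # intercept + per-feature weights (linear fits)
    inference: dict | None = None  # OLS statistics block
    seed: int = 0

    @property
    def selected_features(self) -> list[str]:
        return self.hyperparams.get("selected_features", self.features)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in X.columns]
        if missing:
            raise SchemaError(f"feature(s) absent from input: {', '.join(missing)}")
        return np.asarray(self.estimator.predict(X[self.features].to_numpy(dtype=float)))


@dataclass
class EvalResult:
    subset: str
    rmse: float
    r2: float
    r: float


@dataclass
class ComparisonTable:
    """Resampled per-model means with CIs and Bonferroni-corrected pair tests."""

    means: pd.DataFrame  # model, mean, lo, hi
    pairs: pd.DataFrame  # model_a, model_b, mean_diff, t, p_raw, p_adj, degenerate
    conf_level: float
    n_resamples: int


class _OLSAdapter(BaseEstimator, RegressorMixin):
    """Thin sklearn-compatible wrapper over a closed-form least-squares fit."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        design = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(design, np.asarray(y, dtype=float), rcond=None)
        self.intercept_ = beta[0]
        self.coef_ = beta[1:]
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_


class StepwiseOLS(BaseEstimator, RegressorMixin):
    """Greedy bidirectional feature selection by information criterion.

    Starting from the empty model, repeatedly adds the candidate that most
    improves the criterion, then tries single drops, until no move improves.
    Deterministic: candidates are scanned in column order and a move must
    strictly improve the criterion.
    """

    def __init__(self, criterion: str = "aic", direction: str = "both"):
        self.criterion = criterion
        self.direction = direction

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        selected: list[int] = []
        const = np.ones((n, 1))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        # floor SSR at numerical noise so an exact fit is not "improved"
        # by rounding-level reductions from extra features
        ssr_floor = 1e-12 * max(ss_tot, 1.0)
        penalty = 2.0 if self.criterion == "aic" else math.log(n)

        def crit(cols):
            design = np.hstack([const, X[:, cols]]) if cols else const
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            ssr = float(np.sum((y - design @ beta) ** 2))
            k = design.shape[1]
            return n * math.log(max(ssr, ssr_floor) / n) + penalty * k

        best = crit(selected)
        improved = True
        while improved:
            improved = False
            if self.direction in ("both", "forward"):
                candidates = [j for j in range(p) if j not in selected]
                scores = [(crit(selected + [j]), j) for j in candidates]
                if scores:
                    sc, j = min(scores)
                    if sc < best - 1e-10:
                        selected.append(j)
                        best = sc
                        improved = True
            if self.direction in ("both", "backward") and selected:
                scores = [
                    (crit([k for k in selected if k != j]), j) for j in selected
                ]
                sc, j = min(scores)
                if sc < best - 1e-10:
                    selected.remove(j)
                    best = sc
                    improved = True
        self.selected_ = sorted(selected)
        design = np.hstack([const, X[:, self.selected_]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = beta[0]
        self.coef_full_ = np.zeros(p)
        self.coef_full_[self.selected_] = beta[1:]
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_full_


# ---------------------------------------------------------------------------
# OLS with inference


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [names[j - 1] for j in range(1, design.shape[1]) if diag[j] < tol]
        raise ValidationError(
            "design matrix is rank deficient; collinear feature(s): "
            + (", ".join(bad) if bad else "<undetermined>")
        )


def fit_ols(features: pd.DataFrame, target, seed: int = 0) -> FitResult:
    """Closed-form least squares with the full inference block.

    Reports R, R^2, residual sum of squares, model df, the overall F test and
    per-coefficient standard errors / t / p.  Raises on rank-deficient
    designs, naming the collinear features.
    """
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if len(X) <= X.shape[1] + 1:
        raise ValidationError("need N > p + 1 observations for OLS inference")
    _check_rank(X, names)
    design = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, design).fit()
    coef_names = ["intercept"] + names
    r2 = float(res.rsquared)
    inference = {
        "n": int(res.nobs),
        "r2": r2,
        "r": math.sqrt(max(r2, 0.0)),
        "ss_residual": float(res.ssr),
        "df_model": int(res.df_model),
        "df_resid": int(res.df_resid),
        "f": float(res.fvalue) if names else math.nan,
        "f_p": float(res.f_pvalue) if names else math.nan,
        "coef_se": dict(zip(coef_names, map(float, res.bse))),
        "coef_t": dict(zip(coef_names, map(float, res.tvalues))),
        "coef_p": dict(zip(coef_names, map(float, res.pvalues))),
    }
    est = _OLSAdapter().fit(X, y)
    return FitResult(
        method="OLS",
        features=names,
        estimator=est,
        coefficients=dict(zip(coef_names, map(float, res.params))),
        inference=inference,
        seed=seed,
    )


def stepwise_select(
    features: pd.DataFrame,
    target,
    direction: str = "both",
    criterion: str = "aic",
) -> tuple[list[str], FitResult]:
    """Greedy stepwise selection; returns the kept features and their OLS fit."""
    if features.shape[1] < 1:
        raise ValidationError("need at least one candidate feature")
    sw = StepwiseOLS(criterion=criterion, direction=direction).fit(
        features.to_numpy(dtype=float), np.asarray(target, dtype=float)
    )
    selected = [features.columns[j] for j in sw.selected_]
    if selected:
        fit = fit_ols(features[selected], target)
    else:  # intercept-only null model
        y = np.asarray(target, dtype=float)
        est = _OLSAdapter().fit(np.empty((len(y), 0)), y)
        fit = FitResult(
            method="OLS",
            features=[],
            estimator=est,
            coefficients={"intercept": float(np.mean(y))},
            inference={"n": len(y), "r2": 0.0, "r": 0.0,
                       "ss_residual": float(np.sum((y - y.mean()) ** 2)),
                       "df_model": 0, "df_resid": len(y) - 1,
                       "f": math.nan, "f_p": math.nan,
                       "coef_se": {}, "coef_t": {}, "coef_p": {}},
        )
    fit.method = "GLM"
    fit.hyperparams = {"selected_features": selected, "criterion": criterion,
                       "direction": direction}
    return selected, fit


# ---------------------------------------------------------------------------
# The tuned suite


def default_grids(n_features: int = 5) -> dict:
    """Hyperparameter grids per method.

    NN sweeps the published neuron counts and weight decays; RF sweeps the
    published tree counts (1, 5, 10) and the features-per-split (mtry).
    """
    return {
        "LM": {},
        "GLM": {},
        "PLS": {"n_components": list(range(1, n_features + 1))},
        "Lasso": {"alpha": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1]},
        "ENET": {
            "alpha": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
            "l1_ratio": [0.1, 0.5, 0.9],
        },
        "NN": {
            "hidden_layer_sizes": [(1,), (5,), (10,), (15,), (20,), (50,)],
            "alpha": [1e-8, 0.1, 0.001],
        },
        "RF": {
            "n_estimators": [1, 5, 10],
            "max_features": list(range(1, n_features + 1)),
        },
    }


def _base_estimator(method: str, seed: int):
    if method == "LM":
        return LinearRegression()
    if method == "GLM":
        return StepwiseOLS()
    if method == "PLS":
        return PLSRegression(n_components=2, scale=False)
    if method == "Lasso":
        return Lasso(alpha=1e-4, max_iter=50_000)
    if method == "ENET":
        return ElasticNet(alpha=1e-4, l1_ratio=0.5, max_iter=50_000)
    if method == "NN":
        return MLPRegressor(
            hidden_layer_sizes=(15,),
            alpha=0.001,
            solver="lbfgs",
            max_iter=2000,
            random_state=seed,
        )
    if method == "RF":
        # untuned defaults: the winning sweep point (5 trees, 2 features/split)
        return RandomForestRegressor(
            n_estimators=5, max_features=2, random_state=seed, n_jobs=1
        )
    raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")


def _linear_coefficients(method: str, est, names: list[str]) -> dict | None:
    if method in ("LM", "GLM", "Lasso", "ENET"):
        coef = np.ravel(est.coef_full_ if hasattr(est, "coef_full_") else est.coef_)
        out = {"intercept": float(np.ravel(est.intercept_)[0])}
        out.update({n: float(c) for n, c in zip(names, coef)})
        return out
    if method == "PLS":
        out = {"intercept": float(np.ravel(est.intercept_)[0])}
        out.update({n: float(c) for n, c in zip(names, np.ravel(est.coef_))})
        return out
    return None


def fit_suite(
    train: pd.DataFrame,
    target_col: str = "target",
    feature_cols: list[str] | None = None,
    methods: list[str] | None = None,
    grids: dict | None = None,
    seed: int = 0,
    cv: tuple[int, int] = (5, 3),
    tune: bool = True,
) -> dict[str, FitResult]:
    """Fit (and optionally tune) each requested method on the training cases.

    Tuning uses seeded repeated K-fold CV (``cv = (folds, repeats)``)
    minimizing RMSE; with ``tune=False`` the fixed mid-grid defaults are
    used.  Everything is deterministic under ``seed``.
    """
    methods = list(methods or METHODS)
    for m in methods:
        if m not in METHODS:
            raise ValidationError(f"unknown method {m!r}; choose from {METHODS}")
    if feature_cols is None:
        feature_cols = [c for c in train.columns if c not in
                        (target_col, "query_id", "ref_id")]
    missing = [c for c in feature_cols + [target_col] if c not in train.columns]
    if missing:
        raise SchemaError(f"column(s) absent from training data: {', '.join(missing)}")
    if train.empty:
        raise ValidationError("training data is empty")
    X = train[feature_cols].to_numpy(dtype=float)
    y = train[target_col].to_numpy(dtype=float)
    grids = {**default_grids(len(feature_cols)), **(grids or {})}

    results: dict[str, FitResult] = {}
    for method in methods:
        est = _base_estimator(method, seed)
        grid = grids.get(method, {})
        if method == "PLS":
            grid = {**grid}
            if "n_components" in grid:
                grid["n_components"] = [
                    k for k in grid["n_components"] if k <= len(feature_cols)
                ]
        if tune and grid:
            splitter = RepeatedKFold(
                n_splits=cv[0], n_repeats=cv[1], random_state=seed
            )
            search = GridSearchCV(
                est,
                grid,
                scoring="neg_root_mean_squared_error",
                cv=splitter,
                n_jobs=1,
                refit=True,
            )
            search.fit(X, y)
            est = search.best_estimator_
            hyper = dict(search.best_params_)
        else:
            est = est.fit(X, y)
            hyper = {
                k: getattr(est, k)
                for k in grid
                if hasattr(est, k)
            }
        fr = FitResult(
            method=method,
            features=list(feature_cols),
            estimator=est,
            hyperparams=hyper,
            coefficients=_linear_coefficients(method, est, list(feature_cols)),
            seed=seed,
        )
        if method == "GLM":
            fr.hyperparams["selected_features"] = [
                feature_cols[j] for j in est.selected_
            ]
        if method in ("LM", "GLM"):
            # attach the closed-form inference block for the linear fits
            sel = fr.hyperparams.get("selected_features", feature_cols)
            if sel:
                fr.inference = fit_ols(train[sel], y).inference
        results[method] = fr
    return results


# ---------------------------------------------------------------------------
# Evaluation, importance, comparison


def evaluate(fit: FitResult, data: pd.DataFrame, target_col: str = "target",
             subset: str = "test") -> EvalResult:
    """RMSE, R^2 = 1 - SS_res/SS_tot and R = sqrt(max(R^2, 0)) on one subset."""
    y = data[target_col].to_numpy(dtype=float)
    pred = fit.predict(data)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res == 0 else -math.inf
    return EvalResult(subset=subset, rmse=rmse, r2=r2, r=math.sqrt(max(r2, 0.0)))


def feature_importance(
    fit: FitResult,
    data: pd.DataFrame | None = None,
    target_col: str = "target",
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.Series:
    """Feature scores scaled to [0, 100] with the top feature at 100.

    Linear fits score |coefficient| x feature SD (standardized effect size);
    non-linear fits use seeded permutation importance on the supplied data.
    """
    if fit.coefficients is not None:
        raw = {}
        for name in fit.features:
            c = abs(fit.coefficients.get(name, 0.0))
            if data is not None:
                c *= float(data[name].std(ddof=0))
            raw[name] = c
        scores = pd.Series(raw)
    else:
        if data is None:
            raise ValidationError(
                f"permutation importance for {fit.method} needs evaluation data"
            )
        res = permutation_importance(
            fit.estimator,
            data[fit.features].to_numpy(dtype=float),
            data[target_col].to_numpy(dtype=float),
            n_repeats=n_repeats,
            random_state=seed,
            scoring="neg_root_mean_squared_error",
        )
        scores = pd.Series(res.importances_mean, index=fit.features).clip(lower=0.0)
    top = scores.max()
    if top > 0:
        scores = 100.0 * scores / top
    return scores.sort_values(ascending=False)


def resample_rmse(
    fits: dict[str, FitResult],
    data: pd.DataFrame,
    target_col: str = "target",
    n_splits: int = 5,
    n_repeats: int = 3,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-fold RMSEs on a common set of CV folds, for paired model comparison.

    Each model's chosen configuration is refit on every fold's training part
    and scored on its held-out part, so the resample vectors are paired
    across models.
    """
    splitter = RepeatedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    out = {name: [] for name in fits}
    first = next(iter(fits.values()))
    X_all = data[first.features].to_numpy(dtype=float)
    y_all = data[target_col].to_numpy(dtype=float)
    for train_idx, test_idx in splitter.split(X_all):
        for name, fr in fits.items():
            Xf = data[fr.features].to_numpy(dtype=float)
            est = clone(fr.estimator)
            est.fit(Xf[train_idx], y_all[train_idx])
            pred = est.predict(Xf[test_idx])
            out[name].append(
                float(np.sqrt(np.mean((y_all[test_idx] - np.ravel(pred)) ** 2)))
            )
    return {k: np.asarray(v) for k, v in out.items()}


def compare_models(
    resamples: dict[str, np.ndarray], conf_level: float = 0.95
) -> ComparisonTable:
    """Paired Student's t tests over model pairs with Bonferroni correction.

    The Bonferroni factor is the number of model pairs; adjusted p values are
    clipped at 1.  A zero-variance difference vector is a degenerate t: it is
    reported as p = 0 (p = 1 when the difference itself is zero) with a flag.
    """
    names = sorted(resamples)
    if len(names) < 2:
        raise ValidationError("need at least two models to compare")
    lengths = {len(resamples[n]) for n in names}
    if len(lengths) != 1:
        raise ValidationError("all models need the same number of paired resamples")
    n = lengths.pop()
    alpha = 1.0 - conf_level
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, n - 1)
    mean_rows = []
    for name in names:
        v = np.asarray(resamples[name], dtype=float)
        m = float(v.mean())
        half = tcrit * v.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan
        mean_rows.append({"model": name, "mean": m, "lo": m - half, "hi": m + half})
    pairs = list(itertools.combinations(names, 2))
    m_pairs = len(pairs)
    pair_rows = []
    for a, b in pairs:
        diff = np.asarray(resamples[a], dtype=float) - np.asarray(resamples[b], dtype=float)
        mean_diff = float(diff.mean())
        degenerate = bool(np.allclose(diff.std(ddof=1) if n > 1 else 0.0, 0.0))
        if degenerate:
            t = math.inf if mean_diff != 0 else 0.0
            p_raw = 0.0 if mean_diff != 0 else 1.0
        else:
            t, p_raw = scipy.stats.ttest_rel(resamples[a], resamples[b])
            t, p_raw = float(t), float(p_raw)
        pair_rows.append(
            {
                "model_a": a,
                "model_b": b,
                "mean_diff": mean_diff,
                "t": t,
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * m_pairs),
                "degenerate": degenerate,
            }
        )
    return ComparisonTable(
        means=pd.DataFrame(mean_rows),
        pairs=pd.DataFrame(pair_rows),
        conf_level=conf_level,
        n_resamples=n,
    )
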