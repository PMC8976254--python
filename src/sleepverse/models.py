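"""Single-predictor model families and the predicted-R2 metric.

Five families per outcome: a random-intercept mixed model (replaced by
an ordinary linear model for the person-level depression outcome, which
has no nested structure), k-nearest neighbours, an RBF support vector
machine, gradient-boosted trees, and a spline GAM. Every family uses
exactly one input feature; hyperparameters are chosen by an internal
seeded 5-fold cross-validation over a small fixed grid on the training
set. The feature is standardized with training-set mean/SD (reused at
prediction time), so mixed/linear slopes are standardized coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import PerfectSeparationError

_FIT_ERRORS = (np.linalg.LinAlgError, ValueError, NotImplementedError,
               PerfectSeparationError)

from sleepverse.errors import DegeneratePredictorError

MODEL_KINDS = ("mixed_effects", "knn", "svm_radial", "xgboost", "gam_splines")

KNN_GRID = (3, 5, 7, 9, 15)
SVM_COST_GRID = (0.25, 1.0, 4.0)
XGB_DEPTH_GRID = (2, 3)
GAM_DF_GRID = (5, 10)


def predicted_r2(observed, predicted) -> float:
    """1 - SSE/SST on an evaluation set, with SST about the evaluation
    set's own mean; <= 1, and negative when predictions are worse than
    that mean."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if len(y) < 2:
        raise ValueError("predicted_r2 needs at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("predicted_r2 undefined for constant observed values")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


@dataclass
class FitResult:
    """A fitted single-predictor model plus its prediction closure."""

    kind: str
    feature: str
    outcome: str
    status: str = "ok"  # ok | inoperable
    slope: float | None = None
    slope_se: float | None = None
    slope_ci: tuple[float, float] | None = None
    hyperparams: dict = field(default_factory=dict)
    _predict: Callable | None = None
    _x_mean: float = 0.0
    _x_sd: float = 1.0

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Predictions for evaluation rows with a non-missing feature."""
        if self.status != "ok":
            raise RuntimeError(f"cannot predict from an {self.status} fit")
        z = (rows[self.feature].to_numpy(dtype=float) - self._x_mean) / self._x_sd
        return self._predict(z, rows)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        sd = 1.0
    return (x - mean) / sd, mean, sd


def _fit_mixed(z, y, groups, result: FitResult) -> FitResult:
    exog = sm.add_constant(z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(y, exog, groups=groups)
            fit = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError):
            result.status = "inoperable"
            return result
    if not np.all(np.isfinite(fit.params)):
        result.status = "inoperable"
        return result
    result.slope = float(fit.params[1])
    result.slope_se = float(fit.bse[1])
    ci = fit.conf_int()
    result.slope_ci = (float(ci[1][0]), float(ci[1][1]))
    re = {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}
    intercept, slope = float(fit.params[0]), float(fit.params[1])

    def predict(z_new, rows):
        offsets = rows["participant_id"].map(re).fillna(0.0).to_numpy()
        return intercept + slope * z_new + offsets

    result._predict = predict
    return result


def _fit_linear(z, y, result: FitResult) -> FitResult:
    fit = sm.OLS(y, sm.add_constant(z)).fit()
    result.slope = float(fit.params[1])
    result.slope_se = float(fit.bse[1])
    ci = fit.conf_int()
    result.slope_ci = (float(ci[1][0]), float(ci[1][1]))
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    result._predict = lambda z_new, rows: intercept + slope * z_new
    return result


def _cv(seed: int, n: int) -> KFold:
    return KFold(n_splits=min(5, n), shuffle=True, random_state=seed)


def _fit_knn(z, y, seed: int, result: FitResult) -> FitResult:
    grid = [k for k in KNN_GRID if k <= max(1, int(len(z) * 0.8))]
    if not grid:
        grid = [1]
    est = KNeighborsRegressor()
    if len(z) >= 10 and len(grid) > 1:
        search = GridSearchCV(est, {"n_neighbors": grid}, cv=_cv(seed, len(z)),
                              scoring="neg_mean_squared_error")
        search.fit(z.reshape(-1, 1), y)
        best = search.best_estimator_
        result.hyperparams = {"n_neighbors": search.best_params_["n_neighbors"]}
    else:
        best = KNeighborsRegressor(n_neighbors=grid[0]).fit(z.reshape(-1, 1), y)
        result.hyperparams = {"n_neighbors": grid[0]}
    result._predict = lambda z_new, rows: best.predict(z_new.reshape(-1, 1))
    return result


def _median_heuristic_gamma(z: np.ndarray, seed: int) -> float:
    rng = np.random.default_rng(seed)
    sample = z if len(z) <= 500 else rng.choice(z, 500, replace=False)
    dists = np.abs(sample[:, None] - sample[None, :])
    med = float(np.median(dists[dists > 0])) if (dists > 0).any() else 1.0
    return 1.0 / (2 * med * med)


def _fit_svm(z, y, seed: int, result: FitResult) -> FitResult:
    gamma = _median_heuristic_gamma(z, seed)
    if len(z) >= 10:
        search = GridSearchCV(
            SVR(kernel="rbf", gamma=gamma), {"C": list(SVM_COST_GRID)},
            cv=_cv(seed, len(z)), scoring="neg_mean_squared_error",
        )
        search.fit(z.reshape(-1, 1), y)
        best = search.best_estimator_
        result.hyperparams = {"C": search.best_params_["C"], "gamma": gamma}
    else:
        best = SVR(kernel="rbf", gamma=gamma, C=1.0).fit(z.reshape(-1, 1), y)
        result.hyperparams = {"C": 1.0, "gamma": gamma}
    result._predict = lambda z_new, rows: best.predict(z_new.reshape(-1, 1))
    return result


def _fit_xgb(z, y, seed: int, result: FitResult) -> FitResult:
    base = dict(n_estimators=100, learning_rate=0.1, random_state=seed)
    if len(z) >= 10:
        search = GridSearchCV(
            GradientBoostingRegressor(**base), {"max_depth": list(XGB_DEPTH_GRID)},
            cv=_cv(seed, len(z)), scoring="neg_mean_squared_error",
        )
        search.fit(z.reshape(-1, 1), y)
        best = search.best_estimator_
        result.hyperparams = {"max_depth": search.best_params_["max_depth"], **base}
    else:
        best = GradientBoostingRegressor(max_depth=2, **base).fit(z.reshape(-1, 1), y)
        result.hyperparams = {"max_depth": 2, **base}
    result._predict = lambda z_new, rows: best.predict(z_new.reshape(-1, 1))
    return result


def _gam_fit_one(z, y, df: int):
    smoother = BSplines(z.reshape(-1, 1), df=[df], degree=[3])
    model = GLMGam(y, np.ones((len(y), 1)), smoother=smoother)
    return model.fit()


def _fit_gam(z, y, seed: int, result: FitResult) -> FitResult:
    n_unique = len(np.unique(z))
    grid = [df for df in GAM_DF_GRID if df + 1 < n_unique] or [min(GAM_DF_GRID)]
    best_df, best_mse = grid[0], np.inf
    if len(grid) > 1 and len(z) >= 15:
        cv = _cv(seed, len(z))
        for df in grid:
            mses = []
            for tr, te in cv.split(z):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = _gam_fit_one(z[tr], y[tr], df)
                        # spline basis is only defined on the training range
                        z_te = np.clip(z[te], z[tr].min(), z[tr].max())
                        pred = fit.predict(
                            np.ones((len(te), 1)), exog_smooth=z_te.reshape(-1, 1)
                        )
                    mses.append(float(np.mean((y[te] - pred) ** 2)))
                except _FIT_ERRORS:
                    mses.append(np.inf)
            mse = float(np.mean(mses))
            if mse < best_mse:
                best_df, best_mse = df, mse
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = _gam_fit_one(z, y, best_df)
    except _FIT_ERRORS:
        result.status = "inoperable"
        return result
    result.hyperparams = {"df": best_df}
    z_lo, z_hi = float(z.min()), float(z.max())

    def predict(z_new, rows):
        z_new = np.clip(z_new, z_lo, z_hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(
                fit.predict(np.ones((len(z_new), 1)), exog_smooth=z_new.reshape(-1, 1))
            )

    result._predict = predict
    return result


def fit(
    kind: str,
    train: pd.DataFrame,
    feature: str,
    outcome: str,
    seed: int = 0,
) -> FitResult:
    """Fit one model family on training rows with non-missing feature
    and outcome.

    ``kind`` may also be ``"linear"``, the substitution used for the
    depression outcome. Raises :class:`DegeneratePredictorError` when
    the feature has fewer than 2 distinct values; a non-converging mixed
    model returns a result with ``status="inoperable"``.
    """
    if kind not in MODEL_KINDS and kind != "linear":
        raise ValueError(f"unknown model kind {kind!r}")
    rows = train.dropna(subset=[feature, outcome])
    x = rows[feature].to_numpy(dtype=float)
    y = rows[outcome].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise DegeneratePredictorError(
            f"feature {feature!r} has fewer than 2 distinct training values"
        )
    z, mean, sd = _standardize(x)
    result = FitResult(kind=kind, feature=feature, outcome=outcome,
                       _x_mean=mean, _x_sd=sd)
    if kind == "mixed_effects":
        return _fit_mixed(z, y, rows["participant_id"].to_numpy(), result)
    if kind == "linear":
        return _fit_linear(z, y, result)
    if kind == "knn":
        return _fit_knn(z, y, seed, result)
    if kind == "svm_radial":
        return _fit_svm(z, y, seed, result)
    if kind == "xgboost":
        return _fit_xgb(z, y, seed, result)
    if kind == "gam_splines":
        return _fit_gam(z, y, seed, result)
    raise AssertionError(kind)
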