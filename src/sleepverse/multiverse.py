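"""Grid enumeration, the hold-out workflow and 1-SE model selection.

The full grid crosses 10 sensor configurations x 7 features x 3
outcomes x 5 model families x 4 outlier methods x 3 adjacent-window
thresholds = 12,600 configurations. Each is evaluated with the same
workflow: split the data (first week for training; days 1-4 and 5-7 of
the second week for validation and test for the daily outcomes; a
gender-stratified 60/20/20 participant split for depression), train on
the training set only, score predicted R2 on the validation set, keep
per outcome the models (at most 5) within one standard error of the
best validation R2, and only then score those on the test set.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd

from sleepverse import models as mdl
from sleepverse.errors import DegeneratePredictorError
from sleepverse.features import FEATURES, K_VALUES, compute_feature_table, user_active_table
from sleepverse.ingest import OutcomeTable
from sleepverse.outliers import OUTLIER_KINDS, OutlierMethod, remove_outliers
from sleepverse.preprocess import SensorConfig, clean_events, default_sensor_configs
from sleepverse.windows import build_grids

log = logging.getLogger(__name__)

OUTCOMES = ("ssq", "na", "depression")

# tie-break order for 1-SE selection: fewer tunable parts first
MODEL_SIMPLICITY = ("mixed_effects", "linear", "knn", "svm_radial",
                    "gam_splines", "xgboost")


@dataclass(frozen=True)
class MultiverseConfig:
    """One point of the analysis grid."""

    sensor: str  # SensorConfig label, e.g. "accelerometer_0.5"
    feature: str
    outcome: str
    model: str
    outlier: str
    k: int

    @property
    def key(self) -> str:
        return f"{self.sensor}|{self.feature}|{self.outcome}|{self.model}|{self.outlier}|{self.k}"


def enumerate_grid(
    sensors: list[str] | None = None,
    features: tuple = FEATURES,
    outcomes: tuple = OUTCOMES,
    model_kinds: tuple = mdl.MODEL_KINDS,
    outlier_kinds: tuple = OUTLIER_KINDS,
    ks: tuple = K_VALUES,
) -> list[MultiverseConfig]:
    """Deterministic Cartesian product of the multiverse parameter sets;
    12,600 configurations under the defaults."""
    if sensors is None:
        sensors = [c.label for c in default_sensor_configs()]
    return [
        MultiverseConfig(*combo)
        for combo in itertools.product(sensors, features, outcomes,
                                       model_kinds, outlier_kinds, ks)
    ]


def feature_outcome_pairs(configs: list[MultiverseConfig]) -> list[tuple[str, str]]:
    """Distinct (feature, outcome) combinations in a grid (21 under the
    defaults: 7 features x 3 outcomes)."""
    return sorted({(c.feature, c.outcome) for c in configs})


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class MultiverseData:
    """Feature tables per (sensor label, k) plus the outcome table."""

    tables: dict
    outcomes: OutcomeTable
    exclusion_report: pd.DataFrame = field(default_factory=pd.DataFrame)
    _frame_cache: dict = field(default_factory=dict, repr=False)


def prepare_data(
    events: pd.DataFrame,
    outcomes: OutcomeTable,
    sensor_configs: list[SensorConfig] | None = None,
    ks: tuple = K_VALUES,
) -> MultiverseData:
    """Clean the raw event table once, then derive one feature table per
    sensor configuration and adjacent-window threshold."""
    if sensor_configs is None:
        sensor_configs = default_sensor_configs()
    cleaned, report = clean_events(events)
    activity = user_active_table(cleaned)
    tables = {}
    for config in sensor_configs:
        grids = build_grids(cleaned, config)
        for k in ks:
            tables[(config.label, k)] = compute_feature_table(
                grids, k, user_active=activity)
    return MultiverseData(tables=tables, outcomes=outcomes, exclusion_report=report)


def daily_model_frame(
    feature_rows: pd.DataFrame, outcomes: OutcomeTable, outcome: str
) -> pd.DataFrame:
    """Join night features to the next morning's outcome (the night
    starting on date d pairs with day d+1)."""
    rows = feature_rows.copy()
    rows["date"] = rows["night_date"].map(lambda d: d + timedelta(days=1))
    daily = outcomes.daily[["participant_id", "date", outcome]]
    return rows.merge(daily, on=["participant_id", "date"], how="inner")


def depression_model_frame(
    feature_rows: pd.DataFrame, outcomes: OutcomeTable
) -> pd.DataFrame:
    """One row per participant: mean feature values over nights joined
    to the person-level depression score and gender."""
    cols = [c for c in FEATURES if c in feature_rows.columns]
    means = feature_rows.groupby("participant_id", as_index=False)[cols].mean()
    return means.merge(outcomes.person, on="participant_id", how="inner")


# ---------------------------------------------------------------------------
# splits


def split_longitudinal(rows: pd.DataFrame, allow_short: bool = False):
    """Per-participant study-day split: days 1-7 train, 8-11 validation,
    12-14 test. The day index counts from each participant's first
    observed day. Raises when the data span fewer than 14 study days
    unless ``allow_short`` is set."""
    if rows.empty:
        raise ValueError("cannot split an empty table")
    rows = rows.copy()
    first = rows.groupby("participant_id")["date"].transform("min")
    day_index = rows["date"].map(pd.Timestamp) - first.map(pd.Timestamp)
    rows["day_index"] = day_index.dt.days + 1
    if rows["day_index"].max() < 14 and not allow_short:
        raise ValueError("longitudinal split requires a 14-day span")
    train = rows[rows["day_index"] <= 7]
    validation = rows[(rows["day_index"] >= 8) & (rows["day_index"] <= 11)]
    test = rows[rows["day_index"] >= 12]
    return train, validation, test


def _largest_remainder(n: int, shares=(0.6, 0.2, 0.2)) -> list[int]:
    exact = [n * s for s in shares]
    counts = [int(np.floor(e)) for e in exact]
    remainders = sorted(range(3), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[remainders[i % 3]] += 1
    return counts


def split_depression(rows: pd.DataFrame, seed: int):
    """Participant-level 60/20/20 split stratified by gender, with
    per-gender counts allocated by largest remainder and a seeded
    shuffle within each gender."""
    rng = np.random.default_rng(seed)
    parts = {0: [], 1: [], 2: []}
    for _, grp in rows.sort_values("participant_id").groupby("gender", sort=True):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_train, n_val, n_test = _largest_remainder(len(idx))
        parts[0].append(idx[:n_train])
        parts[1].append(idx[n_train:n_train + n_val])
        parts[2].append(idx[n_train + n_val:])
    out = []
    for i in range(3):
        sel = np.concatenate(parts[i]) if parts[i] else np.array([], dtype=int)
        out.append(rows.loc[sel])
    return tuple(out)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalResult:
    """Train/validation (and, after selection, test) predicted R2 for
    one configuration."""

    config: MultiverseConfig
    status: str = "ok"  # ok | inoperable
    reason: str = ""
    r2_train: float | None = None
    r2_validation: float | None = None
    r2_test: float | None = None
    slope: float | None = None
    slope_ci: tuple | None = None
    hyperparams: dict = field(default_factory=dict)
    n_train: int = 0
    n_validation: int = 0
    n_test: int = 0
    _fit: mdl.FitResult | None = None
    _val_obs: np.ndarray | None = None
    _val_pred: np.ndarray | None = None
    _test_rows: pd.DataFrame | None = None
    _split_fingerprints: dict = field(default_factory=dict)


def _fingerprint(rows: pd.DataFrame) -> frozenset:
    if "date" in rows.columns:
        return frozenset(zip(rows["participant_id"], map(str, rows["date"])))
    return frozenset(rows["participant_id"])


def run_config(config: MultiverseConfig, data: MultiverseData, seed: int = 0) -> EvalResult:
    """Evaluate one configuration; failures are recorded as inoperable,
    never raised."""
    result = EvalResult(config=config)
    table = data.tables.get((config.sensor, config.k))
    if table is None or table.empty:
        result.status, result.reason = "inoperable", "no feature table"
        return result

    model_kind = config.model
    try:
        cache_key = (config.sensor, config.k, config.outcome)
        frame = data._frame_cache.get(cache_key)
        if frame is None:
            if config.outcome == "depression":
                frame = depression_model_frame(table, data.outcomes)
            else:
                frame = daily_model_frame(table, data.outcomes, config.outcome)
            data._frame_cache[cache_key] = frame
        if config.outcome == "depression" and model_kind == "mixed_effects":
            model_kind = "linear"  # no nested structure person-level

        method = OutlierMethod(config.outlier, seed=seed)
        frame, _removed = remove_outliers(frame, config.feature, method)

        if config.outcome == "depression":
            train, validation, test = split_depression(frame, seed)
        else:
            train, validation, test = split_longitudinal(frame)

        cols = [config.feature, config.outcome]
        train = train.dropna(subset=cols)
        validation = validation.dropna(subset=cols)
        test = test.dropna(subset=cols)
        result.n_train, result.n_validation, result.n_test = map(
            len, (train, validation, test))
        result._split_fingerprints = {
            "train": _fingerprint(train),
            "validation": _fingerprint(validation),
            "test": _fingerprint(test),
        }
        if len(train) < 3 or len(validation) < 2:
            result.status, result.reason = "inoperable", "too few observations"
            return result

        fit = mdl.fit(model_kind, train, config.feature, config.outcome, seed=seed)
        if fit.status != "ok":
            result.status, result.reason = "inoperable", "fit did not converge"
            return result
        result.slope, result.slope_ci = fit.slope, fit.slope_ci
        result.hyperparams = fit.hyperparams
        result._fit = fit
        result._test_rows = test

        result.r2_train = mdl.predicted_r2(
            train[config.outcome].to_numpy(dtype=float), fit.predict(train))
        val_obs = validation[config.outcome].to_numpy(dtype=float)
        val_pred = fit.predict(validation)
        result.r2_validation = mdl.predicted_r2(val_obs, val_pred)
        result._val_obs, result._val_pred = val_obs, val_pred
    except (DegeneratePredictorError, ValueError) as exc:
        result.status, result.reason = "inoperable", str(exc)
    return result


def run_multiverse(
    configs: list[MultiverseConfig], data: MultiverseData, seed: int = 0
) -> list[EvalResult]:
    """Evaluate every configuration; order-independent, deterministic
    under the seed, with per-1,000-config progress logging."""
    results = []
    for i, config in enumerate(configs, 1):
        results.append(run_config(config, data, seed=seed))
        if i % 1000 == 0:
            log.info("multiverse sweep: %d/%d configs evaluated", i, len(configs))
    return results


def bootstrap_r2_se(
    obs: np.ndarray, pred: np.ndarray, seed: int, n_boot: int = 1000
) -> float:
    """Nonparametric bootstrap SE of predicted R2 over (observed,
    predicted) pairs; 0 when all residuals are 0."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if np.allclose(obs, pred):
        return 0.0
    rng = np.random.default_rng(seed)
    n = len(obs)
    idx = rng.integers(0, n, size=(n_boot, n))
    o = obs[idx]
    p = pred[idx]
    sst = np.sum((o - o.mean(axis=1, keepdims=True)) ** 2, axis=1)
    sse = np.sum((o - p) ** 2, axis=1)
    valid = sst > 0
    if valid.sum() < 2:
        return 0.0
    r2 = 1.0 - sse[valid] / sst[valid]
    return float(np.std(r2, ddof=1))


def select_one_se(
    results: list[EvalResult], seed: int = 0, max_models: int = 5
) -> list[EvalResult]:
    """1-SE rule for one outcome: keep at most ``max_models`` results
    whose validation R2 is within one bootstrap SE of the best one.

    Ties are broken by simpler model kind, then lexical config order.
    Returns an empty list (with a warning log) when everything is
    inoperable.
    """
    operable = [r for r in results if r.status == "ok" and r.r2_validation is not None]
    if not operable:
        log.warning("1-SE selection: no operable results")
        return []
    outcomes = {r.config.outcome for r in operable}
    if len(outcomes) > 1:
        raise ValueError("select_one_se expects results for a single outcome")
    best = max(operable, key=lambda r: r.r2_validation)
    se = bootstrap_r2_se(best._val_obs, best._val_pred, seed=seed)
    cutoff = best.r2_validation - se
    candidates = [r for r in operable if r.r2_validation >= cutoff]
    candidates.sort(
        key=lambda r: (
            -r.r2_validation,
            MODEL_SIMPLICITY.index(r.config.model),
            r.config.key,
        )
    )
    return candidates[:max_models]


def evaluate_selected(selected: list[EvalResult]) -> pd.DataFrame:
    """Score the selected models on the test set (the fits were trained
    on the training set only) and return the final table."""
    rows = []
    for r in selected:
        if r._fit is None or r._test_rows is None:
            continue
        test = r._test_rows
        obs = test[r.config.outcome].to_numpy(dtype=float)
        try:
            r.r2_test = mdl.predicted_r2(obs, r._fit.predict(test))
        except ValueError:
            r.r2_test = None
        rows.append({
            **_config_dict(r.config),
            "r2_train": r.r2_train,
            "r2_validation": r.r2_validation,
            "r2_test": r.r2_test,
            "slope": r.slope,
            "slope_ci_low": r.slope_ci[0] if r.slope_ci else None,
            "slope_ci_high": r.slope_ci[1] if r.slope_ci else None,
            "n_test": r.n_test,
        })
    return pd.DataFrame(rows)


def _config_dict(config: MultiverseConfig) -> dict:
    return {
        "sensor": config.sensor,
        "feature": config.feature,
        "outcome": config.outcome,
        "model": config.model,
        "outlier": config.outlier,
        "k": config.k,
    }


def results_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Flat results table: one row per configuration."""
    return pd.DataFrame([
        {
            **_config_dict(r.config),
            "status": r.status,
            "reason": r.reason,
            "r2_train": r.r2_train,
            "r2_validation": r.r2_validation,
            "r2_test": r.r2_test,
            "slope": r.slope,
            "n_train": r.n_train,
            "n_validation": r.n_validation,
            "n_test": r.n_test,
        }
        for r in results
    ])


def run_workflow(
    configs: list[MultiverseConfig], data: MultiverseData, seed: int = 0
) -> tuple[list[EvalResult], dict, pd.DataFrame]:
    """Full 5-step workflow: sweep, per-outcome 1-SE selection, test-set
    evaluation of the selected models only."""
    results = run_multiverse(configs, data, seed=seed)
    selections = {}
    finals = []
    for outcome in sorted({c.outcome for c in configs}):
        subset = [r for r in results if r.config.outcome == outcome]
        selected = select_one_se(subset, seed=seed)
        selections[outcome] = selected
        finals.append(evaluate_selected(selected))
    final = pd.concat([f for f in finals if not f.empty], ignore_index=True) \
        if any(not f.empty for f in finals) else pd.DataFrame()
    return results, selections, final
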