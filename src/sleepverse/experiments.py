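"""Seeded validation experiments run by the acceptance suite and the
acceptance report script.

Three experiments against synthetic ground truth:

* slope recovery — the mixed model on true night features recovers a
  known generating coefficient within 2 standard errors;
* end-to-end selection — with signal planted only on the sleep-duration
  feature, the hold-out 1-SE selection for morning sleep quality picks
  configurations carrying that feature;
* null calibration — with all effect sizes zero, selected models earn
  no positive test-set predicted R2 on median.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from datetime import timedelta

import numpy as np
import pandas as pd

from sleepverse import models as mdl
from sleepverse import multiverse as mv
from sleepverse.synthetic import (
    SimulationParams,
    simulate_dataset,
    simulate_outcomes,
    simulate_schedules,
    true_feature_table,
)

TRUE_SLOPE = 4.0


def _recovery_params(seed: int, n_participants: int, n_days: int,
                     slope: float) -> SimulationParams:
    return SimulationParams(
        n_participants=n_participants,
        n_days=n_days,
        seed=seed,
        effect_sizes={"ssq": {"sleep_time": slope}},
        noise_sd={"ssq": 8.0, "na": 8.0, "depression": 8.0},
        participant_intercept_sd=5.0,
        missing_ssq_prob=0.0,
    )


def slope_recovery_trial(seed: int, n_participants: int = 50, n_days: int = 14,
                         slope: float = TRUE_SLOPE) -> bool:
    """One replicate: simulate outcomes from true features with a known
    coefficient, refit the mixed model on the true features, and check
    that the estimate lies within 2 SE of the truth (on the fit's
    standardized scale)."""
    params = _recovery_params(seed, n_participants, n_days, slope)
    schedules = simulate_schedules(params)
    outcomes = simulate_outcomes(schedules, params)
    truth = true_feature_table(schedules)
    truth["date"] = truth["night_date"].map(lambda d: d + timedelta(days=1))
    frame = truth.merge(outcomes.daily, on=["participant_id", "date"]).dropna(
        subset=["ssq"])
    fit = mdl.fit("mixed_effects", frame, "sleep_time", "ssq")
    if fit.status != "ok" or fit.slope_se is None:
        return False
    target = slope * fit._x_sd  # true coefficient on the standardized scale
    return abs(fit.slope - target) <= 2 * fit.slope_se


def slope_recovery_rate(n_replicates: int = 100, base_seed: int = 0,
                        n_participants: int = 50, n_days: int = 14) -> float:
    """Fraction of replicates recovering the coefficient within 2 SE."""
    hits = sum(
        slope_recovery_trial(base_seed * 10_000 + i, n_participants, n_days)
        for i in range(n_replicates)
    )
    return hits / n_replicates


def reduced_grid() -> list[mv.MultiverseConfig]:
    """~500-configuration sweep: all 10 sensors, all 7 features and all
    3 adjacency thresholds, mixed models only, two outlier methods, the
    morning-sleep-quality outcome."""
    return mv.enumerate_grid(
        outcomes=("ssq",),
        model_kinds=("mixed_effects",),
        outlier_kinds=("none", "median_3mad"),
    )


def _sweep_params(seed: int, n_participants: int, effect: float | None,
                  intercept_sd: float = 5.0) -> SimulationParams:
    effect_sizes = {"ssq": {"sleep_time": effect}} if effect else {}
    return SimulationParams(
        n_participants=n_participants,
        n_days=14,
        seed=seed,
        effect_sizes=effect_sizes,
        noise_sd={"ssq": 6.0, "na": 8.0, "depression": 8.0},
        participant_intercept_sd=intercept_sd,
        sensor_flip_prob=0.01,
        interruption_rate=2.0,
        missing_ssq_prob=0.05,
    )


def end_to_end_selection_trial(seed: int, n_participants: int = 12,
                               effect: float = 6.0) -> bool:
    """One seed of the end-to-end experiment: does the 1-SE selection
    for the morning-sleep-quality outcome contain a configuration whose
    feature is the sleep duration the signal was planted on?"""
    params = _sweep_params(seed, n_participants, effect)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, events, outcomes = simulate_dataset(params)
        data = mv.prepare_data(events, outcomes)
        results = mv.run_multiverse(reduced_grid(), data, seed=seed)
        selected = mv.select_one_se(results, seed=seed)
    return any(r.config.feature == "sleep_time" for r in selected)


def null_calibration_trial(seed: int, n_participants: int = 10) -> list[float]:
    """One seed of the null experiment: test-set predicted R2 of every
    selected model when no outcome carries any signal.

    Pure noise requires zero feature effects AND zero between-person
    intercept spread; otherwise the mixed model's random intercepts
    legitimately transfer person-level information to the test days.
    """
    params = _sweep_params(seed, n_participants, effect=None, intercept_sd=0.0)
    configs = mv.enumerate_grid(
        sensors=["charging", "accelerometer_0.5"],
        outcomes=("ssq",),
        model_kinds=("mixed_effects",),
        outlier_kinds=("none",),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, events, outcomes = simulate_dataset(params)
        data = mv.prepare_data(events, outcomes)
        results = mv.run_multiverse(configs, data, seed=seed)
        selected = mv.select_one_se(results, seed=seed)
        final = mv.evaluate_selected(selected)
    if final.empty:
        return []
    return [float(v) for v in final["r2_test"].dropna()]


def null_calibration_median(n_seeds: int = 20, base_seed: int = 0,
                            n_participants: int = 10) -> float:
    """Pooled median test R2 of selected models over null-signal seeds."""
    values: list[float] = []
    for i in range(n_seeds):
        values.extend(null_calibration_trial(base_seed * 10_000 + i,
                                             n_participants))
    return float(np.median(values)) if values else np.nan
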