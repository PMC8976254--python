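"""Outlier-removal strategies applied to feature values before modelling.

Four methods: keep everything, median +/- 3 SD per participant,
median +/- 3 MAD per participant (MAD unscaled), and a pooled
multivariate isolation forest over all feature columns jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from sleepverse.features import FEATURES

OUTLIER_KINDS = ("none", "median_3sd", "median_3mad", "isolation_forest")


@dataclass(frozen=True)
class OutlierMethod:
    kind: str
    contamination: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.kind not in OUTLIER_KINDS:
            raise ValueError(f"kind must be one of {OUTLIER_KINDS}")
        if not 0 < self.contamination < 0.5:
            raise ValueError("contamination must be in (0, 0.5)")


def _median_rule(values: np.ndarray, scale_fn) -> np.ndarray:
    """Keep mask for |x - median| <= 3 * scale; NaNs are kept (they are
    missing, not outlying)."""
    keep = np.ones(len(values), dtype=bool)
    finite = ~np.isnan(values)
    if finite.sum() < 3:
        return keep  # dispersion undefined; handled by caller warning
    x = values[finite]
    med = np.median(x)
    scale = scale_fn(x, med)
    if scale == 0:
        warnings.warn(
            "zero dispersion under median-based outlier rule: only exact-median "
            "values are kept",
            stacklevel=3,
        )
    keep[finite] = np.abs(x - med) <= 3 * scale
    return keep


def _sd(x, med):
    return float(np.std(x, ddof=1))


def _mad(x, med):
    return float(np.median(np.abs(x - med)))


def remove_outliers(
    rows: pd.DataFrame, feature: str, method: OutlierMethod
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split ``rows`` into (kept, removed) for one feature column.

    Median-based rules are applied per participant on that feature;
    participants with fewer than 3 non-missing values are kept
    unfiltered with a warning. The isolation forest is fitted pooled
    over all available feature columns jointly; rows with incomplete
    feature vectors cannot be scored and are kept. Rows with a missing
    value in ``feature`` are always kept (missingness is handled at
    modelling time).
    """
    if method.kind == "none":
        return rows.copy(), rows.iloc[0:0].copy()

    if method.kind == "isolation_forest":
        cols = [c for c in FEATURES if c in rows.columns]
        X = rows[cols].to_numpy(dtype=float)
        complete = ~np.isnan(X).any(axis=1)
        keep = np.ones(len(rows), dtype=bool)
        if complete.sum() >= 2:
            forest = IsolationForest(
                contamination=method.contamination, random_state=method.seed
            )
            pred = forest.fit_predict(X[complete])
            keep[np.flatnonzero(complete)] = pred == 1
        return rows[keep].copy(), rows[~keep].copy()

    scale_fn = _sd if method.kind == "median_3sd" else _mad
    keep = np.ones(len(rows), dtype=bool)
    positions = {idx: i for i, idx in enumerate(rows.index)}
    for pid, grp in rows.groupby("participant_id", sort=False):
        values = grp[feature].to_numpy(dtype=float)
        if (~np.isnan(values)).sum() < 3:
            warnings.warn(
                f"participant {pid!r}: fewer than 3 values for {feature}; "
                "outlier rule not applied",
                stacklevel=2,
            )
            continue
        grp_keep = _median_rule(values, scale_fn)
        for idx, k in zip(grp.index, grp_keep):
            keep[positions[idx]] = k
    return rows[keep].copy(), rows[~keep].copy()
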