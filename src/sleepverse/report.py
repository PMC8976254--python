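"""Descriptive and inferential summaries of the sweep outputs.

Three reports: feature distributions across multiverse settings per
sensor (robustness to analysis choices, not between-person variance),
a correlation analysis (standardized fixed-effect coefficients from
random-intercept models for the daily variables, Pearson correlations
on participant means for depression, Benjamini-Hochberg corrected), and
predicted-R2 distributions grouped by model x sensor and model x
feature. All tables derive solely from sweep outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from sleepverse.features import FEATURES

DAILY_VARS = tuple(f for f in FEATURES) + ("ssq", "na")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped
    at 1); NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    adjusted = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = len(pm)
    if m == 0:
        return adjusted
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adjusted[mask] = out
    return adjusted


@dataclass
class CorrelationEntry:
    var_a: str
    var_b: str
    coefficient: float
    p_raw: float
    p_adjusted: float = np.nan
    source: str = "mixed model"  # mixed model | pearson


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _mixed_correlation(df: pd.DataFrame, a: str, b: str):
    """Standardized fixed-effect coefficient of b on a with a random
    intercept per participant; p-value from a likelihood-ratio test
    against the intercept-only mixed model."""
    sub = df[["participant_id", a, b]].dropna()
    if len(sub) < 5 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
        return None
    y = _standardize(sub[a].to_numpy(dtype=float))
    x = _standardize(sub[b].to_numpy(dtype=float))
    groups = sub["participant_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = MixedLM(y, sm.add_constant(x), groups=groups).fit(reml=False)
            null = MixedLM(y, np.ones((len(y), 1)), groups=groups).fit(reml=False)
        except (np.linalg.LinAlgError, ValueError):
            return None
    lr = 2.0 * (full.llf - null.llf)
    p = float(scipy.stats.chi2.sf(max(lr, 0.0), df=1))
    return float(full.params[1]), p


def correlation_analysis(
    feature_rows: pd.DataFrame,
    daily_outcomes: pd.DataFrame,
    person_outcomes: pd.DataFrame,
) -> pd.DataFrame:
    """Correlation table for one feature table (one sensor config, one
    k).

    ``feature_rows`` must already be joined with the daily outcomes
    (columns ``ssq``/``na`` present) or they are merged from
    ``daily_outcomes`` on participant and date. Pairs among the daily
    variables use mixed-model standardized coefficients; pairs with
    depression use Pearson correlations on participant means. One
    Benjamini-Hochberg family across all tested pairs.
    """
    df = feature_rows
    if "ssq" not in df.columns:
        df = df.copy()
        df["date"] = pd.to_datetime(df["night_date"]).map(
            lambda d: (d + pd.Timedelta(days=1)).date())
        df = df.merge(daily_outcomes, on=["participant_id", "date"], how="left")

    entries: list[CorrelationEntry] = []
    variables = [v for v in DAILY_VARS if v in df.columns]
    for a, b in combinations(variables, 2):
        res = _mixed_correlation(df, a, b)
        if res is None:
            continue
        entries.append(CorrelationEntry(a, b, res[0], res[1], source="mixed model"))

    means = df.groupby("participant_id")[variables].mean()
    means = means.merge(person_outcomes.set_index("participant_id")[["depression"]],
                        left_index=True, right_index=True, how="inner")
    for var in variables:
        sub = means[[var, "depression"]].dropna()
        if len(sub) < 3 or sub[var].nunique() < 2 or sub["depression"].nunique() < 2:
            continue
        r, p = scipy.stats.pearsonr(sub[var], sub["depression"])
        entries.append(CorrelationEntry(var, "depression", float(r), float(p),
                                        source="pearson"))

    table = pd.DataFrame([e.__dict__ for e in entries])
    if not table.empty:
        table["p_adjusted"] = bh_adjust(table["p_raw"].to_numpy())
        table["significant"] = table["p_adjusted"] < 0.05
    return table


def feature_distribution_summary(feature_tables: dict) -> pd.DataFrame:
    """Quartiles/whiskers of each feature's values across multiverse
    settings, per sensor.

    ``feature_tables`` maps (sensor label, k) to a feature table. The
    previous-day activity feature is excluded from the per-sensor
    breakdown because it does not vary with the sensor choice.
    """
    rows = []
    long = []
    for (sensor, k), table in feature_tables.items():
        for feature in FEATURES:
            if feature == "user_active" or feature not in table.columns:
                continue
            vals = table[feature].dropna()
            if len(vals):
                long.append(pd.DataFrame(
                    {"sensor": sensor, "feature": feature, "value": vals}))
    if not long:
        return pd.DataFrame()
    stacked = pd.concat(long, ignore_index=True)
    for (sensor, feature), grp in stacked.groupby(["sensor", "feature"]):
        v = grp["value"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        rows.append({
            "sensor": sensor, "feature": feature, "n": len(v),
            "q1": q1, "median": med, "q3": q3, "iqr": iqr,
            "whisker_low": float(v[v >= q1 - 1.5 * iqr].min()),
            "whisker_high": float(v[v <= q3 + 1.5 * iqr].max()),
        })
    return pd.DataFrame(rows)


def r2_distribution_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Train/validation R2 quartiles of operable results grouped by
    model x sensor and model x feature."""
    ok = results[results["status"] == "ok"]
    rows = []
    for group_col in ("sensor", "feature"):
        for (model, grp_val), grp in ok.groupby(["model", group_col]):
            entry = {"grouping": f"model x {group_col}", "model": model,
                     group_col: grp_val, "n": len(grp)}
            for col in ("r2_train", "r2_validation"):
                v = grp[col].dropna().to_numpy()
                if len(v):
                    q1, med, q3 = np.percentile(v, [25, 50, 75])
                else:
                    q1 = med = q3 = np.nan
                entry.update({f"{col}_q1": q1, f"{col}_median": med, f"{col}_q3": q3})
            rows.append(entry)
    return pd.DataFrame(rows)


def plot_r2_distributions(results: pd.DataFrame, outcome: str, path) -> None:
    """Boxplots of validation R2 by model kind, one panel per sensor."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = results[(results["status"] == "ok") & (results["outcome"] == outcome)]
    sensors = sorted(ok["sensor"].unique())
    models = sorted(ok["model"].unique())
    fig, axes = plt.subplots(
        len(sensors) or 1, 1, figsize=(8, 2 * max(len(sensors), 1)), squeeze=False)
    for ax, sensor in zip(axes[:, 0], sensors):
        data = [ok[(ok["sensor"] == sensor) & (ok["model"] == m)]
                ["r2_validation"].dropna() for m in models]
        ax.boxplot(data, tick_labels=models, orientation="horizontal")
        ax.set_title(sensor, fontsize=8)
        ax.axvline(0, color="grey", lw=0.5)
    fig.suptitle(f"Validation R2 by model, {outcome}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
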