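"""Participant- and sensor-level cleaning.

Order of operations for a raw event table:

1. :func:`drop_sparse_or_dead` — remove participant x sensor streams with
   fewer than 10 observations or stuck at zero (broken sensor).
2. :func:`drop_gap_outliers` — remove temporally isolated observations
   via a boxplot rule on each event's distance to its nearest neighbour.
3. :func:`center_accelerometer` — per-participant centering followed by
   absolute value (the accelerometers are uncalibrated).
4. :func:`filter_screen_flashes` — collapse duplicate screen states and
   drop on/off interactions shorter than 12 seconds (notification
   flashes).

:func:`classify_events` then turns one cleaned stream into per-instant
sleep/wake labels for one :class:`SensorConfig`. Every exclusion is
reported, never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ACCEL_THRESHOLDS = (0.25, 0.5, 1.0)  # m/s^2
LIGHT_THRESHOLDS = (8.0, 12.0, 16.0)  # lux
MIN_OBSERVATIONS = 10
FLASH_SECONDS = 12.0


@dataclass(frozen=True)
class SensorConfig:
    """One sleep-indication rule: a sensor plus (for accelerometer and
    light) its threshold."""

    sensor: str
    threshold: float | None = None

    def __post_init__(self):
        if self.sensor == "accelerometer" and self.threshold not in ACCEL_THRESHOLDS:
            raise ValueError(f"accelerometer threshold must be one of {ACCEL_THRESHOLDS}")
        if self.sensor == "light" and self.threshold not in LIGHT_THRESHOLDS:
            raise ValueError(f"light threshold must be one of {LIGHT_THRESHOLDS}")
        if self.sensor not in ("accelerometer", "light") and self.threshold is not None:
            raise ValueError(f"{self.sensor} takes no threshold")

    @property
    def label(self) -> str:
        if self.threshold is None:
            return self.sensor
        return f"{self.sensor}_{self.threshold:g}"


def default_sensor_configs() -> list[SensorConfig]:
    """The ten sensor configurations: three accelerometer thresholds,
    three light thresholds, and one rule each for charging, activity,
    screen and Wi-Fi."""
    configs = [SensorConfig("accelerometer", t) for t in ACCEL_THRESHOLDS]
    configs += [SensorConfig("light", t) for t in LIGHT_THRESHOLDS]
    configs += [SensorConfig(s) for s in ("charging", "activity", "screen", "wifi")]
    return configs


def _is_all_zero(sensor: str, values: pd.Series) -> bool:
    if sensor in ("accelerometer", "light"):
        return bool((values.astype(float) == 0).all())
    if sensor in ("charging", "wifi"):
        return bool((~values.astype(bool)).all())
    if sensor == "screen":
        return bool((values == "off").all())
    return False  # activity labels have no zero analogue


def drop_sparse_or_dead(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove participant x sensor streams with <10 observations
    ("sparse") or all-zero values ("dead sensor").

    Returns the retained events and an exclusion report with columns
    ``participant_id, sensor, rule, detail``.
    """
    keep_mask = np.ones(len(events), dtype=bool)
    report = []
    for (pid, sensor), grp in events.groupby(["participant_id", "sensor"], sort=False):
        if len(grp) < MIN_OBSERVATIONS:
            keep_mask[events.index.get_indexer(grp.index)] = False
            report.append((pid, sensor, "sparse", f"{len(grp)} observations"))
        elif _is_all_zero(sensor, grp["value"]):
            keep_mask[events.index.get_indexer(grp.index)] = False
            report.append((pid, sensor, "dead sensor", "all values zero"))
    report = pd.DataFrame(report, columns=["participant_id", "sensor", "rule", "detail"])
    return events[keep_mask].reset_index(drop=True), report


def drop_gap_outliers(events: pd.DataFrame) -> pd.DataFrame:
    """Remove temporally isolated events.

    For each event the gap is the minimum of the distances to its
    previous and next neighbour within the participant x sensor stream;
    events whose gap exceeds Q3 + 1.5 IQR of the stream's gaps are
    dropped. Streams with fewer than 4 events (quartiles undefined) pass
    through unchanged with a warning.
    """
    kept = []
    for (pid, sensor), grp in events.groupby(["participant_id", "sensor"], sort=False):
        if len(grp) < 4:
            warnings.warn(
                f"gap-outlier rule skipped for {pid}/{sensor}: fewer than 4 events",
                stacklevel=2,
            )
            kept.append(grp)
            continue
        ts = grp["timestamp"].to_numpy()
        diffs = np.diff(ts).astype("timedelta64[s]").astype(float)
        prev_gap = np.concatenate([[np.inf], diffs])
        next_gap = np.concatenate([diffs, [np.inf]])
        gap = np.minimum(prev_gap, next_gap)
        q1, q3 = np.percentile(gap, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        kept.append(grp[gap <= fence])
    if not kept:
        return events.copy()
    return pd.concat(kept).sort_values(
        ["participant_id", "sensor", "timestamp"], kind="stable"
    ).reset_index(drop=True)


def center_accelerometer(events: pd.DataFrame) -> pd.DataFrame:
    """Per participant, replace accelerometer values by the absolute
    deviation from the participant's mean. Idempotent only up to the
    first application's sign removal; re-centering an already centered
    stream whose mean is zero leaves it unchanged."""
    out = events.copy()
    mask = out["sensor"] == "accelerometer"
    if not mask.any():
        return out
    acc = out.loc[mask, ["participant_id", "value"]].copy()
    acc["value"] = acc["value"].astype(float)
    centered = acc.groupby("participant_id")["value"].transform(lambda v: (v - v.mean()).abs())
    out.loc[mask, "value"] = centered
    return out


def _collapse_duplicates(grp: pd.DataFrame) -> pd.DataFrame:
    states = grp["value"].to_numpy()
    keep = np.ones(len(grp), dtype=bool)
    keep[1:] = states[1:] != states[:-1]
    return grp[keep]


def filter_screen_flashes(events: pd.DataFrame) -> pd.DataFrame:
    """Clean screen on/off streams: collapse runs of duplicate states to
    their first event, then remove on->off pairs shorter than 12 s
    (notification flashes), re-collapsing afterwards so the operation is
    idempotent. A stream starting with "off" keeps its leading off as a
    state anchor."""
    mask = events["sensor"] == "screen"
    if not mask.any():
        return events.copy()
    screen = events[mask]
    others = events[~mask]
    cleaned = []
    for _, grp in screen.groupby("participant_id", sort=False):
        grp = _collapse_duplicates(grp)
        states = grp["value"].to_numpy()
        ts = grp["timestamp"].to_numpy()
        keep = np.ones(len(grp), dtype=bool)
        for i in range(len(grp) - 1):
            if states[i] == "on" and states[i + 1] == "off":
                dur = (ts[i + 1] - ts[i]) / np.timedelta64(1, "s")
                if dur < FLASH_SECONDS:
                    keep[i] = keep[i + 1] = False
        grp = _collapse_duplicates(grp[keep])
        cleaned.append(grp)
    out = pd.concat([others] + cleaned) if cleaned else others
    return out.sort_values(
        ["participant_id", "sensor", "timestamp"], kind="stable"
    ).reset_index(drop=True)


def clean_events(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cleaning chain; returns (cleaned events, exclusion report)."""
    events, report = drop_sparse_or_dead(events)
    events = drop_gap_outliers(events)
    events = center_accelerometer(events)
    events = filter_screen_flashes(events)
    return events, report


def classify_instant(config: SensorConfig, value) -> bool:
    """Apply one sensor's sleep-indication rule to a single value;
    True means sleeping. Thresholded rules use strict less-than."""
    if config.sensor == "accelerometer":
        return abs(float(value)) < config.threshold
    if config.sensor == "light":
        return float(value) < config.threshold
    if config.sensor == "charging":
        return bool(value)
    if config.sensor == "activity":
        return value == "Still"
    if config.sensor == "screen":
        return value == "off"
    if config.sensor == "wifi":
        return bool(value)
    raise ValueError(f"unknown sensor {config.sensor!r}")


def classify_events(events: pd.DataFrame, config: SensorConfig) -> pd.DataFrame:
    """Vectorized :func:`classify_instant` over the rows of ``events``
    matching the config's sensor; adds a boolean ``sleeping`` column."""
    sub = events[events["sensor"] == config.sensor].copy()
    if config.sensor == "accelerometer":
        sub["sleeping"] = sub["value"].astype(float).abs() < config.threshold
    elif config.sensor == "light":
        sub["sleeping"] = sub["value"].astype(float) < config.threshold
    elif config.sensor in ("charging", "wifi"):
        sub["sleeping"] = sub["value"].astype(bool)
    elif config.sensor == "activity":
        sub["sleeping"] = sub["value"] == "Still"
    elif config.sensor == "screen":
        sub["sleeping"] = sub["value"] == "off"
    else:
        raise ValueError(f"unknown sensor {config.sensor!r}")
    return sub
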