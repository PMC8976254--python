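"""Reading and writing the long-format sensor-event and outcome CSVs.

All tables are UTF-8 CSVs with fixed column names; missing values are
empty cells. Rows whose values violate a sensor's domain are collected
into a reject report rather than silently dropped; structural problems
(unknown sensor kind, unparseable timestamp) raise :class:`FormatError`
with a line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sleepverse.errors import FormatError

SENSOR_KINDS = ("accelerometer", "charging", "light", "activity", "screen", "wifi")
ACTIVITY_LABELS = ("Still", "Walking", "Cycling", "Other")
BOOL_VALUES = {"true": True, "false": False}
SCREEN_VALUES = ("on", "off")

EVENT_COLUMNS = ["participant_id", "timestamp", "sensor", "value"]


def _check_value(sensor: str, raw: str):
    """Return (ok, parsed-or-reason) for one raw value string."""
    if sensor in ("accelerometer", "light"):
        try:
            v = float(raw)
        except ValueError:
            return False, f"non-numeric value {raw!r}"
        if sensor == "light" and v < 0:
            return False, "negative lux"
        return True, v
    if sensor in ("charging", "wifi"):
        key = raw.strip().lower()
        if key not in BOOL_VALUES:
            return False, f"non-boolean value {raw!r}"
        return True, BOOL_VALUES[key]
    if sensor == "screen":
        key = raw.strip().lower()
        if key not in SCREEN_VALUES:
            return False, f"invalid screen state {raw!r}"
        return True, key
    if sensor == "activity":
        if raw not in ACTIVITY_LABELS:
            return False, f"unknown activity label {raw!r}"
        return True, raw
    raise AssertionError(sensor)


def read_events(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a sensor-event CSV.

    Returns ``(events, rejects)``. ``events`` has columns
    ``participant_id, timestamp, sensor, value`` sorted by
    participant, sensor and timestamp, with ``value`` parsed
    per sensor (float, bool, ``"on"/"off"`` or an activity label).
    ``rejects`` lists each domain-violating row with its line number
    and reason so that accepted + rejected = input rows.

    Raises
    ------
    FormatError
        On an unknown sensor kind or unparseable timestamp (with the
        offending line number), or a missing/invalid header.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != EVENT_COLUMNS:
        raise FormatError(f"expected header {EVENT_COLUMNS}, got {list(raw.columns)}")
    records, rejects = [], []
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # header is line 1
        sensor = row.sensor
        if sensor not in SENSOR_KINDS:
            raise FormatError(f"unknown sensor kind {sensor!r}", line=line)
        try:
            ts = pd.Timestamp(row.timestamp)
        except (ValueError, TypeError):
            raise FormatError(f"unparseable timestamp {row.timestamp!r}", line=line) from None
        if pd.isna(ts):
            raise FormatError(f"unparseable timestamp {row.timestamp!r}", line=line)
        ok, parsed = _check_value(sensor, row.value)
        if not ok:
            rejects.append((line, row.participant_id, row.timestamp, sensor, row.value, parsed))
            continue
        records.append((row.participant_id, ts, sensor, parsed))
    events = pd.DataFrame(records, columns=EVENT_COLUMNS)
    rejects = pd.DataFrame(
        rejects, columns=["line", "participant_id", "timestamp", "sensor", "value", "reason"]
    )
    if len(events):
        events = events.sort_values(
            ["participant_id", "sensor", "timestamp"], kind="stable"
        ).reset_index(drop=True)
    return events, rejects


def _format_value(sensor: str, value) -> str:
    if sensor in ("charging", "wifi"):
        return "true" if value else "false"
    if sensor in ("accelerometer", "light"):
        return repr(float(value))
    return str(value)


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["value"] = [_format_value(s, v) for s, v in zip(out["sensor"], out["value"])]
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[EVENT_COLUMNS].to_csv(path, index=False)


@dataclass
class OutcomeTable:
    """Daily self-report outcomes plus one person-level record each.

    ``daily`` has columns ``participant_id, date, ssq, na`` (0-100 or
    NaN); ``person`` has ``participant_id, depression, gender`` with at
    most one depression value per participant.
    """

    daily: pd.DataFrame
    person: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        counts = self.person.groupby("participant_id")["depression"].count()
        if (counts > 1).any():
            bad = counts[counts > 1].index[0]
            raise FormatError(f"participant {bad!r} has more than one depression value")


OUTCOME_COLUMNS = ["participant_id", "date", "ssq", "na", "depression", "gender"]


def read_outcomes(path) -> OutcomeTable:
    """Load an outcome CSV with columns ``participant_id, date, ssq, na,
    depression, gender``.

    SSQ/NA/depression values outside [0, 100] are rejected into the
    table's reject report; a participant with two non-missing depression
    rows raises :class:`FormatError`.
    """
    raw = pd.read_csv(path, dtype={"participant_id": str})
    if list(raw.columns) != OUTCOME_COLUMNS:
        raise FormatError(f"expected header {OUTCOME_COLUMNS}, got {list(raw.columns)}")
    raw["date"] = pd.to_datetime(raw["date"]).dt.date

    rejects = []
    for col in ("ssq", "na", "depression"):
        vals = raw[col]
        bad = vals.notna() & ((vals < 0) | (vals > 100))
        for idx in raw.index[bad]:
            rejects.append((idx + 2, raw.at[idx, "participant_id"], col, raw.at[idx, col]))
            raw.at[idx, col] = np.nan
    rejects = pd.DataFrame(rejects, columns=["line", "participant_id", "column", "value"])

    daily = raw[["participant_id", "date", "ssq", "na"]].copy()
    person_rows = raw[raw["depression"].notna() | raw["gender"].notna()]
    dep_counts = person_rows.groupby("participant_id")["depression"].count()
    if (dep_counts > 1).any():
        bad = dep_counts[dep_counts > 1].index[0]
        raise FormatError(f"participant {bad!r} has more than one depression value")
    person = (
        person_rows.groupby("participant_id", as_index=False)
        .agg(depression=("depression", "first"), gender=("gender", "first"))
    )
    return OutcomeTable(daily=daily, person=person, rejects=rejects)


def write_outcomes(table: OutcomeTable, path) -> None:
    daily = table.daily.sort_values(["participant_id", "date"]).reset_index(drop=True)
    out = daily.copy()
    out["depression"] = np.nan
    out["gender"] = None
    person = table.person.set_index("participant_id")
    first = out.groupby("participant_id").head(1).index
    for idx in first:
        pid = out.at[idx, "participant_id"]
        if pid in person.index:
            out.at[idx, "depression"] = person.at[pid, "depression"]
            out.at[idx, "gender"] = person.at[pid, "gender"]
    out[OUTCOME_COLUMNS].to_csv(path, index=False)
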