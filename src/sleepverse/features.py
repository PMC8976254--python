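"""Per-night sleep features derived from a carried-forward night grid.

Seven features per participant-night: bed/wake-derived ``sleep_time``
(hours between the BedTime and WakeUpTime windows), deviations of the
recentred bed and wake clock hours from the participant's average
(``dev_avg_bed_time``, ``dev_avg_wake_up_time``), the number and total
duration of nightly interruptions, ``total_sleep`` (all sleeping windows
over the whole night) and ``user_active`` (minutes spent walking or
cycling the previous day).

Clock hours are recentred so that 10 PM = 0, 11 PM = 1, ..., 10 AM = 12.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd

from sleepverse.windows import AWAKE, MISSING, N_WINDOWS, SLEEP, NightGrid

FEATURES = (
    "dev_avg_bed_time",
    "dev_avg_wake_up_time",
    "interruptions_duration",
    "n_interruptions",
    "sleep_time",
    "total_sleep",
    "user_active",
)

K_VALUES = (3, 4, 5)

ACTIVE_LABELS = ("Walking", "Cycling")

_HOURS_PER_WINDOW = 5 / 60.0


def detect_bed_time(grid: NightGrid, k: int) -> int | None:
    """First window starting a run of >= k consecutive sleeping windows,
    or None when no such run exists."""
    if k not in K_VALUES:
        raise ValueError(f"k must be one of {K_VALUES}")
    states = grid.states
    run = 0
    for i in range(N_WINDOWS):
        if states[i] == SLEEP:
            run += 1
            if run == k:
                return i - k + 1
        else:
            run = 0
    return None


def detect_wake_up_time(grid: NightGrid, k: int, bed: int) -> int | None:
    """Start of the terminal awake run when it spans >= k windows and
    begins after ``bed``; None otherwise (e.g. still asleep at 10 AM).

    Awake runs in the middle of the night are interruptions, not
    wake-ups; only a run extending to the end of the night counts.
    """
    if bed is None:
        raise ValueError("detect_wake_up_time requires a detected bed window")
    states = grid.states
    if states[-1] != AWAKE:
        return None
    w = N_WINDOWS - 1
    while w > 0 and states[w - 1] == AWAKE:
        w -= 1
    if N_WINDOWS - w >= k and w > bed:
        return w
    return None


def window_to_recentred_hours(window: int) -> float:
    """Recentred clock hour of a window's left edge (10 PM = 0)."""
    return window * _HOURS_PER_WINDOW


def compute_night_features(grid: NightGrid, k: int) -> dict:
    """All grid-derived features for one night.

    With bed and wake detected: ``sleep_time`` is the span between them
    in hours; interruptions are the maximal awake runs strictly inside
    that span, their total duration in minutes (5 min per window).
    ``total_sleep`` counts every sleeping window of the night regardless
    of bed/wake. When bed or wake is missing, the bed/wake-derived
    features are missing but ``total_sleep`` is still reported.
    """
    states = grid.states
    bed = detect_bed_time(grid, k)
    wake = detect_wake_up_time(grid, k, bed) if bed is not None else None
    total_sleep = float(np.count_nonzero(states == SLEEP)) * _HOURS_PER_WINDOW

    row = {
        "participant_id": grid.participant_id,
        "night_date": grid.night_date,
        "k": k,
        "bed_window": bed,
        "wake_window": wake,
        "bed_hours": np.nan,
        "wake_hours": np.nan,
        "sleep_time": np.nan,
        "n_interruptions": np.nan,
        "interruptions_duration": np.nan,
        "total_sleep": total_sleep,
    }
    if bed is None or wake is None:
        return row

    span = states[bed:wake]
    awake_in_span = span == AWAKE
    n_awake = int(np.count_nonzero(awake_in_span))
    # maximal awake runs strictly inside (bed, wake): span starts and
    # ends with sleep by construction, so counting run starts suffices
    starts = np.flatnonzero(awake_in_span & ~np.concatenate([[False], awake_in_span[:-1]]))
    row.update(
        bed_hours=window_to_recentred_hours(bed),
        wake_hours=window_to_recentred_hours(wake),
        sleep_time=(wake - bed) * _HOURS_PER_WINDOW,
        n_interruptions=float(len(starts)),
        interruptions_duration=float(n_awake * 5),
    )
    return row


def deviation_features(rows: pd.DataFrame) -> pd.DataFrame:
    """Add ``dev_avg_bed_time`` / ``dev_avg_wake_up_time``: each night's
    recentred bed/wake hour minus the participant's mean over all nights
    with that feature available. Signed, in hours."""
    out = rows.copy()
    for src, dst in (("bed_hours", "dev_avg_bed_time"), ("wake_hours", "dev_avg_wake_up_time")):
        means = out.groupby("participant_id")[src].transform("mean")
        out[dst] = out[src] - means
    return out


def compute_user_active(activity_events: pd.DataFrame, participant_id: str, day: date) -> float:
    """Minutes spent walking or cycling on ``day``.

    The activity stream is a state machine: an active episode runs from
    a Walking/Cycling label to the next label with a non-active state,
    so contiguous Walking/Cycling labels merge into one episode. Returns
    NaN when the participant has no activity data on that day, and 0.0
    when labels exist but none are active.
    """
    sub = activity_events[
        (activity_events["participant_id"] == participant_id)
        & (activity_events["sensor"] == "activity")
    ]
    if len(sub) == 0:
        return np.nan
    day_start = pd.Timestamp(day)
    day_end = day_start + pd.Timedelta(days=1)
    sub = sub[(sub["timestamp"] >= day_start) & (sub["timestamp"] < day_end)]
    if len(sub) == 0:
        return np.nan
    labels = sub["value"].to_numpy()
    ts = sub["timestamp"].to_numpy()
    active = np.isin(labels, ACTIVE_LABELS)
    total = 0.0
    start = None
    for i in range(len(labels)):
        if active[i] and start is None:
            start = ts[i]
        elif not active[i] and start is not None:
            total += (ts[i] - start) / np.timedelta64(1, "m")
            start = None
    # an episode still open at the last label has no observed end -> dropped
    return float(total)


def user_active_table(activity_events: pd.DataFrame) -> pd.DataFrame:
    """Active minutes per participant x calendar day, computed once;
    days with activity data but no walking/cycling get 0, days without
    data are absent (missing)."""
    sub = activity_events[activity_events["sensor"] == "activity"]
    records = []
    for pid, grp in sub.groupby("participant_id", sort=True):
        for day, day_grp in grp.groupby(grp["timestamp"].dt.date):
            labels = day_grp["value"].to_numpy()
            ts = day_grp["timestamp"].to_numpy()
            active = np.isin(labels, ACTIVE_LABELS)
            total, start = 0.0, None
            for i in range(len(labels)):
                if active[i] and start is None:
                    start = ts[i]
                elif not active[i] and start is not None:
                    total += (ts[i] - start) / np.timedelta64(1, "m")
                    start = None
            records.append((pid, day, float(total)))
    return pd.DataFrame(records, columns=["participant_id", "day", "user_active"])


def compute_feature_table(
    grids: list[NightGrid],
    k: int,
    activity_events: pd.DataFrame | None = None,
    user_active: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One SleepFeatureRow per grid: night features, participant-mean
    deviations, and the previous day's active minutes. ``user_active``
    accepts a precomputed :func:`user_active_table` so the sweep does
    not recompute it per sensor config."""
    rows = pd.DataFrame([compute_night_features(g, k) for g in grids])
    if rows.empty:
        return rows
    rows = deviation_features(rows)
    if user_active is None and activity_events is not None:
        user_active = user_active_table(activity_events)
    if user_active is not None:
        rows = rows.merge(
            user_active,
            left_on=["participant_id", "night_date"],
            right_on=["participant_id", "day"],
            how="left",
        ).drop(columns=["day"])
    else:
        rows["user_active"] = np.nan
    return rows
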