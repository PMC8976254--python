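"""Synthetic sensor streams and outcomes with known ground truth.

Generates, per participant-night, a true sleep schedule (bed time, wake
time, nightly interruptions), then emits six sensor event streams whose
sleep-indication rules recover that schedule when noise is switched
off: accelerometer readings near a per-participant calibration offset
during sleep, charging/Wi-Fi true during sleep, light below the night
lux level, activity "Still", and screen state transitions with optional
sub-12-second notification flashes. Outcomes (morning sleep quality,
daily negative affect, one depression score per participant) are linear
in the true night features with configurable effect sizes and noise.

Event times follow a renewal process with truncated-normal intervals so
that inter-arrival gaps within a stream's coverage never exceed the
configured maximum (15 minutes by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date, timedelta

import numpy as np
import pandas as pd

from sleepverse.errors import ConfigurationError
from sleepverse.features import FEATURES
from sleepverse.ingest import EVENT_COLUMNS, OutcomeTable

OUTCOMES = ("ssq", "na", "depression")

_NIGHT_LEN_H = 12.0


def _recentre(clock_hour: float) -> float:
    """Map a 24h clock hour to recentred night hours (10 PM = 0)."""
    return (clock_hour - 22.0) % 24.0


@dataclass(frozen=True)
class TrueSleepSchedule:
    """Ground truth for one participant-night.

    ``bed_hours``/``wake_hours`` are recentred night hours (10 PM = 0,
    10 AM = 12); ``interruptions`` is an ordered list of
    ``(start_hours, duration_minutes)`` pairs, non-overlapping and
    strictly inside the sleep interval. ``active_minutes`` is the true
    walking/cycling time during the day of ``night_date``.
    """

    participant_id: str
    night_date: date
    bed_hours: float
    wake_hours: float
    interruptions: tuple
    active_minutes: float

    def __post_init__(self):
        if not 0 <= self.bed_hours < _NIGHT_LEN_H:
            raise ValueError("bed time must lie in [10 PM, 10 AM)")
        if not self.bed_hours < self.wake_hours <= _NIGHT_LEN_H:
            raise ValueError("wake time must lie in (bed, 10 AM]")
        last_end = self.bed_hours
        for start, dur_min in self.interruptions:
            end = start + dur_min / 60.0
            if start <= last_end or end >= self.wake_hours:
                raise ValueError("interruptions must be ordered, non-overlapping "
                                 "and strictly inside the sleep interval")
            last_end = end

    @property
    def true_bed_time(self) -> pd.Timestamp:
        return pd.Timestamp(self.night_date) + pd.Timedelta(hours=22 + self.bed_hours)

    @property
    def true_wake_time(self) -> pd.Timestamp:
        return pd.Timestamp(self.night_date) + pd.Timedelta(hours=22 + self.wake_hours)

    def asleep(self, hours: np.ndarray) -> np.ndarray:
        """Vectorized truth: asleep at recentred hour(s) ``hours``."""
        h = np.asarray(hours, dtype=float)
        state = (h >= self.bed_hours) & (h < self.wake_hours)
        for start, dur_min in self.interruptions:
            state &= ~((h >= start) & (h < start + dur_min / 60.0))
        return state


@dataclass
class SimulationParams:
    """All knobs of the generator; defaults emulate a 2-week study with
    one reading every ~2.9 minutes (SD 6.72, gaps capped at 15 min)."""

    n_participants: int = 20
    n_days: int = 14
    start_date: date = date(2024, 3, 4)
    # event timing (minutes)
    mean_sampling_interval: float = 2.9
    sampling_interval_sd: float = 6.72
    max_gap_minutes: float = 15.0
    min_interval_minutes: float = 0.25
    # schedule distributions (24h clock hours / hours / per-night rates)
    bed_time_mean_hour: float = 23.5
    bed_time_sd_hours: float = 0.75
    wake_time_mean_hour: float = 7.5
    wake_time_sd_hours: float = 0.75
    interruption_rate: float = 1.0
    interruption_duration_mean_min: float = 20.0
    active_minutes_mean: float = 60.0
    active_minutes_sd: float = 20.0
    # sensor value models
    accel_offset_sd: float = 0.3
    accel_sleep_noise_sd: float = 0.05
    accel_wake_noise_sd: float = 1.0
    accel_wake_base: float = 2.0
    light_night_lux: float = 1.0
    light_day_lux: float = 150.0
    sensor_flip_prob: float = 0.02
    notification_flash_rate: float = 1.0
    # outcome models
    effect_sizes: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=lambda: {o: 10.0 for o in OUTCOMES})
    outcome_mean: dict = field(default_factory=lambda: {o: 50.0 for o in OUTCOMES})
    participant_intercept_sd: float = 10.0
    missing_ssq_prob: float = 0.1
    p_male: float = 0.3
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("sensor_flip_prob", "missing_ssq_prob", "p_male"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        for f in fields(self):
            if f.name.endswith(("_sd", "_sd_hours")):
                v = getattr(self, f.name)
                if isinstance(v, dict):
                    for key, sd in v.items():
                        if sd < 0:
                            raise ConfigurationError(f"{f.name}[{key!r}] must be >= 0")
                elif v < 0:
                    raise ConfigurationError(f"{f.name} must be >= 0")
        if self.n_days < 2:
            raise ConfigurationError("n_days must be >= 2")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.mean_sampling_interval <= 0:
            raise ConfigurationError("mean_sampling_interval must be > 0")
        if not 0 < self.min_interval_minutes < self.max_gap_minutes:
            raise ConfigurationError(
                "min_interval_minutes must lie in (0, max_gap_minutes)")
        for name in ("effect_sizes",):
            for outcome, coefs in getattr(self, name).items():
                if outcome not in OUTCOMES:
                    raise ConfigurationError(
                        f"effect_sizes: unknown outcome {outcome!r}")
                for feat in coefs:
                    if feat not in FEATURES:
                        raise ConfigurationError(
                            f"effect_sizes[{outcome!r}]: unknown feature {feat!r}")


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def participant_ids(params: SimulationParams) -> list[str]:
    return [f"p{i:03d}" for i in range(1, params.n_participants + 1)]


def simulate_schedules(params: SimulationParams) -> list[TrueSleepSchedule]:
    """One ground-truth schedule per participant-night, reproducible
    under the params' seed."""
    rng = _rng(params, 0)
    bed_mean = _recentre(params.bed_time_mean_hour)
    wake_mean = _recentre(params.wake_time_mean_hour)
    schedules = []
    for pid in participant_ids(params):
        for d in range(params.n_days):
            night = params.start_date + timedelta(days=d)
            bed = float(np.clip(rng.normal(bed_mean, params.bed_time_sd_hours),
                                0.0, _NIGHT_LEN_H - 0.25))
            wake = float(np.clip(rng.normal(wake_mean, params.wake_time_sd_hours),
                                 bed + 0.5, _NIGHT_LEN_H))
            n_int = rng.poisson(params.interruption_rate)
            interruptions = []
            last_end = bed
            if n_int > 0:
                starts = np.sort(rng.uniform(bed + 0.1, wake - 0.1, size=n_int))
                for s in starts:
                    dur = float(max(5.0, rng.exponential(
                        params.interruption_duration_mean_min)))
                    end = s + dur / 60.0
                    if s > last_end + 1 / 60.0 and end < wake - 1 / 60.0:
                        interruptions.append((float(s), dur))
                        last_end = end
            active = float(max(0.0, rng.normal(params.active_minutes_mean,
                                               params.active_minutes_sd)))
            schedules.append(TrueSleepSchedule(
                pid, night, bed, wake, tuple(interruptions), active))
    return schedules


def _renewal_hours(rng, start_h: float, end_h: float, params: SimulationParams) -> np.ndarray:
    """Event times (hours) on [start_h, end_h] from truncated-normal
    renewal intervals; gaps never exceed ``max_gap_minutes``."""
    span_min = (end_h - start_h) * 60.0
    n_guess = int(span_min / params.min_interval_minutes) + 8
    times, t = [], 0.0
    while t < span_min:
        draws = rng.normal(params.mean_sampling_interval,
                           params.sampling_interval_sd, size=64)
        draws = draws[(draws >= params.min_interval_minutes)
                      & (draws <= params.max_gap_minutes)]
        for dt in draws:
            t += dt
            if t >= span_min:
                break
            times.append(t)
        if len(times) > n_guess:  # safety, unreachable in practice
            break
    return start_h + np.asarray(times) / 60.0


def _night_ts(night: date, hours: np.ndarray) -> pd.DatetimeIndex:
    base = pd.Timestamp(night) + pd.Timedelta(hours=22)
    return base + pd.to_timedelta(np.round(hours * 3600.0), unit="s")


def simulate_sensor_streams(
    schedules: list[TrueSleepSchedule], params: SimulationParams
) -> pd.DataFrame:
    """Event table for all six sensors.

    Sampled sensors (accelerometer, light, charging, Wi-Fi, night-time
    activity) emit readings at renewal times across the night; each
    reading reflects the true sleep state and is flipped independently
    with ``sensor_flip_prob``. Daytime activity labels (walking/cycling
    episodes matching the schedule's true active minutes) cover 10 AM to
    10 PM. The screen stream consists of on/off state transitions at
    bed, wake and interruption boundaries plus Poisson-distributed
    notification flashes shorter than 12 seconds.
    """
    if not schedules:
        raise ValueError("simulate_sensor_streams requires at least one schedule")
    rng = _rng(params, 1)
    offsets = {pid: rng.normal(0.0, params.accel_offset_sd)
               for pid in sorted({s.participant_id for s in schedules})}

    recs: list[tuple] = []

    def flip(state: np.ndarray) -> np.ndarray:
        if params.sensor_flip_prob == 0:
            return state
        return state ^ (rng.random(len(state)) < params.sensor_flip_prob)

    for sched in schedules:
        pid, night = sched.participant_id, sched.night_date
        # --- sampled night streams ---
        for sensor in ("accelerometer", "light", "charging", "wifi", "activity"):
            hours = _renewal_hours(rng, 0.0, _NIGHT_LEN_H, params)
            if len(hours) == 0:
                continue
            state = flip(sched.asleep(hours))
            ts = _night_ts(night, hours)
            if sensor == "accelerometer":
                n = len(hours)
                sleep_vals = offsets[pid] + rng.normal(
                    0.0, params.accel_sleep_noise_sd, size=n)
                sign = rng.choice([-1.0, 1.0], size=n)
                wake_vals = offsets[pid] + sign * (
                    params.accel_wake_base
                    + np.abs(rng.normal(0.0, params.accel_wake_noise_sd, size=n)))
                vals = np.where(state, sleep_vals, wake_vals)
            elif sensor == "light":
                scale = rng.uniform(0.5, 1.5, size=len(hours))
                vals = np.where(state, params.light_night_lux * scale,
                                params.light_day_lux * scale)
            elif sensor in ("charging", "wifi"):
                vals = state
            else:  # activity at night: Still while asleep, Other while awake
                vals = np.where(state, "Still", "Other")
            recs.extend(zip([pid] * len(ts), ts, [sensor] * len(ts), vals))

        # --- daytime activity (10 AM - 10 PM of the night's date) ---
        day_hours = _renewal_hours(rng, 0.0, 12.0, params)  # offset from 10 AM
        if len(day_hours):
            ep_len_h = min(sched.active_minutes / 60.0, 10.0)
            ep_start = rng.uniform(0.5, max(0.51, 11.0 - ep_len_h))
            in_ep = (day_hours >= ep_start) & (day_hours < ep_start + ep_len_h)
            labels = np.where(
                in_ep,
                rng.choice(["Walking", "Cycling"], size=len(day_hours), p=[0.8, 0.2]),
                rng.choice(["Still", "Other"], size=len(day_hours), p=[0.6, 0.4]),
            )
            ts = (pd.Timestamp(night) + pd.Timedelta(hours=10)
                  + pd.to_timedelta(np.round(day_hours * 3600.0), unit="s"))
            recs.extend(zip([pid] * len(ts), ts, ["activity"] * len(ts), labels))

        # --- screen transitions ---
        trans = [(-(1 / 120.0), "on"), (sched.bed_hours, "off")]
        for start, dur_min in sched.interruptions:
            trans.append((start, "on"))
            trans.append((start + dur_min / 60.0, "off"))
        if sched.wake_hours < _NIGHT_LEN_H:
            trans.append((sched.wake_hours, "on"))
        n_flash = rng.poisson(params.notification_flash_rate)
        for _ in range(n_flash):
            t0 = rng.uniform(sched.bed_hours, sched.wake_hours - 0.01)
            if not sched.asleep(np.array([t0]))[0]:
                continue
            dur_s = rng.uniform(1.0, 10.5)  # stays < 12 s after rounding
            trans.append((t0, "on"))
            trans.append((t0 + dur_s / 3600.0, "off"))
        trans.sort()
        t_arr = np.array([t for t, _ in trans])
        v_arr = np.array([v for _, v in trans])
        if params.sensor_flip_prob > 0:
            flips = rng.random(len(v_arr)) < params.sensor_flip_prob
            v_arr = np.where(flips, np.where(v_arr == "on", "off", "on"), v_arr)
        ts = _night_ts(night, t_arr)
        recs.extend(zip([pid] * len(ts), ts, ["screen"] * len(ts), v_arr))

    events = pd.DataFrame(recs, columns=EVENT_COLUMNS)
    return events.sort_values(
        ["participant_id", "sensor", "timestamp"], kind="stable"
    ).reset_index(drop=True)


def true_feature_table(schedules: list[TrueSleepSchedule]) -> pd.DataFrame:
    """Ground-truth per-night values of the seven features."""
    rows = []
    for s in schedules:
        dur = sum(d for _, d in s.interruptions)
        sleep_time = s.wake_hours - s.bed_hours
        rows.append({
            "participant_id": s.participant_id,
            "night_date": s.night_date,
            "bed_hours": s.bed_hours,
            "wake_hours": s.wake_hours,
            "sleep_time": sleep_time,
            "n_interruptions": float(len(s.interruptions)),
            "interruptions_duration": float(dur),
            "total_sleep": sleep_time - dur / 60.0,
            "user_active": s.active_minutes,
        })
    df = pd.DataFrame(rows)
    for src, dst in (("bed_hours", "dev_avg_bed_time"),
                     ("wake_hours", "dev_avg_wake_up_time")):
        df[dst] = df[src] - df.groupby("participant_id")[src].transform("mean")
    return df


def simulate_outcomes(
    schedules: list[TrueSleepSchedule], params: SimulationParams
) -> OutcomeTable:
    """Outcome table linked to the true features.

    The night starting on date d pairs with day d+1's morning SSQ and
    day d+1's NA; depression is one value per participant, linear in the
    participant's mean true features. All outcomes are clipped to
    [0, 100]; the morning SSQ beep is missed with ``missing_ssq_prob``.
    """
    if not schedules:
        raise ValueError("simulate_outcomes requires at least one schedule")
    rng = _rng(params, 2)
    truth = true_feature_table(schedules)
    pids = sorted(truth["participant_id"].unique())
    intercepts = {
        o: {p: rng.normal(0.0, params.participant_intercept_sd) for p in pids}
        for o in ("ssq", "na")
    }

    def linear_term(outcome: str, row) -> float:
        total = 0.0
        for feat, coef in params.effect_sizes.get(outcome, {}).items():
            total += coef * row[feat]
        return total

    daily_rows = []
    for _, row in truth.iterrows():
        day = row["night_date"] + timedelta(days=1)
        vals = {}
        for o in ("ssq", "na"):
            v = (params.outcome_mean[o]
                 + intercepts[o][row["participant_id"]]
                 + linear_term(o, row)
                 + rng.normal(0.0, params.noise_sd[o]))
            vals[o] = float(np.clip(v, 0.0, 100.0))
        if rng.random() < params.missing_ssq_prob:
            vals["ssq"] = np.nan
        daily_rows.append((row["participant_id"], day, vals["ssq"], vals["na"]))
    daily = pd.DataFrame(daily_rows, columns=["participant_id", "date", "ssq", "na"])

    person_rows = []
    means = truth.groupby("participant_id").mean(numeric_only=True)
    for pid in pids:
        v = params.outcome_mean["depression"] + rng.normal(
            0.0, params.noise_sd["depression"])
        for feat, coef in params.effect_sizes.get("depression", {}).items():
            v += coef * means.loc[pid, feat]
        gender = "M" if rng.random() < params.p_male else "F"
        person_rows.append((pid, float(np.clip(v, 0.0, 100.0)), gender))
    person = pd.DataFrame(person_rows, columns=["participant_id", "depression", "gender"])
    return OutcomeTable(daily=daily, person=person)


def simulate_dataset(params: SimulationParams):
    """Convenience: (schedules, events, outcomes) under one seed."""
    schedules = simulate_schedules(params)
    events = simulate_sensor_streams(schedules, params)
    outcomes = simulate_outcomes(schedules, params)
    return schedules, events, outcomes
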