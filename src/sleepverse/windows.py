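"""Five-minute night grids: majority vote per window plus carry-forward.

A night runs from 10 PM to 10 AM the next morning and is divided into
144 half-open windows of 5 minutes; window 0 starts at 10 PM. Each
window holds the majority state of the observations falling inside it
(ties inherit the previous window's resolved state; a tie with no
resolved predecessor is missing). Windows without data are missing
until :func:`carry_forward` fills them from the last informative
window; leading missing windows stay missing.

Event-driven sensors (charging, screen, Wi-Fi) are state machines: when
no event falls inside a window, the state implied by the last event at
or before the window start contributes one implied observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from sleepverse.preprocess import SensorConfig, classify_events

N_WINDOWS = 144
WINDOW_MINUTES = 5
NIGHT_START_HOUR = 22
NIGHT_HOURS = 12

SLEEP, AWAKE, MISSING = np.int8(1), np.int8(0), np.int8(-1)
_TIE = np.int8(2)

STATE_MACHINE_SENSORS = ("charging", "screen", "wifi")

_NS_PER_WINDOW = WINDOW_MINUTES * 60 * 1_000_000_000
_NS_PER_NIGHT = N_WINDOWS * _NS_PER_WINDOW


@dataclass
class NightGrid:
    """The 144 window states of one participant-night under one sensor
    configuration; ``states`` entries are SLEEP (1), AWAKE (0) or
    MISSING (-1)."""

    participant_id: str
    night_date: date
    config: SensorConfig
    states: np.ndarray

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (N_WINDOWS,):
            raise ValueError(f"a night grid has exactly {N_WINDOWS} windows")

    @property
    def usable(self) -> bool:
        return bool((self.states != MISSING).any())


def night_start(night_date: date) -> pd.Timestamp:
    return pd.Timestamp(night_date) + pd.Timedelta(hours=NIGHT_START_HOUR)


def window_of(ts: pd.Timestamp, night_date: date) -> int:
    """Index of the 5-minute window containing ``ts``, or -1 if outside
    the night."""
    delta = pd.Timestamp(ts) - night_start(night_date)
    idx = int(delta.value // _NS_PER_WINDOW)
    return idx if 0 <= idx < N_WINDOWS else -1


def _resolve_ties(states: np.ndarray) -> np.ndarray:
    """Ties inherit the previous window's resolved state; a tie before
    any resolved window becomes missing."""
    out = states.copy()
    for i in np.flatnonzero(out == _TIE):
        out[i] = out[i - 1] if i > 0 else MISSING
    return out


def _vote_night(
    times_ns: np.ndarray,
    sleeping: np.ndarray,
    start_ns: int,
    state_machine: bool,
) -> np.ndarray:
    """Pre-fill one night's states from event votes (ties marked)."""
    lo = np.searchsorted(times_ns, start_ns, side="left")
    hi = np.searchsorted(times_ns, start_ns + _NS_PER_NIGHT, side="left")
    win = (times_ns[lo:hi] - start_ns) // _NS_PER_WINDOW
    slp = sleeping[lo:hi].astype(np.int64)
    n_obs = np.bincount(win, minlength=N_WINDOWS)
    n_slp = np.bincount(win, weights=slp, minlength=N_WINDOWS).astype(np.int64)

    states = np.full(N_WINDOWS, MISSING, dtype=np.int8)
    has = n_obs > 0
    states[has & (2 * n_slp > n_obs)] = SLEEP
    states[has & (2 * n_slp < n_obs)] = AWAKE
    states[has & (2 * n_slp == n_obs)] = _TIE

    if state_machine:
        empty = np.flatnonzero(~has)
        if len(empty):
            starts = start_ns + empty * _NS_PER_WINDOW
            idx = np.searchsorted(times_ns, starts, side="right") - 1
            valid = idx >= 0
            implied = np.where(sleeping[idx[valid]], SLEEP, AWAKE)
            states[empty[valid]] = implied
    return _resolve_ties(states)


def carry_forward(grid: NightGrid) -> NightGrid:
    """Fill missing windows with the previous window's state. Missing
    entries before the first informative window remain missing; an
    all-missing night is returned unchanged (unusable)."""
    states = grid.states.copy()
    informative = np.flatnonzero(states != MISSING)
    if len(informative):
        last = states[informative[0]]
        for i in range(informative[0] + 1, N_WINDOWS):
            if states[i] == MISSING:
                states[i] = last
            else:
                last = states[i]
    return NightGrid(grid.participant_id, grid.night_date, grid.config, states)


def build_grids(
    events: pd.DataFrame,
    config: SensorConfig,
    nights: dict[str, list[date]] | None = None,
    carry: bool = True,
) -> list[NightGrid]:
    """Build one grid per participant-night for one sensor config.

    ``events`` is a cleaned event table (all sensors; the config's
    sensor is selected internally). ``nights`` optionally fixes which
    nights to grid per participant; by default every night on which the
    participant has at least one in-night observation for this sensor
    is used.
    """
    classified = classify_events(events, config)
    state_machine = config.sensor in STATE_MACHINE_SENSORS
    grids: list[NightGrid] = []
    for pid, grp in classified.groupby("participant_id", sort=True):
        times_ns = grp["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        sleeping = grp["sleeping"].to_numpy(dtype=bool)
        if nights is None:
            shifted = times_ns - NIGHT_START_HOUR * 3_600_000_000_000
            in_night = (shifted % 86_400_000_000_000) < _NS_PER_NIGHT
            days = np.unique(shifted[in_night] // 86_400_000_000_000)
            pid_nights = [
                (pd.Timestamp(0) + pd.Timedelta(days=int(d))).date() for d in days
            ]
        else:
            pid_nights = nights.get(pid, [])
        for nd in pid_nights:
            start_ns = night_start(nd).value
            states = _vote_night(times_ns, sleeping, start_ns, state_machine)
            grid = NightGrid(pid, nd, config, states)
            grids.append(carry_forward(grid) if carry else grid)
    return grids


_STATE_CHARS = {int(SLEEP): "s", int(AWAKE): "a", int(MISSING): "m"}
_CHAR_STATES = {v: np.int8(k) for k, v in _STATE_CHARS.items()}


def grid_to_string(grid: NightGrid) -> str:
    return "".join(_STATE_CHARS[int(s)] for s in grid.states)


def grids_to_frame(grids: list[NightGrid]) -> pd.DataFrame:
    """Debug/fixture export: one row per grid with a 144-char state
    string (s=sleeping, a=awake, m=missing)."""
    return pd.DataFrame(
        {
            "participant_id": [g.participant_id for g in grids],
            "night_date": [g.night_date for g in grids],
            "config": [g.config.label for g in grids],
            "states": [grid_to_string(g) for g in grids],
        }
    )


def grid_from_string(participant_id: str, night_date: date, config: SensorConfig, s: str) -> NightGrid:
    states = np.array([_CHAR_STATES[c] for c in s], dtype=np.int8)
    return NightGrid(participant_id, night_date, config, states)
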