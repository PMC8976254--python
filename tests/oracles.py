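"""Independent brute-force reference implementations used as oracles.

Deliberately naive: plain Python loops over explicit definitions, kept
free of any code from the package so the two routes stay independent.
"""

from __future__ import annotations

import numpy as np


def brute_first_sleep_run(states: list[int], k: int):
    """First index starting >= k consecutive 1s, scanning every index."""
    n = len(states)
    for i in range(n - k + 1):
        if all(states[i + j] == 1 for j in range(k)):
            return i
    return None


def brute_terminal_wake_run(states: list[int], k: int, bed: int):
    """Start of the all-awake suffix if it is >= k long and after bed."""
    n = len(states)
    w = n
    while w > 0 and states[w - 1] == 0:
        w -= 1
    if w == n:  # night ends asleep (or empty suffix)
        return None
    if n - w >= k and w > bed:
        return w
    return None


def brute_interruptions(states: list[int], bed: int, wake: int):
    """(count of maximal awake runs, total awake windows) strictly
    inside (bed, wake)."""
    count, total, in_run = 0, 0, False
    for i in range(bed + 1, wake):
        if states[i] == 0:
            total += 1
            if not in_run:
                count += 1
                in_run = True
        else:
            in_run = False
    return count, total


def brute_gap_outlier_mask(times: list[float]) -> list[bool]:
    """Keep-mask of the boxplot rule on min-neighbour gaps."""
    n = len(times)
    if n < 4:
        return [True] * n
    gaps = []
    for i in range(n):
        prev = times[i] - times[i - 1] if i > 0 else float("inf")
        nxt = times[i + 1] - times[i] if i < n - 1 else float("inf")
        gaps.append(min(prev, nxt))
    q1 = float(np.percentile(gaps, 25))
    q3 = float(np.percentile(gaps, 75))
    fence = q3 + 1.5 * (q3 - q1)
    return [g <= fence for g in gaps]


def brute_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg by the textbook definition:
    p_adj(i) = min over j >= i (ordered) of m * p_(j) / j, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * pvalues[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def brute_night_grid(event_times, event_sleeping, night_start_ts, state_machine):
    """144-window majority-vote grid built one window at a time.

    ``event_times``/``event_sleeping``: the participant's full stream
    for one sensor, sorted (seconds relative to any origin);
    ``night_start_ts`` in the same units. Returns a list of 144 values
    in {1 sleep, 0 awake, -1 missing}, ties resolved by the previous
    resolved window (missing when there is none), then carry-forward.
    """
    states = []
    for w in range(144):
        lo = night_start_ts + w * 300
        hi = lo + 300
        votes = [s for t, s in zip(event_times, event_sleeping) if lo <= t < hi]
        if not votes and state_machine:
            before = [s for t, s in zip(event_times, event_sleeping) if t <= lo]
            if before:
                votes = [before[-1]]
        if not votes:
            states.append(-1)
        elif sum(votes) * 2 > len(votes):
            states.append(1)
        elif sum(votes) * 2 < len(votes):
            states.append(0)
        else:  # tie
            prev = states[-1] if states else -1
            states.append(prev)
    # carry-forward
    out, last = [], None
    for s in states:
        if s == -1 and last is not None:
            out.append(last)
        else:
            out.append(s)
            if s != -1:
                last = s
    return out
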