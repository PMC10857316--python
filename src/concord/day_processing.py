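"""Social-day assembly, non-wear detection and valid-day flagging.

The analysis day is the *social day*: the 24 hours from 03:00 to 02:59 the
next civil day, indexed by the date on which it starts.  Slot 0 is 03:00,
slot 1439 is 02:59 the following morning.

Non-wear is a run of more than 60 consecutive minutes with fewer than 10
steps.  The phrase is ambiguous about whether "fewer than 10 steps" applies
to the run's total step count or to each minute individually, so both
interpretations are implemented and selectable:

``run_total`` (default)
    a span is non-wear when it lasts at least ``min_run_minutes`` and its
    *total* steps are below ``max_run_steps``.  Implemented as the union of
    all qualifying intervals, so a single moderately-stepped minute inside a
    long idle stretch blocks the whole stretch only if no sub-interval of
    sufficient length stays under the step budget.

``per_minute``
    candidate minutes are those with fewer than ``max_run_steps`` steps
    (unobserved minutes always qualify); maximal candidate runs of length at
    least ``min_run_minutes`` are non-wear.

A day is *valid* when it has at least ``min_wear_minutes`` (default 600,
i.e. 10 h) of wear; only valid days enter downstream agreement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Optional

import numpy as np

from .io_formats import MinuteSeries, SEDENTARY

SLOTS_PER_DAY = 1440
DAY_START_MINUTE = 3 * 60  # social day starts at 03:00

DEFAULT_MIN_RUN_MINUTES = 61   # ">60 consecutive minutes" is strict
DEFAULT_MAX_RUN_STEPS = 10     # "fewer than 10 steps" is strict
DEFAULT_MIN_WEAR_MINUTES = 600


@dataclass
class SocialDay:
    """One participant social day as fixed 1440-slot arrays."""
    participant_id: str
    day_date: date
    steps: np.ndarray                 # int64[1440]
    intensity: np.ndarray             # int8[1440]
    observed: np.ndarray              # bool[1440], had a data row
    wear: Optional[np.ndarray] = None  # bool[1440], set by detect_nonwear
    wear_minutes: int = 0
    valid: bool = False


def assign_social_day(timestamp: datetime) -> date:
    """Map a civil timestamp to the date of the social day containing it.

    Times at or after 03:00 belong to that date's social day; earlier times
    belong to the previous date's.
    """
    return (timestamp - timedelta(hours=3)).date()


def build_social_days(series: MinuteSeries) -> list[SocialDay]:
    """Split a sorted, de-duplicated minute series into social days.

    Every input minute lands in exactly one slot of exactly one day
    (partition property).  Slots without a data row get steps=0,
    intensity=sedentary, observed=False.
    """
    frame = series.frame
    if len(frame) == 0:
        return []
    tmins = frame["timestamp"].astype("int64").to_numpy() // 60_000_000_000
    rel = tmins - DAY_START_MINUTE
    day_index = rel // SLOTS_PER_DAY      # days since epoch of the social day
    slot = rel % SLOTS_PER_DAY
    steps = frame["steps"].to_numpy()
    intensity = frame["intensity"].to_numpy()

    # timestamps are sorted, so day_index is non-decreasing: contiguous slices
    uniq, first = np.unique(day_index, return_index=True)
    bounds = np.append(first, len(day_index))
    days: list[SocialDay] = []
    for k, d in enumerate(uniq):
        lo, hi = bounds[k], bounds[k + 1]
        day = SocialDay(
            participant_id=series.participant_id,
            day_date=(datetime(1970, 1, 1) + timedelta(days=int(d))).date(),
            steps=np.zeros(SLOTS_PER_DAY, dtype=np.int64),
            intensity=np.full(SLOTS_PER_DAY, SEDENTARY, dtype=np.int8),
            observed=np.zeros(SLOTS_PER_DAY, dtype=bool),
        )
        s = slot[lo:hi]
        day.steps[s] = steps[lo:hi]
        day.intensity[s] = intensity[lo:hi]
        day.observed[s] = True
        days.append(day)
    return days


def detect_nonwear(steps: np.ndarray,
                   observed: np.ndarray,
                   min_run_minutes: int = DEFAULT_MIN_RUN_MINUTES,
                   max_run_steps: int = DEFAULT_MAX_RUN_STEPS,
                   interpretation: str = "run_total") -> np.ndarray:
    """Return the per-slot wear mask for one social day.

    Unobserved slots contribute zero steps and are always eligible to join a
    non-wear run; an isolated unobserved stretch shorter than the run
    threshold stays wear (short sync gaps are not deleted).  Runs never
    bridge the day boundary because the function only ever sees one day.
    """
    steps = np.asarray(steps)
    observed = np.asarray(observed, dtype=bool)
    if steps.shape != (SLOTS_PER_DAY,) or observed.shape != (SLOTS_PER_DAY,):
        raise ValueError(
            f"expected arrays of length {SLOTS_PER_DAY}, got "
            f"{steps.shape} / {observed.shape}")
    eff_steps = np.where(observed, steps, 0).astype(np.int64)
    nonwear = np.zeros(SLOTS_PER_DAY, dtype=bool)

    if interpretation == "run_total":
        # union of all intervals with length >= min_run and total < max_steps;
        # it suffices to take, for each start, the maximal low-total window
        # (steps are non-negative so totals only grow when extending right)
        cs = np.concatenate([[0], np.cumsum(eff_steps)])
        # first prefix index with cs[t] >= cs[i] + max_steps
        t = np.searchsorted(cs, cs[:-1] + max_run_steps, side="left")
        length = t - 1 - np.arange(SLOTS_PER_DAY)       # window [i, i+len)
        starts = np.nonzero(length >= min_run_minutes)[0]
        if starts.size:
            diff = np.zeros(SLOTS_PER_DAY + 1, dtype=np.int64)
            np.add.at(diff, starts, 1)
            np.add.at(diff, starts + length[starts], -1)
            nonwear = np.cumsum(diff[:-1]) > 0
    elif interpretation == "per_minute":
        candidate = ~observed | (eff_steps < max_run_steps)
        padded = np.concatenate([[False], candidate, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        run_starts, run_ends = edges[::2], edges[1::2]
        for a, b in zip(run_starts, run_ends):
            if b - a >= min_run_minutes:
                nonwear[a:b] = True
    else:
        raise ValueError(f"unknown non-wear interpretation '{interpretation}'")

    return ~nonwear


def finalize_day(day: SocialDay,
                 min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES) -> SocialDay:
    """Fill in wear_minutes and the validity flag (in place, also returned)."""
    if day.wear is None:
        raise ValueError("wear mask not computed; run detect_nonwear first")
    day.wear_minutes = int(day.wear.sum())
    day.valid = day.wear_minutes >= min_wear_minutes
    return day


def process_series(series: MinuteSeries,
                   min_run_minutes: int = DEFAULT_MIN_RUN_MINUTES,
                   max_run_steps: int = DEFAULT_MAX_RUN_STEPS,
                   interpretation: str = "run_total",
                   min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES,
                   ) -> list[SocialDay]:
    """Convenience: build, non-wear-screen and finalize all of one
    participant's social days."""
    days = build_social_days(series)
    for day in days:
        day.wear = detect_nonwear(day.steps, day.observed,
                                  min_run_minutes=min_run_minutes,
                                  max_run_steps=max_run_steps,
                                  interpretation=interpretation)
        finalize_day(day, min_wear_minutes=min_wear_minutes)
    return days
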