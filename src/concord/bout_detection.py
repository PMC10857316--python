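"""Sliding-window exercise-day classification and the definition sweep.

A social day counts as an *exercise day* when some consecutive W-minute
window contains at least m active minutes.  The primary definition is
m=24 active (moderate-or-vigorous) minutes within W=30, which tolerates up
to 6 below-threshold minutes (e.g. rest between intervals) inside the bout.
The sweep varies m from 15 to 30 and the intensity set over
{light+moderate+vigorous, moderate+vigorous, vigorous}.

Windows are confined to the 1440-slot day; non-wear minutes are gated out
of the active indicator but window positions are unrestricted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .day_processing import SLOTS_PER_DAY, SocialDay
from .io_formats import LIGHT, MODERATE, VIGOROUS, NAME_TO_INTENSITY

MVPA = frozenset({MODERATE, VIGOROUS})
ALL_INTENSITIES = frozenset({LIGHT, MODERATE, VIGOROUS})
VIGOROUS_ONLY = frozenset({VIGOROUS})

DEFAULT_SWEEP_SETS = (ALL_INTENSITIES, MVPA, VIGOROUS_ONLY)


def intensity_set_label(intensity_set: frozenset[int]) -> str:
    """Canonical string form, e.g. ``moderate+vigorous``."""
    return "+".join(name for code, name in
                    sorted((c, n) for c, n in
                           [(c, {1: "light", 2: "moderate", 3: "vigorous"}[c])
                            for c in intensity_set]))


def parse_intensity_set(label: str) -> frozenset[int]:
    parts = [p.strip().lower() for p in label.replace(",", "+").split("+") if p.strip()]
    codes = set()
    for p in parts:
        if p not in NAME_TO_INTENSITY or p == "sedentary":
            raise ValueError(f"unknown intensity '{p}'")
        codes.add(NAME_TO_INTENSITY[p])
    if not codes:
        raise ValueError("empty intensity set")
    return frozenset(codes)


@dataclass(frozen=True)
class BoutDefinition:
    """Parameters of the exercise-day rule: >=m active minutes in any
    consecutive window of ``window_minutes``."""
    window_minutes: int = 30
    active_minutes: int = 24
    intensity_set: frozenset[int] = MVPA

    def __post_init__(self):
        if not (1 <= self.active_minutes <= self.window_minutes <= SLOTS_PER_DAY):
            raise ValueError(
                f"need 1 <= m ({self.active_minutes}) <= W "
                f"({self.window_minutes}) <= {SLOTS_PER_DAY}")


@dataclass
class DayClassification:
    participant_id: str
    day_date: date
    max_window_active: int
    exercise: bool
    valid: bool = True


def active_indicator(intensity: np.ndarray, wear: np.ndarray,
                     intensity_set: Iterable[int] = MVPA) -> np.ndarray:
    """Minute is active iff worn and its intensity is in the set.

    Sedentary (0) is never active regardless of the set.
    """
    intensity = np.asarray(intensity)
    wear = np.asarray(wear, dtype=bool)
    codes = [c for c in intensity_set if c != 0]
    return wear & np.isin(intensity, codes)


def max_window_active(active: np.ndarray, window_minutes: int = 30) -> int:
    """Maximum active-minute count over every in-day W-minute window.

    Running-sum sliding window, O(n); validated in the test suite against a
    quadratic brute-force enumeration.
    """
    active = np.asarray(active, dtype=np.int64)
    n = active.shape[0]
    if not 1 <= window_minutes <= n:
        raise ValueError(f"window_minutes must be in 1..{n}")
    cs = np.concatenate([[0], np.cumsum(active)])
    return int((cs[window_minutes:] - cs[:-window_minutes]).max())


def classify_day(day: SocialDay,
                 defn: BoutDefinition = BoutDefinition()) -> DayClassification:
    """Apply the bout rule to one finalized social day.

    Classification is computed for every day; downstream analysis filters to
    valid days, which is why the validity flag rides along.
    """
    active = active_indicator(day.intensity, day.wear, defn.intensity_set)
    mwa = max_window_active(active, defn.window_minutes)
    return DayClassification(
        participant_id=day.participant_id,
        day_date=day.day_date,
        max_window_active=mwa,
        exercise=mwa >= defn.active_minutes,
        valid=day.valid,
    )


def classification_frame(days: Iterable[SocialDay],
                         defn: BoutDefinition = BoutDefinition()) -> pd.DataFrame:
    """Classify many days into a tidy frame
    (participant_id, day_date, max_window_active, exercise, valid)."""
    rows = [classify_day(d, defn) for d in days]
    return pd.DataFrame({
        "participant_id": [r.participant_id for r in rows],
        "day_date": [r.day_date for r in rows],
        "max_window_active": [r.max_window_active for r in rows],
        "exercise": [r.exercise for r in rows],
        "valid": [r.valid for r in rows],
    })


def sweep_definitions(days: Sequence[SocialDay],
                      m_range: Sequence[int] = range(15, 31),
                      intensity_sets: Sequence[frozenset[int]] = DEFAULT_SWEEP_SETS,
                      window_minutes: int = 30) -> pd.DataFrame:
    """Classify every day under every (intensity set, m) combination.

    ``max_window_active`` is computed once per (day, set) and thresholded at
    each m, so the sweep is a single pass.  Returns a long frame with one
    row per (day, set, m).
    """
    m_range = list(m_range)
    if not m_range:
        raise ValueError("empty m_range")
    if any(not 1 <= m <= window_minutes for m in m_range):
        raise ValueError(f"m values must lie in 1..{window_minutes}")

    base_rows = []
    for day in days:
        for iset in intensity_sets:
            active = active_indicator(day.intensity, day.wear, iset)
            mwa = max_window_active(active, window_minutes)
            base_rows.append((day.participant_id, day.day_date,
                              intensity_set_label(iset), mwa, day.valid))
    base = pd.DataFrame(base_rows, columns=[
        "participant_id", "day_date", "intensity_set", "max_window_active",
        "valid"])
    frames = []
    for m in m_range:
        f = base.copy()
        f["m"] = m
        f["exercise"] = f["max_window_active"] >= m
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
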