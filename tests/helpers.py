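"""Shared builders for hand-constructed days and minute series."""

from datetime import date

import numpy as np
import pandas as pd

from concord.day_processing import SLOTS_PER_DAY, SocialDay
from concord.io_formats import MinuteSeries


def series_from_minutes(timestamps, steps=None, intensity=None, pid="P1"):
    n = len(timestamps)
    frame = pd.DataFrame({
        "timestamp": pd.to_datetime(timestamps),
        "steps": steps if steps is not None else np.zeros(n, dtype=int),
        "intensity": (intensity if intensity is not None
                      else np.zeros(n, dtype=np.int8)),
    }).sort_values("timestamp").reset_index(drop=True)
    return MinuteSeries(pid, frame)


def make_day(intensity, wear=None, pid="P1", valid=True):
    intensity = np.asarray(intensity, dtype=np.int8)
    day = SocialDay(pid, date(2020, 1, 1),
                    steps=np.zeros(SLOTS_PER_DAY, dtype=np.int64),
                    intensity=intensity,
                    observed=np.ones(SLOTS_PER_DAY, dtype=bool))
    day.wear = (np.ones(SLOTS_PER_DAY, dtype=bool) if wear is None
                else np.asarray(wear, dtype=bool))
    day.wear_minutes = int(day.wear.sum())
    day.valid = valid
    return day


def brute_force_max_window(active, w):
    """Quadratic oracle: literally count every window."""
    active = [int(a) for a in active]
    return max(sum(active[i:i + w]) for i in range(len(active) - w + 1))
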