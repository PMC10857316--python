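"""Readers and writers for the pipeline's CSV/JSON interfaces.

All files are plain CSV (or JSON for the agreement report) in naive local
civil time; no timezone arithmetic happens anywhere in the package because
the social-day definition is a local-clock concept.

Schemas
-------
minutes CSV     participant_id,timestamp,steps,intensity
                (ISO 8601 "YYYY-MM-DDTHH:MM", int >= 0, int 0-3)
ema CSV         participant_id,report_date,response[,completed_at]
covariates CSV  participant_id,age,sex,bmi,black,hispanic,grad_degree,
                partner,caregiver,mean_stress,tech_use
daily CSV       participant_id,day_date,accel_exercise,ema_exercise,included
sweep CSV       intensity_set,m,mean_kappa,sd_kappa,median_kappa,ci_low,
                ci_high,pooled_kappa,pooled_se,n_participants,n_days

This module only parses and validates; every computation (social-day
assignment, non-wear, classification) lives downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: device intensity categories, as exported minute by minute
SEDENTARY, LIGHT, MODERATE, VIGOROUS = 0, 1, 2, 3
INTENSITY_NAMES = {SEDENTARY: "sedentary", LIGHT: "light",
                   MODERATE: "moderate", VIGOROUS: "vigorous"}
NAME_TO_INTENSITY = {v: k for k, v in INTENSITY_NAMES.items()}


class SchemaError(ValueError):
    """A file is missing a required column or has an unusable layout."""


class RowError(ValueError):
    """A single row fails validation; carries its 1-based file line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass
class ParseReport:
    """Bookkeeping attached to a parsed minutes file."""
    n_rows: int = 0
    n_duplicates: int = 0
    n_gaps: int = 0          # missing interior minutes across all participants
    n_conflicts: int = 0     # EMA same-day conflicts resolved


@dataclass
class MinuteSeries:
    """Sorted, de-duplicated per-minute record stream for one participant.

    ``frame`` has columns ``timestamp`` (datetime64[ns], minute resolution),
    ``steps`` (int64) and ``intensity`` (int8), sorted by timestamp with
    unique timestamps.
    """
    participant_id: str
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class MinuteData:
    """All participants' minute series plus the parse report."""
    series: dict[str, MinuteSeries]
    report: ParseReport = field(default_factory=ParseReport)

    def __iter__(self):
        return iter(self.series.values())


@dataclass
class EmaRecord:
    """One end-of-day yes/no exercise response, keyed to a social-day date."""
    participant_id: str
    report_date: date
    response: str                      # "yes" | "no" | "missing"
    completed_at: Optional[datetime] = None


@dataclass
class ParticipantCovariates:
    """Person-level predictors of agreement; optional fields stay ``None``."""
    participant_id: str
    age: Optional[float] = None
    female: Optional[int] = None       # sex coded 1=female, 0=male
    bmi: Optional[float] = None
    black: Optional[int] = None
    hispanic: Optional[int] = None
    grad_degree: Optional[int] = None
    partner: Optional[int] = None
    caregiver: Optional[int] = None
    mean_stress: Optional[float] = None
    tech_use: Optional[int] = None


MINUTES_COLUMNS = ["participant_id", "timestamp", "steps", "intensity"]
EMA_COLUMNS = ["participant_id", "report_date", "response"]
COVARIATE_COLUMNS = ["participant_id", "age", "sex", "bmi", "black",
                     "hispanic", "grad_degree", "partner", "caregiver",
                     "mean_stress", "tech_use"]
DAILY_COLUMNS = ["participant_id", "day_date", "accel_exercise",
                 "ema_exercise", "included"]
SWEEP_COLUMNS = ["intensity_set", "m", "mean_kappa", "sd_kappa",
                 "median_kappa", "ci_low", "ci_high", "pooled_kappa",
                 "pooled_se", "n_participants", "n_days"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_minutes(path) -> MinuteData:
    """Read a minute-level accelerometer CSV.

    Rows are grouped per participant and sorted by timestamp.  Duplicate
    (participant, timestamp) rows keep the first occurrence in file order;
    the dropped count is recorded on the report.  Gaps (missing interior
    minutes between a participant's first and last timestamp) are counted
    but never imputed here.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, MINUTES_COLUMNS, path)
    # line numbers: header is line 1
    lines = df.index.to_numpy() + 2

    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        raise RowError(int(lines[ts.isna().to_numpy()][0]),
                       "unparseable timestamp")
    steps = pd.to_numeric(df["steps"], errors="coerce")
    bad = steps.isna() | (steps < 0) | (steps != steps.round())
    if bad.any():
        raise RowError(int(lines[bad.to_numpy()][0]),
                       "steps must be a non-negative integer")
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = intensity.isna() | ~intensity.isin([0, 1, 2, 3])
    if bad.any():
        raise RowError(int(lines[bad.to_numpy()][0]),
                       "intensity must be in {0,1,2,3}")

    clean = pd.DataFrame({
        "participant_id": df["participant_id"],
        "timestamp": ts.dt.floor("min"),
        "steps": steps.astype(np.int64),
        "intensity": intensity.astype(np.int8),
    })
    report = ParseReport(n_rows=len(clean))

    series: dict[str, MinuteSeries] = {}
    for pid, grp in clean.groupby("participant_id", sort=True):
        # stable sort keeps file order within equal timestamps, so "first
        # occurrence wins" is deterministic
        grp = grp.sort_values("timestamp", kind="stable")
        deduped = grp.drop_duplicates("timestamp", keep="first")
        report.n_duplicates += len(grp) - len(deduped)
        tmins = deduped["timestamp"].astype("int64").to_numpy() // 60_000_000_000
        if len(tmins) > 1:
            report.n_gaps += int(tmins[-1] - tmins[0] + 1 - len(tmins))
        series[str(pid)] = MinuteSeries(
            str(pid), deduped.drop(columns="participant_id").reset_index(drop=True))
    return MinuteData(series=series, report=report)


_RESPONSE_MAP = {"1": "yes", "yes": "yes", "0": "no", "no": "no",
                 "true": "yes", "false": "no"}


def read_ema(path, report: Optional[ParseReport] = None) -> list[EmaRecord]:
    """Read the daily EMA CSV and resolve to one record per participant-day.

    When a participant-day appears more than once, the row with the latest
    ``completed_at`` wins; ties or absent timestamps fall back to the first
    row in file order, and the conflict is counted on ``report``.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "response": str})
    _require_columns(df, EMA_COLUMNS, path)
    lines = df.index.to_numpy() + 2

    dates = pd.to_datetime(df["report_date"], errors="coerce")
    if dates.isna().any():
        raise RowError(int(lines[dates.isna().to_numpy()][0]),
                       "unparseable report_date")
    resp_raw = df["response"].fillna("").str.strip().str.lower()
    resp = resp_raw.map(_RESPONSE_MAP)
    bad = resp.isna() & (resp_raw != "")
    if bad.any():
        raise RowError(int(lines[bad.to_numpy()][0]),
                       f"response '{resp_raw[bad].iloc[0]}' not in {{0,1,yes,no,empty}}")
    resp = resp.fillna("missing")

    if "completed_at" in df.columns:
        completed = pd.to_datetime(df["completed_at"], errors="coerce")
    else:
        completed = pd.Series(pd.NaT, index=df.index)

    resolved: dict[tuple[str, date], EmaRecord] = {}
    for i in df.index:
        rec = EmaRecord(
            participant_id=str(df.at[i, "participant_id"]),
            report_date=dates[i].date(),
            response=resp[i],
            completed_at=None if pd.isna(completed[i]) else completed[i].to_pydatetime(),
        )
        key = (rec.participant_id, rec.report_date)
        if key not in resolved:
            resolved[key] = rec
        else:
            if report is not None:
                report.n_conflicts += 1
            prev = resolved[key]
            # later completion wins; ties / missing timestamps keep first row
            if (rec.completed_at is not None and
                    (prev.completed_at is None or rec.completed_at > prev.completed_at)):
                resolved[key] = rec
    return sorted(resolved.values(),
                  key=lambda r: (r.participant_id, r.report_date))


_SEX_MAP = {"female": 1, "male": 0, "1": 1, "0": 0, "f": 1, "m": 0}
_BINARY_FIELDS = ["black", "hispanic", "grad_degree", "partner",
                  "caregiver", "tech_use"]


def read_covariates(path) -> dict[str, ParticipantCovariates]:
    """Read the participant covariate CSV.

    Missing optional fields become ``None`` (never zero); regressions using
    such a field drop the participant listwise.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ["participant_id"], path)
    out: dict[str, ParticipantCovariates] = {}
    for i in df.index:
        line = int(i) + 2
        pid = str(df.at[i, "participant_id"])
        cov = ParticipantCovariates(participant_id=pid)
        if "sex" in df.columns and not pd.isna(df.at[i, "sex"]):
            raw = str(df.at[i, "sex"]).strip().lower()
            # tolerate numeric dtype rendering "1" as "1.0"
            if raw.endswith(".0"):
                raw = raw[:-2]
            if raw not in _SEX_MAP:
                raise RowError(line, f"sex '{raw}' not in {{female,male,0,1}}")
            cov.female = _SEX_MAP[raw]
        for name in ("age", "bmi", "mean_stress"):
            if name in df.columns and not pd.isna(df.at[i, name]):
                val = float(df.at[i, name])
                if name in ("age", "bmi") and val <= 0:
                    raise RowError(line, f"{name} must be positive")
                setattr(cov, name, val)
        for name in _BINARY_FIELDS:
            if name in df.columns and not pd.isna(df.at[i, name]):
                val = float(df.at[i, name])
                if val not in (0.0, 1.0):
                    raise RowError(line, f"{name} must be 0 or 1")
                setattr(cov, name, int(val))
        out[pid] = cov
    return out


def covariates_frame(covs: dict[str, ParticipantCovariates]) -> pd.DataFrame:
    """Covariates as a DataFrame indexed by participant_id (None -> NaN)."""
    rows = []
    for pid in sorted(covs):
        c = covs[pid]
        rows.append({"participant_id": pid, "age": c.age, "female": c.female,
                     "bmi": c.bmi, "black": c.black, "hispanic": c.hispanic,
                     "grad_degree": c.grad_degree, "partner": c.partner,
                     "caregiver": c.caregiver, "mean_stress": c.mean_stress,
                     "tech_use": c.tech_use})
    df = pd.DataFrame(rows, columns=["participant_id", "age", "female", "bmi",
                                     "black", "hispanic", "grad_degree",
                                     "partner", "caregiver", "mean_stress",
                                     "tech_use"])
    return df.set_index("participant_id").astype(float)


# ---------------------------------------------------------------------------
# daily outcome table

def write_daily_table(outcomes: pd.DataFrame, path) -> None:
    """Write the participant-day outcome table.

    ``outcomes`` columns: participant_id, day_date, accel_exercise,
    ema_exercise, included.  Absent classifications (invalid day / missing
    EMA) are empty cells; present ones are 0/1.
    """
    df = outcomes.copy()
    for col in ("accel_exercise", "ema_exercise"):
        df[col] = df[col].map(
            lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v))
            else str(int(v)))
    df["included"] = df["included"].astype(int)
    df = df.sort_values(["participant_id", "day_date"])
    df.to_csv(path, index=False, columns=DAILY_COLUMNS)


def read_daily_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, DAILY_COLUMNS, path)
    df["day_date"] = pd.to_datetime(df["day_date"]).dt.date
    for col in ("accel_exercise", "ema_exercise"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["included"] = df["included"].astype(int).astype(bool)
    return df.sort_values(["participant_id", "day_date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# agreement JSON and sweep CSV

def write_agreement_json(results: dict, path) -> None:
    """Serialize the agreement report (per-participant, pooled, summary)."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(results, indent=2, default=_default,
                                     allow_nan=True) + "\n")


def read_agreement_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_sweep_csv(sweep: pd.DataFrame, path) -> None:
    sweep.to_csv(path, index=False, columns=SWEEP_COLUMNS)


def read_sweep_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SWEEP_COLUMNS, path)
    return df
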