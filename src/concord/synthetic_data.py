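"""Synthetic cohort generator with known ground truth.

Emulates a year-long free-living study: per-minute step counts and device
intensity categories with embedded exercise bouts, overnight non-wear runs,
end-of-day yes/no exercise reports generated with configurable
sensitivity/specificity against the latent true exercise state, and
participant covariates drawn to match the study population's margins.  The
latent per-day truth table is returned alongside, so every pipeline stage
can be tested for recovery without any real data.

Two generation paths exist on purpose:

* :func:`generate_cohort` builds actual minute streams, so accelerometer
  error arises *mechanistically* (bout duration near the threshold,
  non-wear masking, incidental activity);
* :func:`day_level_generator` draws day-level outcomes directly from the
  parametric two-noisy-raters model whose exact kappa
  :func:`analytic_kappa` computes in closed form — the fast path for
  agreement-layer convergence tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (EmaRecord, MinuteSeries, ParticipantCovariates,
                         SEDENTARY, LIGHT, MODERATE, VIGOROUS)
from .day_processing import SLOTS_PER_DAY
from .agreement import ContingencyTable, cohen_kappa, KappaResult


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the study's observed margins.

    ``exercise_prevalence`` is the cohort-mean per-day probability of a true
    exercise day; per-participant prevalences are Beta-distributed around it
    with the given concentration (mean 0.32, concentration 7 gives a
    between-person SD of ~0.17).  ``ema_sensitivity``/``ema_specificity``
    tie the self-report to the truth; the defaults yield a self-report
    prevalence of ~37% at true prevalence 0.32.  Compliance values are the
    probabilities that a day has an EMA response and >=10 h of wear.
    """
    n_participants: int = 79
    n_days: int = 365
    start_date: date = date(2020, 1, 1)

    exercise_prevalence: float = 0.32
    prevalence_concentration: Optional[float] = 7.0  # None -> no heterogeneity

    bout_mvpa_min: int = 25          # MVPA minutes per inserted bout
    bout_mvpa_max: int = 60
    bout_rest_max: int = 6           # below-threshold minutes inside the bout
    bout_vigorous_frac: float = 0.3  # chance an MVPA bout minute is vigorous

    ema_sensitivity: float = 0.70    # P(report yes | true exercise day)
    ema_specificity: float = 0.78    # P(report no  | no exercise)
    ema_compliance: float = 0.64     # P(response present)
    wear_compliance: float = 0.68    # P(day reaches >=10 h wear)

    # overnight non-wear run lengths, minutes (valid / low-wear days)
    nonwear_valid_min: int = 120
    nonwear_valid_max: int = 420
    nonwear_invalid_min: int = 860
    nonwear_invalid_max: int = 1320

    # background activity
    light_rate: float = 0.15             # chance a worn background minute is light
    sedentary_steps_mean: float = 6.0
    light_steps_mean: float = 25.0
    mvpa_steps_mean: float = 110.0
    incidental_mvpa_per_day: float = 0.5  # Poisson mean of short moderate episodes
    incidental_len_min: int = 5
    incidental_len_max: int = 20

    seed: int = 0

    def validate(self) -> None:
        for name in ("exercise_prevalence", "ema_sensitivity",
                     "ema_specificity", "ema_compliance", "wear_compliance",
                     "light_rate", "bout_vigorous_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("n_participants and n_days must be >= 1")
        span = self.bout_mvpa_max + self.bout_rest_max
        if span > SLOTS_PER_DAY:
            raise ValueError("bout longer than a day")
        if self.bout_mvpa_min < 1 or self.bout_mvpa_min > self.bout_mvpa_max:
            raise ValueError("invalid bout_mvpa range")


@dataclass
class GroundTruth:
    """Latent truth behind a generated cohort."""
    days: pd.DataFrame                  # participant_id, day_date, true_exercise
    prevalence: dict[str, float]        # per-participant true prevalence
    config: SyntheticConfig


@dataclass
class Cohort:
    minutes: dict[str, MinuteSeries]
    ema: list[EmaRecord]
    covariates: dict[str, ParticipantCovariates]
    truth: GroundTruth

    def write(self, out_dir) -> None:
        """Emit the io_formats CSV schemas plus ground_truth.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = []
        for pid in sorted(self.minutes):
            f = self.minutes[pid].frame.copy()
            f.insert(0, "participant_id", pid)
            frames.append(f)
        allmin = pd.concat(frames, ignore_index=True)
        allmin["timestamp"] = allmin["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        allmin.to_csv(out / "minutes.csv", index=False)

        pd.DataFrame([{
            "participant_id": r.participant_id,
            "report_date": r.report_date.isoformat(),
            "response": {"yes": 1, "no": 0, "missing": ""}[r.response],
            "completed_at": ("" if r.completed_at is None
                             else r.completed_at.strftime("%Y-%m-%dT%H:%M")),
        } for r in self.ema]).to_csv(out / "ema.csv", index=False)

        pd.DataFrame([{
            "participant_id": c.participant_id, "age": c.age,
            "sex": {1: "female", 0: "male", None: ""}[c.female],
            "bmi": c.bmi, "black": c.black, "hispanic": c.hispanic,
            "grad_degree": c.grad_degree, "partner": c.partner,
            "caregiver": c.caregiver, "mean_stress": c.mean_stress,
            "tech_use": c.tech_use,
        } for c in sorted(self.covariates.values(),
                          key=lambda c: c.participant_id)]
        ).to_csv(out / "covariates.csv", index=False)

        t = self.truth.days.copy()
        t["true_exercise"] = t["true_exercise"].astype(int)
        t.to_csv(out / "ground_truth.csv", index=False)


def _participant_prevalences(cfg: SyntheticConfig,
                             rng: np.random.Generator) -> np.ndarray:
    pi = cfg.exercise_prevalence
    if cfg.prevalence_concentration is None or pi in (0.0, 1.0):
        return np.full(cfg.n_participants, pi)
    c = cfg.prevalence_concentration
    draws = rng.beta(pi * c, (1 - pi) * c, size=cfg.n_participants)
    return np.clip(draws, 0.01, 0.99)


def _insert_bout(intensity: np.ndarray, steps: np.ndarray, start: int,
                 cfg: SyntheticConfig, rng: np.random.Generator) -> None:
    """Place one exercise bout beginning at ``start``.

    The first 24 slots are always MVPA, so any bout satisfies the primary
    24-of-30 rule; remaining MVPA minutes and up to ``bout_rest_max`` rest
    minutes are shuffled into the tail.
    """
    d = int(rng.integers(cfg.bout_mvpa_min, cfg.bout_mvpa_max + 1))
    r = int(rng.integers(0, cfg.bout_rest_max + 1))
    head = min(24, d)
    tail = np.array([1] * (d - head) + [0] * r, dtype=np.int8)
    rng.shuffle(tail)
    is_mvpa = np.concatenate([np.ones(head, dtype=np.int8), tail]).astype(bool)
    span = len(is_mvpa)
    sl = slice(start, start + span)
    vig = rng.random(span) < cfg.bout_vigorous_frac
    intensity[sl] = np.where(is_mvpa, np.where(vig, VIGOROUS, MODERATE), LIGHT)
    steps[sl] = np.where(
        is_mvpa, rng.poisson(cfg.mvpa_steps_mean, span),
        rng.poisson(cfg.light_steps_mean, span))


def generate_participant(cfg: SyntheticConfig, pid: str, prevalence: float,
                         rng: np.random.Generator
                         ) -> tuple[MinuteSeries, list[EmaRecord], pd.DataFrame]:
    """Minute stream, EMA records and truth rows for one participant."""
    n_days = cfg.n_days
    n_slots = n_days * SLOTS_PER_DAY

    # background: sedentary with occasional light minutes
    light = rng.random(n_slots) < cfg.light_rate
    steps = np.where(light,
                     rng.poisson(cfg.light_steps_mean, n_slots),
                     rng.poisson(cfg.sedentary_steps_mean, n_slots)
                     ).astype(np.int32)
    intensity = np.where(light, LIGHT, SEDENTARY).astype(np.int8)

    true_exercise = rng.random(n_days) < prevalence
    worn = rng.random(n_days) < cfg.wear_compliance
    respond = rng.random(n_days) < cfg.ema_compliance

    ema: list[EmaRecord] = []
    truth_rows = []
    bout_span_max = cfg.bout_mvpa_max + cfg.bout_rest_max
    for d in range(n_days):
        base = d * SLOTS_PER_DAY
        day_int = intensity[base:base + SLOTS_PER_DAY]
        day_steps = steps[base:base + SLOTS_PER_DAY]

        # overnight non-wear run from 03:00 (device charging / late wear)
        if worn[d]:
            nw = int(rng.integers(cfg.nonwear_valid_min,
                                  cfg.nonwear_valid_max + 1))
        else:
            nw = int(rng.integers(cfg.nonwear_invalid_min,
                                  cfg.nonwear_invalid_max + 1))
        day_steps[:nw] = 0
        day_int[:nw] = SEDENTARY

        # incidental (non-bout) moderate episodes: short walks etc.
        n_epi = rng.poisson(cfg.incidental_mvpa_per_day)
        for _ in range(n_epi):
            ln = int(rng.integers(cfg.incidental_len_min,
                                  cfg.incidental_len_max + 1))
            s = int(rng.integers(nw, SLOTS_PER_DAY - ln))
            day_int[s:s + ln] = MODERATE
            day_steps[s:s + ln] = rng.poisson(cfg.mvpa_steps_mean, ln)

        if true_exercise[d]:
            lo = max(nw + 1, 240)           # waking hours, after the non-wear run
            hi = SLOTS_PER_DAY - bout_span_max - 1
            start = int(rng.integers(lo, hi)) if lo < hi else hi
            _insert_bout(day_int, day_steps, start, cfg, rng)

        day_date = cfg.start_date + timedelta(days=d)
        truth_rows.append((pid, day_date, bool(true_exercise[d])))
        # response drawn regardless of compliance so the truth->report noise
        # stream does not depend on the missingness stream
        said_yes = (rng.random() < cfg.ema_sensitivity if true_exercise[d]
                    else rng.random() >= cfg.ema_specificity)
        if respond[d]:
            ema.append(EmaRecord(
                participant_id=pid, report_date=day_date,
                response="yes" if said_yes else "no",
                completed_at=datetime.combine(day_date,
                                              datetime.min.time())
                + timedelta(hours=21, minutes=30)))

    t0 = np.datetime64(datetime.combine(cfg.start_date, datetime.min.time())
                       + timedelta(hours=3), "m")
    timestamps = t0 + np.arange(n_slots, dtype=np.int64)
    frame = pd.DataFrame({
        "timestamp": pd.Series(timestamps).astype("datetime64[ns]"),
        "steps": steps.astype(np.int64),
        "intensity": intensity,
    })
    truth = pd.DataFrame(truth_rows,
                         columns=["participant_id", "day_date", "true_exercise"])
    return MinuteSeries(pid, frame), ema, truth


def generate_covariates(cfg: SyntheticConfig, rng: np.random.Generator
                        ) -> dict[str, ParticipantCovariates]:
    """Covariates matching the study population's margins (57% female,
    age 31.9 +/- 9.5, BMI 26.4 +/- 5.3, ...); no joint structure."""
    out = {}
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:03d}"
        out[pid] = ParticipantCovariates(
            participant_id=pid,
            age=float(np.round(np.clip(rng.normal(31.9, 9.5), 18, 80), 1)),
            female=int(rng.random() < 0.57),
            bmi=float(np.round(np.clip(rng.normal(26.4, 5.3), 15, 55), 1)),
            black=int(rng.random() < 0.139),
            hispanic=int(rng.random() < 0.278),
            grad_degree=int(rng.random() < 0.405),
            partner=int(rng.random() < 0.405),
            caregiver=int(rng.random() < 0.494),
            mean_stress=float(np.round(np.clip(rng.normal(22.6, 6.0), 0, 40), 1)),
            tech_use=int(rng.random() < 0.494),
        )
    return out


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate the full synthetic cohort (deterministic in ``cfg.seed``)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    prevalences = _participant_prevalences(cfg, rng)
    covariates = generate_covariates(cfg, rng)

    minutes: dict[str, MinuteSeries] = {}
    ema: list[EmaRecord] = []
    truth_frames = []
    prev_map = {}
    for i, pid in enumerate(sorted(covariates)):
        series, ema_p, truth_p = generate_participant(
            cfg, pid, float(prevalences[i]), rng)
        minutes[pid] = series
        ema.extend(ema_p)
        truth_frames.append(truth_p)
        prev_map[pid] = float(prevalences[i])
    truth = GroundTruth(days=pd.concat(truth_frames, ignore_index=True),
                        prevalence=prev_map, config=cfg)
    return Cohort(minutes=minutes, ema=ema, covariates=covariates, truth=truth)


# ---------------------------------------------------------------------------
# parametric day-level model and its closed-form kappa

def joint_cells(pi: float, se_a: float, sp_a: float,
                se_e: float, sp_e: float) -> np.ndarray:
    """Joint P(accel=a, ema=e) under two conditionally independent noisy
    raters of the latent exercise state.  Returns [[p11, p10], [p01, p00]]
    indexed (accel, ema)."""
    def f(se, sp, y, t):
        if t == 1:
            return se if y == 1 else 1 - se
        return 1 - sp if y == 1 else sp

    p = np.zeros((2, 2))
    for a in (1, 0):
        for e in (1, 0):
            p[1 - a, 1 - e] = (pi * f(se_a, sp_a, a, 1) * f(se_e, sp_e, e, 1)
                               + (1 - pi) * f(se_a, sp_a, a, 0)
                               * f(se_e, sp_e, e, 0))
    return p


def analytic_kappa(pi: float, se_a: float, sp_a: float,
                   se_e: float, sp_e: float) -> float:
    """Exact population kappa of the two-noisy-raters model.

    Returns NaN when the chance agreement is 1 (degenerate marginals).
    """
    p = joint_cells(pi, se_a, sp_a, se_e, sp_e)
    p_o = p[0, 0] + p[1, 1]
    pa = p[0, :].sum()   # P(accel = yes)
    pe_ = p[:, 0].sum()  # P(ema = yes)
    p_chance = pa * pe_ + (1 - pa) * (1 - pe_)
    if p_chance >= 1.0:
        return float("nan")
    return float((p_o - p_chance) / (1 - p_chance))


def day_level_generator(pi: float, se_a: float, sp_a: float,
                        se_e: float, sp_e: float,
                        n_days: int, seed: int = 0) -> pd.DataFrame:
    """I.i.d. daily outcomes from the parametric joint distribution.

    Returns the daily outcome frame (single pseudo-participant, all days
    included), for convergence tests of empirical vs analytic kappa.
    """
    rng = np.random.default_rng(seed)
    truth = rng.random(n_days) < pi
    accel = np.where(truth, rng.random(n_days) < se_a,
                     rng.random(n_days) >= sp_a)
    ema = np.where(truth, rng.random(n_days) < se_e,
                   rng.random(n_days) >= sp_e)
    return pd.DataFrame({
        "participant_id": "SIM",
        "day_date": [date(2020, 1, 1) + timedelta(days=int(i))
                     for i in range(n_days)],
        "accel_exercise": accel.astype(float),
        "ema_exercise": ema.astype(float),
        "included": True,
    })
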