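"""High-level orchestration: minutes -> social days -> classification ->
daily outcomes -> agreement/sweep.  The CLI is a thin shell over these
functions; tests and the acceptance script call them directly."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import pandas as pd

from . import agreement, bout_detection, correlates, day_processing
from .config import RunConfig
from .io_formats import EmaRecord, MinuteData, MinuteSeries


@dataclass
class AttritionLog:
    """Per-stage record counts, mirroring compliance reporting."""
    n_days_observed: int = 0
    n_days_valid: int = 0
    n_days_with_ema: int = 0
    n_days_included: int = 0


def _series_map(minutes: Union[MinuteData, Mapping[str, MinuteSeries]]
                ) -> Mapping[str, MinuteSeries]:
    return minutes.series if isinstance(minutes, MinuteData) else minutes


def iter_social_days(minutes, cfg: RunConfig):
    """Yield finalized social days participant by participant (bounded
    memory even for year-long cohorts)."""
    series_map = _series_map(minutes)
    for pid in sorted(series_map):
        yield from day_processing.process_series(
            series_map[pid],
            min_run_minutes=cfg.nonwear.min_run_minutes,
            max_run_steps=cfg.nonwear.max_run_steps,
            interpretation=cfg.nonwear.interpretation,
            min_wear_minutes=cfg.valid_day.min_wear_minutes)


def classify_cohort(minutes, cfg: RunConfig) -> pd.DataFrame:
    """Primary-definition day classification for the whole cohort."""
    defn = cfg.bout.definition()
    frames = []
    series_map = _series_map(minutes)
    for pid in sorted(series_map):
        days = day_processing.process_series(
            series_map[pid],
            min_run_minutes=cfg.nonwear.min_run_minutes,
            max_run_steps=cfg.nonwear.max_run_steps,
            interpretation=cfg.nonwear.interpretation,
            min_wear_minutes=cfg.valid_day.min_wear_minutes)
        frames.append(bout_detection.classification_frame(days, defn))
    return pd.concat(frames, ignore_index=True)


def daily_outcomes(minutes, ema: Iterable[EmaRecord],
                   cfg: RunConfig) -> pd.DataFrame:
    """End-to-end to the daily outcome table under the primary definition."""
    return agreement.pair_days(classify_cohort(minutes, cfg), ema)


def sweep_cohort(minutes, ema: Iterable[EmaRecord],
                 cfg: RunConfig) -> pd.DataFrame:
    """Definition sweep -> agreement summaries per (intensity set, m)."""
    frames = []
    series_map = _series_map(minutes)
    for pid in sorted(series_map):
        days = day_processing.process_series(
            series_map[pid],
            min_run_minutes=cfg.nonwear.min_run_minutes,
            max_run_steps=cfg.nonwear.max_run_steps,
            interpretation=cfg.nonwear.interpretation,
            min_wear_minutes=cfg.valid_day.min_wear_minutes)
        frames.append(bout_detection.sweep_definitions(
            days, m_range=cfg.sweep.m_range(),
            intensity_sets=cfg.sweep.sets(),
            window_minutes=cfg.bout.window_minutes))
    sweep_cls = pd.concat(frames, ignore_index=True)
    return agreement.sweep_agreement(
        sweep_cls, ema,
        min_days=cfg.agreement.min_days_per_participant, seed=cfg.seed)


def attrition(outcomes: pd.DataFrame) -> AttritionLog:
    return AttritionLog(
        n_days_observed=len(outcomes),
        n_days_valid=int(outcomes["accel_exercise"].notna().sum()),
        n_days_with_ema=int(outcomes["ema_exercise"].notna().sum()),
        n_days_included=int(outcomes["included"].sum()))


def percent_days_exercised(outcomes: pd.DataFrame) -> dict:
    """Participant-mean and pooled-days percentages of included days
    exercised by each measure (the participant-mean is the headline form)."""
    inc = outcomes[outcomes["included"]]
    if len(inc) == 0:
        return {k: float("nan") for k in
                ("ema_mean", "ema_sd", "accel_mean", "accel_sd",
                 "ema_pooled", "accel_pooled")}
    per = inc.groupby("participant_id")[["ema_exercise", "accel_exercise"]].mean() * 100
    return {
        "ema_mean": float(per["ema_exercise"].mean()),
        "ema_sd": float(per["ema_exercise"].std(ddof=1)),
        "accel_mean": float(per["accel_exercise"].mean()),
        "accel_sd": float(per["accel_exercise"].std(ddof=1)),
        "ema_pooled": float(inc["ema_exercise"].mean() * 100),
        "accel_pooled": float(inc["accel_exercise"].mean() * 100),
    }


def run_correlates(agreement_report: dict, covariates: pd.DataFrame,
                   outcomes: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Univariate screen plus both multivariate modes, one labeled frame."""
    kappas = pd.Series(
        {row["id"]: row["kappa"] for row in agreement_report["per_participant"]
         if row["kappa"] is not None}, dtype=float)
    kappas.index = kappas.index.astype(str)
    design = correlates.build_design(covariates, outcomes)
    kappas = kappas.reindex(design.index)

    uni = correlates.univariate_screen(kappas, design)
    rows = list(uni)
    rows += correlates.multivariate_model(
        kappas, design, mode="significant_only", alpha=cfg.correlates.alpha,
        univariate=uni)
    try:
        rows += correlates.multivariate_model(kappas, design,
                                              mode="all_covariates")
    except ValueError:
        pass  # too few participants for the all-covariates fit; screen stands
    return correlates.rows_frame(rows)
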