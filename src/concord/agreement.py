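"""Day-level agreement between self-reported and accelerometer exercise.

The analysis unit is the participant-day on which both a valid
accelerometer day and an EMA yes/no response exist.  Agreement is
chance-corrected with Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

computed per participant (then summarized across participants) and pooled
over the summed 2x2 table of all person-days.  The pooled kappa carries the
Fleiss-Cohen-Everitt large-sample standard error; a nonparametric bootstrap
SE is available as a cross-check.

A participant whose included days are constant on either measure (all EMA
yes, all accelerometer no, ...) has an uninformative table; such kappas are
flagged undefined, excluded from cross-participant moments, and counted
separately rather than imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EmaRecord


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are the EMA response, columns the accelerometer.

    a: EMA yes / accel yes    b: EMA yes / accel no
    c: EMA no  / accel yes    d: EMA no  / accel no
    """
    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(self.a + other.a, self.b + other.b,
                                self.c + other.c, self.d + other.d)

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class KappaResult:
    kappa: float = float("nan")
    p_o: float = float("nan")
    p_e: float = float("nan")
    se: Optional[float] = None   # asymptotic SE, pooled tables only
    n: int = 0
    undefined: bool = False
    reason: Optional[str] = None


@dataclass
class KappaSummary:
    """Cross-participant summary of defined kappa values.

    ``ci_low``/``ci_high`` bracket the *median* (seeded percentile
    bootstrap, matching the sweep figures); the t-interval for the mean is
    carried separately.
    """
    mean: float = float("nan")
    sd: float = float("nan")
    median: float = float("nan")
    min: float = float("nan")
    max: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    mean_ci_low: float = float("nan")
    mean_ci_high: float = float("nan")
    n_participants: int = 0
    n_undefined: int = 0


def pair_days(classifications: pd.DataFrame,
              ema_records: Iterable[EmaRecord]) -> pd.DataFrame:
    """Join day classifications with EMA responses into daily outcomes.

    ``classifications`` needs columns participant_id, day_date, exercise,
    valid.  The result has one row per (participant, day) present in either
    source; ``accel_exercise`` is NaN on invalid days, ``ema_exercise`` is
    NaN when the response is missing, and ``included`` is true only when
    both are present.
    """
    accel = classifications[["participant_id", "day_date", "exercise",
                             "valid"]].copy()
    accel["accel_exercise"] = np.where(accel["valid"],
                                       accel["exercise"].astype(float),
                                       np.nan)
    accel = accel[["participant_id", "day_date", "accel_exercise"]]

    ema_rows = [(r.participant_id, r.report_date,
                 1.0 if r.response == "yes" else
                 0.0 if r.response == "no" else np.nan)
                for r in ema_records]
    ema = pd.DataFrame(ema_rows, columns=["participant_id", "day_date",
                                          "ema_exercise"])
    out = accel.merge(ema, on=["participant_id", "day_date"], how="outer")
    out["included"] = out["accel_exercise"].notna() & out["ema_exercise"].notna()
    return out.sort_values(["participant_id", "day_date"]).reset_index(drop=True)


def contingency(outcomes: pd.DataFrame) -> ContingencyTable:
    """Tally included days of one participant into a 2x2 table."""
    inc = outcomes[outcomes["included"]]
    e = inc["ema_exercise"].to_numpy() > 0.5
    acc = inc["accel_exercise"].to_numpy() > 0.5
    return ContingencyTable(
        a=int((e & acc).sum()), b=int((e & ~acc).sum()),
        c=int((~e & acc).sum()), d=int((~e & ~acc).sum()))


def cohen_kappa(t: ContingencyTable) -> KappaResult:
    """Cohen's kappa of a 2x2 table.

    p_o = (a+d)/n; with marginals r = (a+b)/n and s = (a+c)/n,
    p_e = r*s + (1-r)(1-s).  The result is flagged undefined when there are
    no included days, when p_e = 1, or when either measure is constant
    (a degenerate, uninformative table).
    """
    n = t.n
    if n == 0:
        return KappaResult(n=0, undefined=True, reason="no included days")
    p_o = (t.a + t.d) / n
    r = (t.a + t.b) / n
    s = (t.a + t.c) / n
    p_e = r * s + (1 - r) * (1 - s)
    if p_e >= 1.0:
        return KappaResult(p_o=p_o, p_e=p_e, n=n, undefined=True,
                           reason="chance agreement is 1 (both measures constant)")
    if r in (0.0, 1.0) or s in (0.0, 1.0):
        return KappaResult(p_o=p_o, p_e=p_e, n=n, undefined=True,
                           reason="one measure constant across days")
    return KappaResult(kappa=(p_o - p_e) / (1 - p_e), p_o=p_o, p_e=p_e, n=n)


def _fce_variance(p: np.ndarray, n: int) -> float:
    """Fleiss-Cohen-Everitt large-sample variance of kappa.

    ``p`` is the k x k joint-proportion matrix.  With row marginals p_i.,
    column marginals p_.j, observed agreement p_o = sum_i p_ii and chance
    agreement p_e = sum_i p_i. * p_.i:

    Var = [ sum_i p_ii ((1-p_e) - (p_.i + p_i.)(1-p_o))^2
          + (1-p_o)^2 sum_{i != j} p_ij (p_.i + p_j.)^2
          - (p_o p_e - 2 p_e + p_o)^2 ] / (n (1-p_e)^4)
    """
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    k = p.shape[0]
    term1 = sum(p[i, i] * ((1 - p_e) - (col[i] + row[i]) * (1 - p_o)) ** 2
                for i in range(k))
    term2 = (1 - p_o) ** 2 * sum(p[i, j] * (col[i] + row[j]) ** 2
                                 for i in range(k) for j in range(k) if i != j)
    term3 = (p_o * p_e - 2 * p_e + p_o) ** 2
    return (term1 + term2 - term3) / (n * (1 - p_e) ** 4)


def pooled_kappa(tables: Iterable[ContingencyTable]) -> KappaResult:
    """Kappa of the element-wise summed table, with asymptotic SE."""
    total = ContingencyTable()
    for t in tables:
        total = total + t
    res = cohen_kappa(total)
    if not res.undefined:
        var = _fce_variance(total.as_matrix() / total.n, total.n)
        res.se = float(np.sqrt(max(var, 0.0)))
    return res


def bootstrap_pooled_se(t: ContingencyTable, n_boot: int = 2000,
                        seed: int = 0) -> float:
    """Nonparametric day-resampling SE of the pooled kappa (cross-check for
    the asymptotic formula)."""
    rng = np.random.default_rng(seed)
    probs = np.array([t.a, t.b, t.c, t.d], dtype=float) / t.n
    draws = rng.multinomial(t.n, probs, size=n_boot)
    kappas = np.full(n_boot, np.nan)
    for i, (a, b, c, d) in enumerate(draws):
        r = cohen_kappa(ContingencyTable(int(a), int(b), int(c), int(d)))
        if not r.undefined:
            kappas[i] = r.kappa
    return float(np.nanstd(kappas, ddof=1))


def summarize_kappas(results: Sequence[KappaResult], seed: int = 0,
                     n_boot: int = 2000) -> KappaSummary:
    """Moments and CIs of the defined per-participant kappas.

    Mean CI: t-interval.  Median CI: seeded percentile bootstrap over
    participants.  Undefined kappas are excluded and counted.
    """
    vals = np.array([r.kappa for r in results if not r.undefined], dtype=float)
    n_undef = sum(1 for r in results if r.undefined)
    out = KappaSummary(n_participants=len(vals), n_undefined=n_undef)
    if len(vals) == 0:
        return out
    out.mean = float(vals.mean())
    out.median = float(np.median(vals))
    out.min = float(vals.min())
    out.max = float(vals.max())
    if len(vals) > 1:
        out.sd = float(vals.std(ddof=1))
        sem = out.sd / np.sqrt(len(vals))
        tcrit = stats.t.ppf(0.975, df=len(vals) - 1)
        out.mean_ci_low = out.mean - tcrit * sem
        out.mean_ci_high = out.mean + tcrit * sem
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        med = np.median(vals[idx], axis=1)
        out.ci_low = float(np.percentile(med, 2.5))
        out.ci_high = float(np.percentile(med, 97.5))
    else:
        out.sd = float("nan")
        out.ci_low = out.ci_high = out.median
        out.mean_ci_low = out.mean_ci_high = out.mean
    return out


def per_participant_kappas(outcomes: pd.DataFrame,
                           min_days: int = 1
                           ) -> dict[str, tuple[ContingencyTable, KappaResult]]:
    """Contingency table and kappa for every participant with at least
    ``min_days`` included days."""
    out: dict[str, tuple[ContingencyTable, KappaResult]] = {}
    for pid, grp in outcomes.groupby("participant_id", sort=True):
        table = contingency(grp)
        if table.n < min_days:
            continue
        out[str(pid)] = (table, cohen_kappa(table))
    return out


def analyze(outcomes: pd.DataFrame, min_days: int = 1,
            seed: int = 0) -> dict:
    """Full agreement report: per-participant kappas, pooled kappa with SE,
    and the cross-participant summary, as a JSON-serializable dict."""
    per = per_participant_kappas(outcomes, min_days=min_days)
    tables = [t for t, _ in per.values()]
    pooled = pooled_kappa(tables) if tables else KappaResult(
        undefined=True, reason="no included days")
    summary = summarize_kappas([r for _, r in per.values()], seed=seed)
    return {
        "per_participant": [
            {"id": pid, "kappa": None if r.undefined else r.kappa,
             "undefined_reason": r.reason, "n": t.n,
             "a": t.a, "b": t.b, "c": t.c, "d": t.d}
            for pid, (t, r) in per.items()],
        "pooled": {"kappa": None if pooled.undefined else pooled.kappa,
                   "se": pooled.se, "n": pooled.n},
        "summary": {"mean": summary.mean, "sd": summary.sd,
                    "median": summary.median, "min": summary.min,
                    "max": summary.max,
                    "ci_low": summary.ci_low, "ci_high": summary.ci_high,
                    "mean_ci_low": summary.mean_ci_low,
                    "mean_ci_high": summary.mean_ci_high,
                    "n_participants": summary.n_participants,
                    "n_undefined": summary.n_undefined},
    }


def sweep_agreement(sweep_classifications: pd.DataFrame,
                    ema_records: Iterable[EmaRecord],
                    min_days: int = 1, seed: int = 0) -> pd.DataFrame:
    """Kappa summaries for every (intensity set, m) of a definition sweep.

    ``sweep_classifications`` is the long frame from
    :func:`concord.bout_detection.sweep_definitions`.  Day inclusion depends
    only on validity and the EMA response, so the pooled n is constant
    across rows.  One row per (set, m): mean/median kappa with CIs, pooled
    kappa with SE, participant and day counts.
    """
    ema_records = list(ema_records)
    rows = []
    for (label, m), grp in sweep_classifications.groupby(
            ["intensity_set", "m"], sort=True):
        outcomes = pair_days(grp, ema_records)
        per = per_participant_kappas(outcomes, min_days=min_days)
        tables = [t for t, _ in per.values()]
        pooled = pooled_kappa(tables) if tables else KappaResult(undefined=True)
        summary = summarize_kappas([r for _, r in per.values()], seed=seed)
        rows.append({
            "intensity_set": label, "m": m,
            "mean_kappa": summary.mean, "sd_kappa": summary.sd,
            "median_kappa": summary.median,
            "ci_low": summary.ci_low, "ci_high": summary.ci_high,
            "pooled_kappa": np.nan if pooled.undefined else pooled.kappa,
            "pooled_se": pooled.se if pooled.se is not None else np.nan,
            "n_participants": summary.n_participants,
            "n_days": pooled.n,
        })
    return pd.DataFrame(rows)
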