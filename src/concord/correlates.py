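"""Person-level correlates of agreement: OLS screens of kappa on covariates.

Each participant contributes one observation: their kappa regressed on
demographics (age, sex, BMI, race, ethnicity, education, partner,
caregiver), mean perceived stress, health-tech use, and the percentage of
included days with exercise by each measure plus squared terms (centered
before squaring to limit collinearity).  Univariate screens run one simple
regression per predictor; the multivariate model either keeps only the
univariately significant predictors (default) or adjusts for every
predictor at once — both modes exist because either reading of the analysis
plan is defensible, and every output row is labeled with its model.

Fits go through statsmodels OLS; p-values are two-sided t tests.  No
multiple-testing correction is applied to the primary columns; a
Benjamini-Hochberg adjusted column is appended to the univariate output as
clearly-labeled supplementary information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

PREDICTORS = ["age", "female", "bmi", "black", "hispanic", "grad_degree",
              "partner", "caregiver", "mean_stress", "tech_use",
              "pct_days_ema", "pct_days_accel",
              "pct_days_ema_sq", "pct_days_accel_sq"]


@dataclass
class RegressionRow:
    predictor: str
    beta: float = float("nan")
    se: float = float("nan")
    p: float = float("nan")
    n: int = 0
    model: str = "univariate"
    undefined: bool = False
    reason: Optional[str] = None


def build_design(covariates: pd.DataFrame,
                 outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-participant predictor matrix.

    ``covariates`` is indexed by participant_id (see
    :func:`concord.io_formats.covariates_frame`); ``outcomes`` is the daily
    outcome table.  Adds pct_days_ema / pct_days_accel on the 0-100 scale
    over each participant's *included* days, and their squares computed
    after mean-centering.  Participants with no included days are dropped.
    """
    inc = outcomes[outcomes["included"]]
    if len(inc) == 0:
        raise ValueError("no included participant-days; cannot build design")
    grp = inc.groupby("participant_id")
    pct = pd.DataFrame({
        "pct_days_ema": grp["ema_exercise"].mean() * 100.0,
        "pct_days_accel": grp["accel_exercise"].mean() * 100.0,
        "n_included_days": grp.size(),
    })
    design = covariates.join(pct, how="inner")
    for col in ("pct_days_ema", "pct_days_accel"):
        centered = design[col] - design[col].mean()
        design[col + "_sq"] = centered ** 2
    design.index = design.index.astype(str)
    return design.sort_index()


def _fit_ols(y: np.ndarray, X: pd.DataFrame, model_label: str
             ) -> list[RegressionRow]:
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    rows = []
    for name in X.columns:
        rows.append(RegressionRow(
            predictor=name, beta=float(fit.params[name]),
            se=float(fit.bse[name]), p=float(fit.pvalues[name]),
            n=int(fit.nobs), model=model_label))
    return rows


def univariate_screen(kappas: pd.Series, design: pd.DataFrame,
                      predictors: Sequence[str] = PREDICTORS
                      ) -> list[RegressionRow]:
    """One simple OLS regression of kappa per predictor.

    Listwise deletion per predictor; a predictor with zero variance or
    fewer than 3 complete participants yields an undefined row.  A BH
    false-discovery-rate adjusted p (``p_bh``, supplementary) is attached to
    each defined row.
    """
    rows: list[RegressionRow] = []
    for name in predictors:
        if name not in design.columns:
            rows.append(RegressionRow(predictor=name, undefined=True,
                                      reason="predictor not in design"))
            continue
        sub = pd.DataFrame({"kappa": kappas, name: design[name]}).dropna()
        if len(sub) < 3:
            rows.append(RegressionRow(predictor=name, undefined=True,
                                      reason="fewer than 3 participants",
                                      n=len(sub)))
            continue
        if np.isclose(sub[name].std(ddof=0), 0.0):
            rows.append(RegressionRow(predictor=name, undefined=True,
                                      reason="zero-variance predictor",
                                      n=len(sub)))
            continue
        rows.extend(_fit_ols(sub["kappa"].to_numpy(), sub[[name]],
                             "univariate"))
    defined = [r for r in rows if not r.undefined]
    if defined:
        _, p_bh, _, _ = multipletests([r.p for r in defined], method="fdr_bh")
        for r, pb in zip(defined, p_bh):
            r.p_bh = float(pb)  # supplementary column, labeled as such in output
    return rows


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that make the design rank deficient (warn per drop)."""
    keep: list[str] = []
    for col in X.columns:
        candidate = X[keep + [col]].to_numpy(dtype=float)
        aug = np.column_stack([np.ones(len(X)), candidate])
        if np.linalg.matrix_rank(aug) == aug.shape[1]:
            keep.append(col)
        else:
            warnings.warn(f"dropping collinear predictor '{col}' from "
                          "multivariate model", stacklevel=3)
    return X[keep]


def multivariate_model(kappas: pd.Series, design: pd.DataFrame,
                       mode: str = "significant_only",
                       predictors: Sequence[str] = PREDICTORS,
                       alpha: float = 0.05,
                       univariate: Optional[list[RegressionRow]] = None
                       ) -> list[RegressionRow]:
    """Multivariate OLS of kappa on a predictor set.

    mode="significant_only": keep predictors univariately significant at
    ``alpha`` (the screen is run here if not supplied).
    mode="all_covariates": adjust for every available predictor at once.
    Listwise deletion across the selected set; collinear duplicates are
    dropped with a warning.
    """
    if mode not in ("significant_only", "all_covariates"):
        raise ValueError(f"unknown mode '{mode}'")
    label = ("multivariate_significant" if mode == "significant_only"
             else "multivariate_all")
    if mode == "significant_only":
        uni = univariate if univariate is not None else univariate_screen(
            kappas, design, predictors)
        selected = [r.predictor for r in uni
                    if not r.undefined and r.p < alpha]
        if not selected:
            return []
    else:
        selected = [p for p in predictors if p in design.columns]

    sub = design[selected].copy()
    sub["kappa"] = kappas
    sub = sub.dropna()
    X = _drop_collinear(sub[selected])
    if len(sub) <= X.shape[1] + 1:
        raise ValueError("insufficient participants for multivariate fit "
                         f"(n={len(sub)}, predictors={X.shape[1]})")
    return _fit_ols(sub["kappa"].to_numpy(), X, label)


def rows_frame(rows: Sequence[RegressionRow]) -> pd.DataFrame:
    """Regression rows as the correlates CSV frame."""
    return pd.DataFrame([{
        "predictor": r.predictor, "beta": r.beta, "se": r.se, "p": r.p,
        "n": r.n, "model": r.model,
        "p_bh": getattr(r, "p_bh", np.nan),
        "undefined": r.undefined, "reason": r.reason,
    } for r in rows])
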