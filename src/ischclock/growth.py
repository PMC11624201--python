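"""Infarct-expansion analysis: % growth, baseline multiregression, and the
added value of lesion-age estimates.

Percent lesion growth between two scans is regressed on six baseline
predictors (volume at t1, inter-scan interval, NIHSS, age, sex,
thrombolysis); a candidate lesion-age column (entered as its natural log)
is then added and its coefficient, t statistic and the Spearman correlation
between baseline-model residuals and the age estimate quantify the added
predictive value. Competing age estimates are compared by a Z test on their
regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .fusion_eval import compare_slopes_z

__all__ = ["percent_growth", "edema_correct", "fit_growth_baseline",
           "added_value", "BASELINE_PREDICTORS", "GrowthFit", "AddedValue"]

BASELINE_PREDICTORS = ("v1", "interval", "nihss", "age", "sex", "lysis")


def percent_growth(v1: float, v2: float) -> float:
    """100 * (v2 - v1) / v1; negative values are shrinkage."""
    if v1 <= 0:
        raise ValueError("v1 must be positive")
    return 100.0 * (v2 - v1) / v1


def edema_correct(v2: float, correction=None) -> float:
    """Corrected follow-up volume. ``correction`` is None (identity), a
    multiplicative factor, or a callable; the default is identity since
    conclusions are insensitive to the correction."""
    if correction is None:
        out = float(v2)
    elif callable(correction):
        out = float(correction(v2))
    else:
        out = float(correction) * float(v2)
    if out < 0:
        raise ValueError("corrected volume is negative")
    return out


@dataclass
class GrowthFit:
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    resid: np.ndarray
    df_resid: int
    model: object


def _design(records: pd.DataFrame, extra: list[str] = ()) -> pd.DataFrame:
    cols = list(BASELINE_PREDICTORS) + list(extra)
    X = records[cols].astype(float)
    return sm.add_constant(X)


def fit_growth_baseline(records: pd.DataFrame,
                        outcome: str = "pct_growth") -> GrowthFit:
    """OLS of % growth on the six baseline predictors."""
    n = len(records)
    if n <= len(BASELINE_PREDICTORS) + 2:
        raise ValueError("too few records for the baseline model")
    X = _design(records)
    if np.linalg.cond(X.to_numpy()) > 1e6:
        raise ValueError("collinear predictors (condition number > 1e6)")
    fit = sm.OLS(records[outcome].astype(float), X).fit()
    return GrowthFit(fit.params, fit.tvalues, fit.pvalues, fit.bse,
                     np.asarray(fit.resid), int(fit.df_resid), fit)


@dataclass
class AddedValue:
    age_column: str
    coefficient: float
    se: float
    t: float
    p: float
    residual_rho: float
    residual_rho_p: float


def added_value(records: pd.DataFrame, age_column: str,
                outcome: str = "pct_growth",
                baseline: GrowthFit | None = None) -> AddedValue:
    """Effect of adding log(age estimate) to the baseline model.

    Reports the added coefficient with its t/p, plus the Spearman rho
    between standardized baseline residuals and the log age estimate.
    """
    ages = records[age_column].astype(float)
    if ages.nunique() <= 1:
        raise ValueError(f"constant age column {age_column!r}")
    if (ages <= 0).any():
        raise ValueError("age estimates must be positive hours")
    base = baseline or fit_growth_baseline(records, outcome)
    log_age = np.log(ages.to_numpy())
    rec = records.copy()
    rec["_log_age"] = log_age
    X = _design(rec, ["_log_age"])
    fit = sm.OLS(rec[outcome].astype(float), X).fit()
    std_resid = base.resid / base.resid.std()
    rho, rho_p = stats.spearmanr(std_resid, log_age)
    return AddedValue(
        age_column=age_column,
        coefficient=float(fit.params["_log_age"]),
        se=float(fit.bse["_log_age"]),
        t=float(fit.tvalues["_log_age"]),
        p=float(fit.pvalues["_log_age"]),
        residual_rho=float(rho),
        residual_rho_p=float(rho_p),
    )


def compare_added_values(a: AddedValue, b: AddedValue):
    """Z test on two added-age coefficients -> (Z, p)."""
    return compare_slopes_z(a.coefficient, a.se, b.coefficient, b.se)
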