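"""CNN-radiomics fusion, the calibration-split protocol, and evaluation
statistics.

The fused lesion-age model ("CNN-R") is one Gaussian-process regression of
log onset-to-scan (OTS) on the CNN's log-OTS estimate concatenated with the
selected radiomic features. Evaluation follows a calibration-split protocol:
the held-out set is split in half, one half refits ("calibrates") the GPR
output model, the other half is scored, and vice versa; metrics are averaged
over repeated random splits. Comparison statistics mirror standard practice
for correlated models evaluated on one cohort: partial F for nested R^2,
Fisher-Z for correlations, DeLong for paired AUROCs, McNemar for paired
classification accuracy, and a coefficient Z test for regression slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
import statsmodels.api as sm

__all__ = [
    "FusionModel", "EvalReport", "fit_fusion", "family_columns",
    "calibration_split_evaluate", "r2_rmse", "time_window_metrics",
    "auroc", "auroc_delong", "compare_correlations_fisher",
    "compare_r2_ftest", "mcnemar", "error_vs_time_regression",
    "compare_slopes_z", "DEFAULT_WINDOWS",
]

#: boundaries (hours) of the four consecutive time windows
DEFAULT_WINDOWS = (4.5, 9.0, 24.0)


def _gpr(seed: int = 0, n_restarts: int = 1) -> GaussianProcessRegressor:
    kernel = ConstantKernel(1.0) * RBF(1.0) + WhiteKernel(0.5)
    return GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                    n_restarts_optimizer=n_restarts,
                                    random_state=seed)


@dataclass
class FusionModel:
    """GPR over [cnn log-OTS estimate, selected radiomic features]."""

    feature_names: list[str]
    seed: int = 0
    _est: GaussianProcessRegressor = None
    _mu: np.ndarray = None
    _sd: np.ndarray = None

    def _design(self, cnn_log, feats: pd.DataFrame | None) -> np.ndarray:
        cols = [np.asarray(cnn_log, dtype=float).reshape(-1, 1)]
        if self.feature_names:
            if feats is None or any(c not in feats.columns
                                    for c in self.feature_names):
                raise ValueError("feature table does not match fitted schema")
            cols.append(feats[self.feature_names].to_numpy(dtype=float))
        return np.hstack(cols)

    def fit(self, cnn_log, feats, ots_hours) -> "FusionModel":
        ots = np.asarray(ots_hours, dtype=float)
        if np.any(ots <= 0):
            raise ValueError("ots must be positive")
        Z = self._design(cnn_log, feats)
        self._mu = Z.mean(axis=0)
        sd = Z.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._est = _gpr(self.seed)
        self._est.fit((Z - self._mu) / self._sd, np.log(ots))
        return self

    def predict_log(self, cnn_log, feats) -> np.ndarray:
        Z = self._design(cnn_log, feats)
        return self._est.predict((Z - self._mu) / self._sd)


def fit_fusion(cnn_est_log, feats: pd.DataFrame | None, ots_hours,
               seed: int = 0) -> FusionModel:
    """Fit the fused GPR; with an empty feature table this reduces to a GPR
    recalibration of the CNN estimate alone."""
    names = list(feats.columns) if feats is not None else []
    return FusionModel(names, seed=seed).fit(cnn_est_log, feats, ots_hours)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def r2_rmse(pred_log, true_hours) -> tuple[float, float]:
    """R^2 on the log-hour scale; RMSE in minutes on the raw scale."""
    pred_log = np.asarray(pred_log, dtype=float)
    true = np.asarray(true_hours, dtype=float)
    if pred_log.size != true.size or true.size < 2:
        raise ValueError("need aligned arrays with n >= 2")
    lt = np.log(true)
    sst = ((lt - lt.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("zero variance in true ages")
    r2 = 1.0 - ((lt - pred_log) ** 2).sum() / sst
    rmse_min = float(np.sqrt(((np.exp(pred_log) - true) ** 2).mean()) * 60.0)
    return float(r2), rmse_min


def _window_of(hours: np.ndarray, bounds=DEFAULT_WINDOWS) -> np.ndarray:
    return np.searchsorted(np.asarray(bounds, dtype=float), hours, side="left")


def time_window_metrics(pred_hours, true_hours, bounds=DEFAULT_WINDOWS) -> dict:
    """Per-window one-vs-rest F1 and accuracy, plus prevalence-weighted means.

    Windows partition (0, inf) at ``bounds``. A window absent from the truth
    has undefined F1, reported as None and excluded from the weighted mean.
    """
    pred_w = _window_of(np.asarray(pred_hours, dtype=float), bounds)
    true_w = _window_of(np.asarray(true_hours, dtype=float), bounds)
    n_win = len(bounds) + 1
    f1s, accs, counts = [], [], []
    for w in range(n_win):
        t = true_w == w
        p = pred_w == w
        counts.append(int(t.sum()))
        accs.append(float((t == p).mean()))
        if not t.any():
            f1s.append(None)
            continue
        tp = float((t & p).sum())
        denom = t.sum() + p.sum()
        f1s.append(2.0 * tp / denom if denom else 0.0)
    cnt = np.asarray(counts, dtype=float)
    have = np.asarray([f is not None for f in f1s])
    wf1 = (float(np.sum([f * c for f, c in zip(f1s, cnt) if f is not None])
                 / cnt[have].sum()) if have.any() else None)
    wacc = float((np.asarray(accs) * cnt).sum() / cnt.sum())
    return dict(f1=f1s, accuracy=accs, counts=counts,
                weighted_f1=wf1, weighted_accuracy=wacc)


# ---------------------------------------------------------------------------
# calibration-split protocol
# ---------------------------------------------------------------------------

#: predictor columns per model family (feature columns appended for the
#: radiomics-bearing families)
_FAMILIES = ("ri_linear", "ri_gpr", "radiomics", "cnn", "cnn_r")


def family_columns(family: str, feature_cols) -> tuple[list[str], str]:
    """(predictor column names, estimator kind) for a model family."""
    if family == "ri_linear":
        return ["ri"], "linear"
    if family == "ri_gpr":
        return ["ri"], "gpr"
    if family == "radiomics":
        return list(feature_cols), "gpr"
    if family == "cnn":
        return ["cnn_log"], "gpr"
    if family == "cnn_r":
        return ["cnn_log"] + list(feature_cols), "gpr"
    raise ValueError(f"unknown model family {family!r}")


def _fit_family(table: pd.DataFrame, cols, kind, seed) -> object:
    Z = table[cols].to_numpy(dtype=float)
    mu, sd = Z.mean(axis=0), Z.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    est = LinearRegression() if kind == "linear" else _gpr(seed)
    est.fit((Z - mu) / sd, np.log(table["ots"].to_numpy(dtype=float)))
    return est, mu, sd


def _predict_family(model, table: pd.DataFrame, cols) -> np.ndarray:
    est, mu, sd = model
    return est.predict((table[cols].to_numpy(dtype=float) - mu) / sd)


@dataclass
class EvalReport:
    family: str
    r2: float
    rmse_minutes: float
    window_f1: list
    window_accuracy: list
    weighted_f1: float
    weighted_accuracy: float
    n: int
    n_splits: int
    split_seed: int
    per_split_r2: list = field(default_factory=list)


def calibration_split_evaluate(
    test_table: pd.DataFrame,
    family: str,
    feature_cols=(),
    calib_size: int | None = None,
    n_splits: int = 20,
    seed: int = 0,
    prior_model=None,
    bounds=DEFAULT_WINDOWS,
) -> EvalReport:
    """Split-calibrate-test protocol on a held-out table.

    ``test_table`` needs columns ``ots``, plus ``ri`` / ``cnn_log`` /
    radiomic feature columns as required by the family. Default protocol:
    each random split divides the set in half, each half calibrates a model
    scored on the other (both directions pooled), and metrics are averaged
    over ``n_splits`` splits. With ``calib_size`` given, that many subjects
    calibrate and the remainder are scored; ``calib_size=0`` scores the
    supplied training-phase ``prior_model`` on the full set.
    """
    n = len(test_table)
    cols, kind = family_columns(family, feature_cols)
    if calib_size is not None and calib_size >= n:
        raise ValueError("calib_size must be smaller than the test set")
    if calib_size == 0 and prior_model is None:
        raise ValueError("calib_size=0 requires a prior model")
    if calib_size is None and n < 4:
        raise ValueError("need >= 4 subjects for half-splits")
    rng = np.random.default_rng(seed)
    reports, per_r2 = [], []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        pred_log = np.full(n, np.nan)
        if calib_size == 0:
            pred_log = _predict_family(prior_model, test_table, cols)
        elif calib_size is None:
            half = n // 2
            a, b = perm[:half], perm[half:]
            for cal, tst in ((a, b), (b, a)):
                model = _fit_family(test_table.iloc[cal], cols, kind, seed)
                pred_log[tst] = _predict_family(
                    model, test_table.iloc[tst], cols)
        else:
            cal, tst = perm[:calib_size], perm[calib_size:]
            model = _fit_family(test_table.iloc[cal], cols, kind, seed)
            pred_log[tst] = _predict_family(model, test_table.iloc[tst], cols)
        sel = ~np.isnan(pred_log)
        true = test_table["ots"].to_numpy(dtype=float)[sel]
        r2, rmse = r2_rmse(pred_log[sel], true)
        win = time_window_metrics(np.exp(pred_log[sel]), true, bounds)
        reports.append((r2, rmse, win))
        per_r2.append(r2)

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    n_win = len(bounds) + 1
    return EvalReport(
        family=family,
        r2=_mean([r[0] for r in reports]),
        rmse_minutes=_mean([r[1] for r in reports]),
        window_f1=[_mean([r[2]["f1"][w] for r in reports])
                   for w in range(n_win)],
        window_accuracy=[_mean([r[2]["accuracy"][w] for r in reports])
                         for w in range(n_win)],
        weighted_f1=_mean([r[2]["weighted_f1"] for r in reports]),
        weighted_accuracy=_mean([r[2]["weighted_accuracy"] for r in reports]),
        n=n, n_splits=n_splits, split_seed=seed, per_split_r2=per_r2,
    )


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels]
    neg = scores[~labels]
    m, k = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * k)
    v10 = (tz[:m] - tx) / k
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def auroc(scores, labels) -> float:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return float(_delong_components(np.asarray(scores, float), labels)[0])


def auroc_delong(scores_a, scores_b, labels):
    """Paired-sample DeLong test for two correlated AUROCs.

    Returns (auc_a, auc_b, Z, two-sided p).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    auc_a, v10a, v01a = _delong_components(sa, labels)
    auc_b, v10b, v01b = _delong_components(sb, labels)
    m, k = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    S = s10 / m + s01 / k
    var = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    if var <= 0:
        z = 0.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


def compare_correlations_fisher(r1: float, n1: int, r2: float, n2: int):
    """Fisher-Z comparison of two independent correlations -> (Z, p)."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("n must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def compare_r2_ftest(r2_small: float, r2_large: float, n: int,
                     p_small: int, p_large: int):
    """Partial F test for nested models from their R^2 values.

    ``p_*`` are predictor counts (excluding intercept); returns (F, (df1,
    df2), p). The smaller model must be nested in the larger.
    """
    df1 = p_large - p_small
    df2 = n - p_large - 1
    if df1 <= 0 or df2 <= 0:
        raise ValueError("invalid degrees of freedom: models must be nested")
    if r2_large < r2_small - 1e-12:
        raise ValueError("larger model has smaller R^2: models are not nested")
    F = ((r2_large - r2_small) / df1) / ((1.0 - r2_large) / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def mcnemar(correct_a, correct_b):
    """Continuity-corrected McNemar test on paired correctness indicators.

    chi2 = (|b - c| - 1)^2 / (b + c) over the discordant counts.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.size != b.size:
        raise ValueError("arrays must align")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    if n01 + n10 == 0:
        raise ValueError("no discordant pairs: McNemar undefined")
    table = [[int((a & b).sum()), n10], [n01, int((~a & ~b).sum())]]
    res = _sm_mcnemar(table, exact=False, correction=True)
    return float(res.statistic), float(res.pvalue)


def error_vs_time_regression(abs_err_minutes, ots_hours):
    """OLS of absolute error (minutes) on OTS (hours).

    Returns (slope, (ci_lo, ci_hi), se): minutes of error per hour of OTS.
    """
    err = np.asarray(abs_err_minutes, dtype=float)
    ots = np.asarray(ots_hours, dtype=float)
    if err.size < 10:
        raise ValueError("need n >= 10")
    if np.std(ots) == 0:
        raise ValueError("zero OTS variance")
    X = sm.add_constant(ots)
    fit = sm.OLS(err, X).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    lo, hi = fit.conf_int()[1]
    return slope, (float(lo), float(hi)), se


def compare_slopes_z(slope1: float, se1: float, slope2: float, se2: float):
    """Z test on two regression coefficients -> (Z, p)."""
    z = (slope1 - slope2) / np.sqrt(se1 ** 2 + se2 ** 2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
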