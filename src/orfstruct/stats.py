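"""Correlation, bootstrap, ROC, stepwise-regression and outlier machinery.

Spearman correlations use average ranks for ties (bacterial count data tie
frequently); confidence intervals are case-resampling percentile bootstrap.
Regressions are on log TE, which spans roughly two orders of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.anova import anova_lm


def _row_spearman(x_rows: np.ndarray, y_rows: np.ndarray) -> np.ndarray:
    """Spearman rho per row of two equally-shaped matrices (vectorized)."""
    xr = sps.rankdata(x_rows, axis=1)
    yr = sps.rankdata(y_rows, axis=1)
    xr = xr - xr.mean(axis=1, keepdims=True)
    yr = yr - yr.mean(axis=1, keepdims=True)
    num = (xr * yr).sum(axis=1)
    den = np.sqrt((xr**2).sum(axis=1) * (yr**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


@dataclass
class SpearmanBootstrap:
    rho: float
    ci_low: float
    ci_high: float
    distribution: np.ndarray

    @property
    def ci(self) -> tuple[float, float]:
        return self.ci_low, self.ci_high


def spearman_bootstrap(
    x: np.ndarray,
    y: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> SpearmanBootstrap:
    """Spearman rho with a case-resampling percentile bootstrap CI.

    Resamples with NaN rho (e.g. a constant resample) are dropped from the
    bootstrap distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 5:
        raise ValueError("need n >= 5")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = float(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    dist = _row_spearman(x[idx], y[idx])
    dist = dist[np.isfinite(dist)]
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(dist, [tail, 1.0 - tail])
    return SpearmanBootstrap(rho=rho, ci_low=float(lo), ci_high=float(hi),
                             distribution=dist)


def ks_compare_rho(boot1: np.ndarray, boot2: np.ndarray) -> tuple[float, float]:
    """Two-sample K-S comparison of two bootstrap rho distributions."""
    b1, b2 = np.asarray(boot1), np.asarray(boot2)
    if b1.size == 0 or b2.size == 0:
        raise ValueError("empty bootstrap distribution")
    res = sps.ks_2samp(b1, b2)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_tested: int
    signal: np.ndarray
    labels: np.ndarray  # 1 = unpaired & accessible, 0 = paired

    def accuracy(self, threshold: float) -> float:
        """(TP + TN) / all tested at a signal threshold: predicted unpaired
        when signal > threshold."""
        pred = self.signal > threshold
        correct = (pred & (self.labels == 1)) | (~pred & (self.labels == 0))
        return float(correct.mean())


def roc_reference(
    signal: np.ndarray,
    paired: np.ndarray,
    accessible: np.ndarray,
    is_ac: np.ndarray | None = None,
) -> RocResult:
    """ROC of probing signal against a reference structure.

    Tested bases (A/C only when ``is_ac`` is given): positives are unpaired
    AND solvent-accessible; negatives are paired; unpaired-but-buried bases
    are excluded, since a probe could legitimately miss them.
    """
    signal = np.asarray(signal, dtype=float)
    paired = np.asarray(paired, dtype=bool)
    accessible = np.asarray(accessible, dtype=bool)
    mask = np.ones_like(paired) if is_ac is None else np.asarray(is_ac, dtype=bool)
    positive = mask & ~paired & accessible
    negative = mask & paired
    tested = positive | negative
    if positive.sum() == 0 or negative.sum() == 0:
        raise ValueError("single-class reference: AUC undefined")
    y = positive[tested].astype(int)
    s = signal[tested]
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=float(roc_auc_score(y, s)),
        n_tested=int(tested.sum()), signal=s, labels=y,
    )


def _signif_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def stepwise_te_regression(
    features: pd.DataFrame,
    te: np.ndarray | pd.Series,
    log_te: bool = True,
    condition_warn: float = 1e6,
) -> pd.DataFrame:
    """R^2 trajectory of nested least-squares models on (log) TE.

    Features are added in column order; each addition is scored by the
    nested-model ANOVA F-test.  Zero-variance features are rejected with a
    warning; an ill-conditioned design triggers a condition-number warning.
    """
    y = np.asarray(te, dtype=float)
    if log_te:
        if (y <= 0).any():
            raise ValueError("TE must be positive for log regression")
        y = np.log(y)
    keep = []
    for col in features.columns:
        if np.ptp(features[col].to_numpy(dtype=float)) == 0:
            warnings.warn(f"feature {col!r} has zero variance; rejected")
        else:
            keep.append(col)
    if len(y) < 10 * max(1, len(keep)):
        raise ValueError("need >= 10 complete cases per feature")
    rows = []
    prev_fit = None
    for k, col in enumerate(keep):
        X = sm.add_constant(features[keep[: k + 1]].to_numpy(dtype=float))
        fit = sm.OLS(y, X).fit()
        if np.linalg.cond(X) > condition_warn:
            warnings.warn(f"ill-conditioned design after adding {col!r}")
        if prev_fit is None:
            # F-test of the first factor against the intercept-only model
            p = float(fit.f_pvalue)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = anova_lm(prev_fit, fit)
            p = float(table["Pr(>F)"].iloc[1])
        rows.append(
            {"step": k + 1, "feature": col, "r_squared": float(fit.rsquared),
             "anova_p": p, "signif": _signif_code(p)}
        )
        prev_fit = fit
    return pd.DataFrame(rows)


def outlier_test(
    x: np.ndarray,
    y: np.ndarray,
    candidate: object,
    ids: list | np.ndarray | None = None,
) -> float:
    """Bonferroni-adjusted outlier p-value of one point in an x-y regression.

    Externally studentized residual from OLS of y on x; the two-sided p is
    multiplied by n and capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need n >= 10")
    labels = np.arange(x.size) if ids is None else np.asarray(ids, dtype=object)
    where = np.flatnonzero(labels == candidate)
    if where.size != 1:
        raise ValueError(f"candidate {candidate!r} not found (or duplicated)")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    table = fit.outlier_test(method="bonf")
    if hasattr(table, "iloc"):  # DataFrame for pandas inputs
        bonf = np.asarray(table["bonf(p)"])
    else:  # plain array: [studentized residual, unadjusted p, bonferroni p]
        bonf = np.asarray(table)[:, 2]
    return float(min(bonf[where[0]], 1.0))
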