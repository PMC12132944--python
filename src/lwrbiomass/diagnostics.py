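"""Concordance statistics between estimated and field-measured weights.

Two coefficients of determination score each point set:

* ``r2_regression`` — the usual OLS R-squared of measured on estimated;
* ``r2_identity`` — R-squared computed against the fixed line y = x,
  1 - SSE/SST with SSE taken against the estimates themselves. It measures
  absolute agreement, and is negative whenever the estimates predict worse
  than the mean of the measured values. Because OLS minimizes SSE over all
  lines, r2_identity <= r2_regression always.

Outlier handling mirrors a two-stage screen: first, points whose absolute
raw-scale residual exceeds 6 times the median absolute residual (MedAD) are
excluded (Q score filter, single pass); second, Cook's distance flags
points whose deletion materially moves the fitted line (default cutoff
4/n, single pass). A descriptive 1.5-IQR screen on log weights is provided
for reporting only and removes nothing.

Quantile convention: numpy's default linear interpolation, so the IQR
screen is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

Q_THRESHOLD_DEFAULT = 6.0


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    r2: float
    fitted: np.ndarray
    residuals: np.ndarray
    mse: float  # SSE / (n - p), p = 2


@dataclass(frozen=True)
class QScoreResult:
    """Per-point outlier scores Q_i = |residual_i| / MedAD."""

    q: np.ndarray
    med_ad: float
    keep_mask: np.ndarray
    threshold: float


@dataclass(frozen=True)
class CooksResult:
    """Per-point Cook's distances for the simple linear fit (p = 2)."""

    d: np.ndarray
    p: int
    mse: float
    influential_mask: np.ndarray
    cutoff: float


def _paired(measured, estimated) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(estimated, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("measured and estimated must be 1-D arrays of equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def yx_r2(measured, estimated) -> float:
    """Coefficient of determination against the identity line y = x.

    ``1 - sum((y - yhat)**2) / sum((y - ybar)**2)`` where ``y`` is the
    measured weight, ``yhat`` the estimate and ``ybar`` the mean measured
    weight. May be arbitrarily negative; requires SST > 0.
    """
    y, yhat = _paired(measured, estimated)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("measured values all identical: SST = 0, R2 undefined")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def ols_fit(x, y) -> OLSFit:
    """OLS line of measured (y) on estimated (x), via statsmodels."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(model.resid)
    n = x.size
    mse = float(resid @ resid / (n - 2)) if n > 2 else 0.0
    return OLSFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        fitted=np.asarray(model.fittedvalues),
        residuals=resid,
        mse=mse,
    )


def q_scores(measured, estimated, threshold: float = Q_THRESHOLD_DEFAULT) -> QScoreResult:
    """Q outlier scores: absolute raw-gram residual over the median absolute residual.

    MedAD = 0 with some non-zero residual gives those points Q = +inf (always
    filtered); MedAD = 0 with all residuals zero gives all Q = 0.
    """
    y, yhat = _paired(measured, estimated)
    resid = np.abs(y - yhat)
    med_ad = float(np.median(resid))
    if med_ad == 0.0:
        q = np.where(resid > 0, np.inf, 0.0)
    else:
        q = resid / med_ad
    return QScoreResult(q=q, med_ad=med_ad, keep_mask=~(q > threshold), threshold=threshold)


def filter_q(measured, estimated, threshold: float = Q_THRESHOLD_DEFAULT) -> QScoreResult:
    """Single-pass Q filter: removed iff Q_i > threshold (strict).

    Q scores are not recomputed after removal. Returns the full
    :class:`QScoreResult`; callers apply ``keep_mask`` to their point lists.
    """
    return q_scores(measured, estimated, threshold)


def cooks_distance(x, y, cutoff: float | str = "4/n") -> CooksResult:
    """Cook's distances for the simple linear regression of y on x.

    Uses the leverage closed form
    ``D_i = e_i**2 * h_ii / (p * MSE * (1 - h_ii)**2)`` with p = 2 and MSE
    from the full fit, which equals the deletion definition
    ``sum_j (yhat_j - yhat_j(i))**2 / (p * MSE)`` exactly.

    ``cutoff`` is either the conventional string ``"4/n"``, a numeric
    threshold, or ``("top_k", k)`` to flag the k largest distances.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 4:
        raise ValueError("need at least p + 2 = 4 points for Cook's distance")
    fit = ols_fit(x, y)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("constant x: leverage undefined")
    h = 1.0 / n + xc**2 / sxx
    e = fit.residuals
    p = 2
    sse = float(e @ e)
    sst = float(np.sum((y - y.mean()) ** 2))
    # A fit perfect to machine precision leaves only float-noise residuals;
    # dividing them by a float-noise MSE would yield arbitrary distances.
    if sse <= 1e-20 * sst or fit.mse == 0.0:
        d = np.zeros(n)
    else:
        d = e**2 * h / (p * fit.mse * (1.0 - h) ** 2)
    cut, mask = _resolve_cutoff(d, n, cutoff)
    return CooksResult(d=d, p=p, mse=fit.mse, influential_mask=mask, cutoff=cut)


def _resolve_cutoff(d: np.ndarray, n: int, cutoff) -> tuple[float, np.ndarray]:
    if isinstance(cutoff, str):
        if cutoff == "4/n":
            cut = 4.0 / n
        else:
            raise ValueError(f"unknown Cook's cutoff rule {cutoff!r}")
        return cut, d > cut
    if isinstance(cutoff, tuple) and len(cutoff) == 2 and cutoff[0] == "top_k":
        k = int(cutoff[1])
        mask = np.zeros(n, dtype=bool)
        if k > 0:
            mask[np.argsort(d)[-k:]] = True
            mask &= d > 0  # never flag zero-distance points
        return float(d[mask].min()) if mask.any() else math.inf, mask
    cut = float(cutoff)
    return cut, d > cut


def filter_influential(x, y, cutoff: float | str = "4/n") -> CooksResult:
    """Single-pass influential-point filter at the given Cook's cutoff."""
    return cooks_distance(x, y, cutoff)


def rmse(measured, estimated) -> float:
    """Root-mean-square residual (g) against the supplied predictions."""
    y, yhat = _paired(measured, estimated)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(measured, estimated) -> float:
    """Mean absolute residual (g) against the supplied predictions."""
    y, yhat = _paired(measured, estimated)
    return float(np.mean(np.abs(y - yhat)))


def iqr_outlier_screen(weights) -> np.ndarray:
    """Descriptive 1.5-IQR outlier flags on the natural-log weight scale.

    Flags ln(weight) outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] using linear
    interpolation quantiles. Purely descriptive: callers must not use this
    to drop data.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty input")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("all weights must be positive and finite")
    lw = np.log(w)
    q1, q3 = np.quantile(lw, [0.25, 0.75])
    iqr = q3 - q1
    return (lw < q1 - 1.5 * iqr) | (lw > q3 + 1.5 * iqr)
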