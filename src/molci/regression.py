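"""Straight-line least squares with coefficient CIs and prediction bands.

The fit is y = alpha + beta*x with beta = cov(x,y)/var(x) and
alpha = mean(y) - beta*mean(x).  Coefficient variances use the residual
mean square with N-2 degrees of freedom:

    var(beta)  = [sum (y - yhat)^2 / (N-2)] / sum (x - xbar)^2
    var(alpha) = var(beta) * sum x^2 / N

The pointwise band for the fitted mean at x0 absorbs the slope/intercept
covariance by centering:

    yhat(x0) +/- t * sqrt((x0 - xbar)^2 var(beta) + residual_ms / N)

and an approximate form highlights the structure: half-width
t * (RMSE/sqrt(N)) * sqrt(1 + 12 (x0 - xbar)^2 / L^2) with L the x range.
A full predictive band (adds the residual variance once more, for a new
observation rather than the mean) sits behind ``predictive=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ConfidenceInterval, resolve_multiplier
from .exceptions import InsufficientDataError, MolciError

__all__ = ["RegressionFit", "fit_line", "coefficient_cis", "prediction_band"]


@dataclass(frozen=True)
class RegressionFit:
    alpha: float
    beta: float
    var_alpha: float
    var_beta: float
    residual_ms: float      # sum (y - yhat)^2 / (N - 2)
    n: int
    x_mean: float
    sxx: float              # sum (x - xbar)^2
    sum_x2: float           # sum x^2
    rmse: float             # sqrt(sum resid^2 / N)
    x_range: float          # L = max(x) - min(x)

    def predict(self, x0: float) -> float:
        return self.alpha + self.beta * x0


def fit_line(x, y) -> RegressionFit:
    """Ordinary least squares on (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MolciError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise InsufficientDataError("fit_line needs n >= 3")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise MolciError("degenerate design: x has zero variance")
    sxy = float(((x - xm) * (y - ym)).sum())
    beta = sxy / sxx
    alpha = ym - beta * xm
    resid = y - (alpha + beta * x)
    sse = float((resid ** 2).sum())
    residual_ms = sse / (n - 2)
    var_beta = residual_ms / sxx
    sum_x2 = float((x ** 2).sum())
    var_alpha = var_beta * sum_x2 / n
    return RegressionFit(
        alpha=float(alpha), beta=float(beta),
        var_alpha=var_alpha, var_beta=var_beta,
        residual_ms=residual_ms, n=n, x_mean=float(xm), sxx=sxx,
        sum_x2=sum_x2, rmse=math.sqrt(sse / n),
        x_range=float(x.max() - x.min()),
    )


def coefficient_cis(fit: RegressionFit, level: float = 0.95,
                    multiplier: float | None = None
                    ) -> tuple[ConfidenceInterval, ConfidenceInterval]:
    """(slope CI, intercept CI), t at df = N-2."""
    if fit.n < 4:
        raise InsufficientDataError("coefficient CIs need n >= 4")
    df = fit.n - 2
    t = resolve_multiplier(level, df, multiplier)
    hb = t * math.sqrt(fit.var_beta)
    ha = t * math.sqrt(fit.var_alpha)
    slope_ci = ConfidenceInterval(
        estimate=fit.beta, lower=fit.beta - hb, upper=fit.beta + hb,
        level=level, method="ols-slope", df=df,
    )
    intercept_ci = ConfidenceInterval(
        estimate=fit.alpha, lower=fit.alpha - ha, upper=fit.alpha + ha,
        level=level, method="ols-intercept", df=df,
    )
    return slope_ci, intercept_ci


def prediction_band(fit: RegressionFit, x0: float, level: float = 0.95,
                    mode: str = "exact", predictive: bool = False,
                    multiplier: float | None = None) -> ConfidenceInterval:
    """Pointwise band for the fitted line at x0.

    ``mode="exact"`` uses the centered variance formula; ``"approximate"``
    the RMSE/range form (requires a nonzero x range).  ``predictive=True``
    widens the exact band by one extra residual variance, giving the band
    for a new observation (a nonstandard extension of the mean band).
    """
    if fit.n < 4:
        raise InsufficientDataError("prediction band needs n >= 4")
    df = fit.n - 2
    t = resolve_multiplier(level, df, multiplier)
    yhat = fit.predict(x0)
    dx = x0 - fit.x_mean
    if mode == "exact":
        var = dx * dx * fit.var_beta + fit.residual_ms / fit.n
        if predictive:
            var += fit.residual_ms
        half = t * math.sqrt(var)
        method = "band-exact" + ("-predictive" if predictive else "")
    elif mode == "approximate":
        if fit.x_range == 0.0:
            raise MolciError("approximate band undefined for zero x range")
        if predictive:
            raise MolciError("predictive widening is only defined for the exact band")
        half = t * (fit.rmse / math.sqrt(fit.n)) * math.sqrt(
            1.0 + 12.0 * dx * dx / (fit.x_range ** 2))
        method = "band-approximate"
    else:
        raise MolciError(f"mode must be 'exact' or 'approximate', got {mode!r}")
    return ConfidenceInterval(
        estimate=yhat, lower=yhat - half, upper=yhat + half,
        level=level, method=method, df=df,
    )
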