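"""Pearson and Spearman correlation with Fisher-transform intervals.

The sampling distribution of r is strongly skewed as |r| approaches 1, so
symmetric error bars are wrong there.  The Fisher transform
F = arctanh(r) = 0.5*ln((1+r)/(1-r)) maps r onto an approximately Gaussian
variable with standard error 1/sqrt(N-3); symmetric bounds on F
back-transform to properly asymmetric bounds on r (the upper arm shorter
than the lower for r > 0).

Also provided: the minimum |r| that is significantly non-zero at a given
level, the small-sample bias correction of the point estimate, a Spearman
variant (Fisher interval with effective sample size shrunk by the constant
1.06), and Theil's adjusted r-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConfidenceInterval, t_quantile
from .exceptions import InsufficientDataError, MolciError
from .options import get_paper_compat

__all__ = [
    "CorrelationEstimate",
    "pearson_r",
    "fisher_transform",
    "fisher_back",
    "r_confidence_interval",
    "r2_bounds",
    "r_significance_threshold",
    "unbiased_r",
    "pearson_ci",
    "spearman_ci",
    "adjusted_r2",
]


@dataclass(frozen=True)
class CorrelationEstimate:
    """A correlation with its transform, bias-corrected value and CI."""

    r: float
    n: int
    fisher_z: float
    rho_unbiased: float
    ci: ConfidenceInterval
    kind: str = "pearson"


def pearson_r(x, y) -> float:
    """Pearson correlation: covariance over the product of SDs (N-1 form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MolciError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise InsufficientDataError("pearson_r needs n >= 3")
    if x.std(ddof=1) == 0.0 or y.std(ddof=1) == 0.0:
        raise MolciError("correlation undefined for constant input")
    return float(np.clip(stats.pearsonr(x, y).statistic, -1.0, 1.0))


def fisher_transform(r: float) -> float:
    """F = 0.5 ln((1+r)/(1-r)) = arctanh(r)."""
    if not abs(r) < 1.0:
        raise MolciError("Fisher transform infinite at |r| = 1")
    return float(np.arctanh(r))


def fisher_back(F: float) -> float:
    """Inverse transform (e^{2F} - 1)/(e^{2F} + 1) = tanh(F)."""
    return float(np.tanh(F))


def _multiplier(level: float, multiplier) -> float:
    """Normal quantile by default; a number reproduces t-based worked examples."""
    if multiplier is None or multiplier == "auto":
        if get_paper_compat():
            return 2.0
        return float(stats.norm.ppf((1.0 + level) / 2.0))
    return float(multiplier)


def r_confidence_interval(r: float, n: int, level: float = 0.95,
                          multiplier: float | str | None = "auto") -> ConfidenceInterval:
    """Fisher-transform CI: tanh(arctanh(r) +/- m/sqrt(n-3)).

    The default multiplier is the normal quantile (the Fisher statistic is
    asymptotically normal); pass a number (e.g. a small-sample t value) to
    reproduce t-based conventions.
    """
    if n <= 3:
        raise InsufficientDataError("Fisher CI needs n >= 4")
    if abs(r) >= 1.0:
        return ConfidenceInterval(
            estimate=r, lower=r, upper=r, level=level, method="fisher", df=n - 3,
            warnings=("|r| = 1: transform degenerate, zero-width interval",),
        )
    m = _multiplier(level, multiplier)
    F = fisher_transform(r)
    half = m / math.sqrt(n - 3)
    return ConfidenceInterval(
        estimate=r, lower=fisher_back(F - half), upper=fisher_back(F + half),
        level=level, method="fisher", df=n - 3,
    )


def r2_bounds(ci: ConfidenceInterval) -> tuple[float, float]:
    """Bounds on r^2 implied by bounds on r (0 if the CI straddles 0)."""
    lo, hi = ci.lower, ci.upper
    if lo <= 0.0 <= hi:
        return 0.0, max(lo * lo, hi * hi)
    lo2, hi2 = sorted((lo * lo, hi * hi))
    return lo2, hi2


def r_significance_threshold(n: int, level: float = 0.95,
                             form: str = "exact",
                             multiplier: float | None = None) -> float:
    """Smallest |r| distinguishable from zero at the given level.

    ``form="exact"``: t/sqrt(n-2+t^2) with t at df = n-2 (follows from the
    t test of the regression slope).  ``form="large_n"``: t/sqrt(n-3), the
    Fisher-scale approximation.  ``multiplier`` overrides the t value
    (classic worked examples sometimes carry a t from a neighboring df).
    """
    if n < 3:
        raise InsufficientDataError("significance threshold needs n >= 3")
    t = multiplier if multiplier is not None else t_quantile(level, n - 2, tails="two")
    if form == "exact":
        return t / math.sqrt(n - 2 + t * t)
    if form == "large_n":
        if n < 4:
            raise InsufficientDataError("large-n form needs n >= 4")
        return t / math.sqrt(n - 3)
    raise MolciError(f"form must be 'exact' or 'large_n', got {form!r}")


def unbiased_r(r: float, n: int) -> float:
    """Small-sample bias correction r(1 - (1-r^2)/(2(n-1)))."""
    if n < 2:
        raise InsufficientDataError("bias correction needs n >= 2")
    return r * (1.0 - (1.0 - r * r) / (2.0 * (n - 1)))


def pearson_ci(x, y, level: float = 0.95,
               multiplier: float | str | None = "auto") -> CorrelationEstimate:
    """Pearson r with Fisher CI and bias-corrected estimate, from raw data."""
    r = pearson_r(x, y)
    n = len(x)
    ci = r_confidence_interval(r, n, level=level, multiplier=multiplier)
    return CorrelationEstimate(
        r=r, n=n, fisher_z=fisher_transform(r) if abs(r) < 1 else math.inf,
        rho_unbiased=unbiased_r(r, n), ci=ci, kind="pearson",
    )


def spearman_ci(x, y, level: float = 0.95,
                multiplier: float | str | None = "auto") -> CorrelationEstimate:
    """Spearman rank correlation with a widened Fisher interval.

    rho is Pearson's r on mid-ranks; the Fisher interval uses the effective
    sample term (n-3)/1.06 in place of n-3, reflecting the extra variance
    of the rank statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("spearman_ci needs n >= 4")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if abs(rho) >= 1.0:
        ci = ConfidenceInterval(
            estimate=rho, lower=rho, upper=rho, level=level,
            method="fisher-spearman", df=(n - 3) / 1.06,
            warnings=("|rho| = 1: transform degenerate, zero-width interval",),
        )
        fz = math.inf
    else:
        m = _multiplier(level, multiplier)
        fz = fisher_transform(rho)
        half = m / math.sqrt((n - 3) / 1.06)
        ci = ConfidenceInterval(
            estimate=rho, lower=fisher_back(fz - half), upper=fisher_back(fz + half),
            level=level, method="fisher-spearman", df=(n - 3) / 1.06,
        )
    return CorrelationEstimate(
        r=rho, n=n, fisher_z=fz, rho_unbiased=unbiased_r(rho, n),
        ci=ci, kind="spearman",
    )


def adjusted_r2(r2: float, n: int, n_params: int) -> float:
    """Theil's adjusted r^2: 1 - (1-R^2)(N-1)/(N-1-#parameters)."""
    if not (0.0 <= r2 <= 1.0):
        raise MolciError("r2 must lie in [0, 1]")
    if n - 1 - n_params <= 0:
        raise MolciError("need n > n_params + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - n_params)
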