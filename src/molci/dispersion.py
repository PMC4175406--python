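"""Confidence intervals for standard deviations and RMSEs.

An RMSE is itself a standard deviation (of prediction errors), so it has
sampling uncertainty like any other statistic.  Two intervals:

* Gaussian large-N approximation on the *variance*:
  s^2 +/- sqrt(2) * t * s^2 / sqrt(N-1), square-rooted to an SD interval.
  At small N the lower variance bound can go negative — returned as-is
  with ``valid=False`` rather than clipped, since the failure is the
  motivation for the exact form.

* Exact chi-squared interval: (N-1) s^2 / sigma^2 is chi-squared
  distributed, so sigma is bracketed by
  sqrt((N-1) s^2 / chi2_upper) < sigma < sqrt((N-1) s^2 / chi2_lower).
  Always positive and asymmetric (the upper arm longer at small N).

``df_convention`` selects the chi-squared degrees of freedom: "n_minus_1"
(standard) or "n" (matches classical printed table lookups that index the
table by the number of variables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ConfidenceInterval, chi2_bounds, resolve_multiplier
from .exceptions import InsufficientDataError, MolciError

__all__ = ["DispersionEstimate", "variance_ci_gaussian", "sd_ci_chi2"]


@dataclass(frozen=True)
class DispersionEstimate:
    """An observed SD or RMSE with its sample size."""

    value: float
    n: int
    kind: str = "rmse"

    def __post_init__(self) -> None:
        if self.value < 0 or not math.isfinite(self.value):
            raise MolciError("dispersion value must be finite and >= 0")
        if self.n < 2:
            raise InsufficientDataError("dispersion estimate needs n >= 2")
        if self.kind not in ("sd", "rmse"):
            raise MolciError("kind must be 'sd' or 'rmse'")


def variance_ci_gaussian(est: DispersionEstimate, level: float = 0.95,
                         multiplier: float | None = None) -> ConfidenceInterval:
    """Large-N Gaussian interval on the SD/RMSE (via its variance).

    Variance bounds s^2 -/+ sqrt(2) t s^2/sqrt(N-1); the SD interval is the
    square root where defined.  A negative variance lower bound flags the
    interval invalid (the small-N failure mode); the returned lower bound
    is then the signed variance bound itself so the breakage is visible.
    """
    s2 = est.value ** 2
    t = resolve_multiplier(level, est.n - 1, multiplier)
    half = math.sqrt(2.0) * t * s2 / math.sqrt(est.n - 1)
    v_lo, v_hi = s2 - half, s2 + half
    if v_lo < 0.0:
        return ConfidenceInterval(
            estimate=est.value, lower=v_lo, upper=math.sqrt(v_hi),
            level=level, method="gaussian-variance", df=est.n - 1, valid=False,
            warnings=("variance lower bound negative; Gaussian approximation "
                      "breaks down at this N — use the chi-squared interval",),
        )
    return ConfidenceInterval(
        estimate=est.value, lower=math.sqrt(v_lo), upper=math.sqrt(v_hi),
        level=level, method="gaussian-variance", df=est.n - 1,
    )


def sd_ci_chi2(est: DispersionEstimate, level: float = 0.95,
               df_convention: str = "n_minus_1") -> ConfidenceInterval:
    """Exact chi-squared interval for sigma; strictly positive bounds."""
    if df_convention == "n_minus_1":
        df = est.n - 1
    elif df_convention == "n":
        df = est.n
    else:
        raise MolciError("df_convention must be 'n_minus_1' or 'n'")
    lo_q, hi_q = chi2_bounds(level, df)
    scale = (est.n - 1) * est.value ** 2
    return ConfidenceInterval(
        estimate=est.value,
        lower=math.sqrt(scale / hi_q), upper=math.sqrt(scale / lo_q),
        level=level, method=f"chi2-{df_convention}", df=df,
    )
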