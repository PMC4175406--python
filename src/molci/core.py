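"""Sample summaries, distribution quantiles, and effective degrees of freedom.

Every other module builds on three primitives defined here:

* :func:`t_quantile` / :func:`chi2_bounds` — continuous quantile functions of
  the Student-t and chi-squared distributions (fractional degrees of freedom
  accepted everywhere, as required when degrees of freedom come out of the
  Welch–Satterthwaite approximation);
* :func:`welch_satterthwaite` — the effective-degrees-of-freedom rule for a
  variance assembled from several components with distinct sample sizes;
* :class:`ConfidenceInterval` — the universal return type carrying the
  estimate, the bounds, the confidence level, a method tag and the degrees of
  freedom actually used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, MolciError
from .options import get_paper_compat

__all__ = [
    "SampleSummary",
    "ConfidenceInterval",
    "ErrorComponent",
    "summarize",
    "t_quantile",
    "chi2_bounds",
    "welch_satterthwaite",
    "mean_ci",
    "resolve_multiplier",
]


@dataclass(frozen=True)
class SampleSummary:
    """Mean, sample standard deviation (N-1 denominator) and standard error."""

    n: int
    mean: float
    sd: float
    se: float


@dataclass(frozen=True)
class ConfidenceInterval:
    """An estimate with lower/upper confidence bounds.

    ``valid`` is False when the nominal bounds escape the natural range of
    the quantity (e.g. a Gaussian interval on a probability dipping below
    zero).  Such intervals are returned untruncated so the failure is
    visible; the asymmetric (logit / chi-squared) constructions are the fix.
    """

    estimate: float
    lower: float
    upper: float
    level: float
    method: str = ""
    df: float = math.inf
    valid: bool = True
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise MolciError(f"confidence level must be in (0, 1), got {self.level}")
        if self.valid and not (self.lower <= self.estimate + 1e-12 and
                               self.estimate <= self.upper + 1e-12):
            raise MolciError(
                f"invalid interval ordering: {self.lower} <= {self.estimate} <= {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def with_warning(self, message: str) -> "ConfidenceInterval":
        return replace(self, warnings=self.warnings + (message,))

    def to_dict(self) -> dict:
        """Flat JSON-serializable record."""
        return {
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "method": self.method,
            "df": self.df,
            "valid": self.valid,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class ErrorComponent:
    """One additive variance contribution Var_i/N_i with its own df."""

    variance_over_n: float
    df: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.variance_over_n) or self.variance_over_n < 0:
            raise MolciError("variance_over_n must be finite and >= 0")
        if not self.df > 0:
            raise MolciError("df must be > 0")


def summarize(values: Sequence[float]) -> SampleSummary:
    """Mean, N-1 sample SD, and standard error of the mean SD/sqrt(N)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n < 2:
        raise InsufficientDataError("summarize needs at least 2 finite values")
    sd = float(arr.std(ddof=1))
    return SampleSummary(n=n, mean=float(arr.mean()), sd=sd, se=sd / math.sqrt(n))


def t_quantile(level: float, df: float, tails: str = "two") -> float:
    """Student-t multiplier enclosing central (two-tailed) mass ``level``.

    ``tails="one"`` returns the upper one-tailed quantile instead.  ``df``
    may be fractional or ``inf`` (normal limit).
    """
    if not (0.0 < level < 1.0):
        raise MolciError(f"level must be in (0, 1), got {level}")
    if not df > 0:
        raise MolciError(f"df must be > 0, got {df}")
    p = (1.0 + level) / 2.0 if tails == "two" else level
    if tails not in ("one", "two"):
        raise MolciError(f"tails must be 'one' or 'two', got {tails!r}")
    if math.isinf(df):
        return float(stats.norm.ppf(p))
    return float(stats.t.ppf(p, df))


def chi2_bounds(level: float, df: float) -> tuple[float, float]:
    """(lower, upper) chi-squared quantiles bracketing the central mass."""
    if not (0.0 < level < 1.0):
        raise MolciError(f"level must be in (0, 1), got {level}")
    if not df > 0:
        raise MolciError(f"df must be > 0, got {df}")
    alpha = (1.0 - level) / 2.0
    return float(stats.chi2.ppf(alpha, df)), float(stats.chi2.ppf(1.0 - alpha, df))


def welch_satterthwaite(components: Sequence[ErrorComponent]) -> float:
    """Effective degrees of freedom for a summed variance.

    nu_eff = (sum v_i)^2 / sum(v_i^2 / nu_i)  with  v_i = Var_i/N_i.
    Bounded by min(nu_i) <= nu_eff <= sum(nu_i) for positive components.
    """
    if not components:
        raise InsufficientDataError("need at least one error component")
    total = sum(c.variance_over_n for c in components)
    if total == 0.0:
        raise MolciError("all variance components are zero; df undefined")
    denom = sum((c.variance_over_n ** 2) / c.df for c in components)
    return total * total / denom


def resolve_multiplier(level: float, df: float, multiplier: float | None = None) -> float:
    """The t-style multiplier a CI should use.

    Explicit ``multiplier`` wins; otherwise the global paper-compat switch
    substitutes 2.0; otherwise the exact two-tailed t quantile at ``df``.
    """
    if multiplier is not None:
        return float(multiplier)
    if get_paper_compat():
        return 2.0
    return t_quantile(level, df, tails="two")


def mean_ci(summary: SampleSummary, level: float = 0.95,
            multiplier: float | None = None) -> ConfidenceInterval:
    """Student-t interval for a mean: estimate +/- t(level, n-1) * SE."""
    if summary.n < 2:
        raise InsufficientDataError("mean_ci needs n >= 2")
    df = summary.n - 1
    t = resolve_multiplier(level, df, multiplier)
    half = t * summary.se
    return ConfidenceInterval(
        estimate=summary.mean, lower=summary.mean - half, upper=summary.mean + half,
        level=level, method="t-mean", df=df,
    )
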