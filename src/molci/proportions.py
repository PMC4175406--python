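"""Confidence intervals for probabilities and counts.

A success rate p = m/N (a docking success rate, a hit rate) carries binomial
uncertainty with variance approximately p(1-p)/N.  The symmetric Gaussian
interval built from that variance can escape [0, 1] near the boundaries; it
is returned untruncated with ``valid=False`` so the failure is explicit.
The logit-transformed interval is the fix: transform p to log(p/(1-p)),
build symmetric bounds there, and back-transform — the resulting bounds
always lie inside (0, 1) and collapse to the Gaussian interval for large N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ConfidenceInterval, resolve_multiplier
from .exceptions import BoundaryError, InsufficientDataError, MolciError

__all__ = [
    "ProportionEstimate",
    "proportion_variance",
    "proportion_ci_gaussian",
    "proportion_ci_logit",
]


@dataclass(frozen=True)
class ProportionEstimate:
    """m successes out of N trials."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise MolciError("trials must be >= 1")
        if not (0 <= self.successes <= self.trials):
            raise MolciError("successes must lie in [0, trials]")

    @property
    def p(self) -> float:
        return self.successes / self.trials


def proportion_variance(p: float, n: int | None = None,
                        exact_prefactor: bool = False) -> float:
    """Per-observation variance of a Bernoulli indicator, p(1-p).

    With ``exact_prefactor`` the unbiased N/(N-1) factor is kept; by default
    it is dropped (the usual large-N approximation).
    """
    if not (0.0 <= p <= 1.0):
        raise MolciError(f"p must be in [0, 1], got {p}")
    v = p * (1.0 - p)
    if exact_prefactor:
        if n is None or n < 2:
            raise InsufficientDataError("exact prefactor needs n >= 2")
        v *= n / (n - 1.0)
    return v


def proportion_ci_gaussian(est: ProportionEstimate, level: float = 0.95,
                           multiplier: float | None = None,
                           scale: str = "fraction") -> ConfidenceInterval:
    """Symmetric interval p +/- t*sqrt(p(1-p)/N).

    ``scale="count"`` returns the interval on the count m = Np instead
    (half-width t*sqrt(Np(1-p))).  Bounds outside the admissible range are
    NOT clipped; the interval is flagged ``valid=False``.
    """
    if est.trials < 2:
        raise InsufficientDataError("gaussian proportion CI needs N >= 2")
    p = est.p
    n = est.trials
    t = resolve_multiplier(level, n - 1, multiplier)
    if p in (0.0, 1.0):
        e = p if scale == "fraction" else est.successes
        return ConfidenceInterval(
            estimate=e, lower=e, upper=e, level=level,
            method=f"gaussian-{scale}", df=n - 1,
        ).with_warning("degenerate: observed proportion on the boundary")
    se = math.sqrt(p * (1.0 - p) / n)
    if scale == "fraction":
        lower, upper, lo_ok, hi_ok = p - t * se, p + t * se, 0.0, 1.0
        estimate = p
    elif scale == "count":
        half = t * math.sqrt(n * p * (1.0 - p))
        estimate = float(est.successes)
        lower, upper, lo_ok, hi_ok = estimate - half, estimate + half, 0.0, float(n)
    else:
        raise MolciError(f"scale must be 'fraction' or 'count', got {scale!r}")
    valid = lower >= lo_ok - 1e-12 and upper <= hi_ok + 1e-12
    ci = ConfidenceInterval(
        estimate=estimate, lower=lower, upper=upper, level=level,
        method=f"gaussian-{scale}", df=n - 1, valid=True,
    )
    if not valid:
        ci = ConfidenceInterval(
            estimate=estimate, lower=lower, upper=upper, level=level,
            method=f"gaussian-{scale}", df=n - 1, valid=False,
            warnings=("interval exits the admissible range; "
                      "use the logit form for boundary-safe bounds",),
        )
    return ci


def proportion_ci_logit(est: ProportionEstimate, level: float = 0.95,
                        multiplier: float | None = None,
                        continuity_correction: bool = False) -> ConfidenceInterval:
    """Logit-transformed interval; bounds always inside (0, 1).

    With lambda = exp(t / sqrt(p(1-p)N)) the interval is
    [p/(p + lambda(1-p)), p/(p + (1-p)/lambda)].  Observed p of exactly 0
    or 1 has an unbounded transform; the optional ``continuity_correction``
    (a Laplace-style (m+1/2)/(N+1) shrinkage, not part of the classical
    treatment) makes those cases usable.
    """
    p = est.p
    n = est.trials
    warnings: tuple[str, ...] = ()
    if p in (0.0, 1.0):
        if not continuity_correction:
            raise BoundaryError(
                "logit CI undefined at p in {0, 1}; set continuity_correction=True"
            )
        p = (est.successes + 0.5) / (n + 1.0)
        warnings = ("boundary proportion shrunk to (m+1/2)/(N+1) "
                    "before the logit transform",)
    t = resolve_multiplier(level, n - 1, multiplier)
    lam = math.exp(t / math.sqrt(p * (1.0 - p) * n))
    lower = p / (p + lam * (1.0 - p))
    upper = p / (p + (1.0 - p) / lam)
    return ConfidenceInterval(
        estimate=p, lower=lower, upper=upper, level=level,
        method="logit", df=n - 1, warnings=warnings,
    )
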