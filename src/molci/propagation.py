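"""Propagation of independent (and covarying) error sources.

For a function X(x_1, ..., x_m) with known sensitivities dX/dx_i, the
first-order variance is

    var(X) = sum_i (dX/dx_i)^2 var(x_i)
           + sum_{i != j} (dX/dx_i)(dX/dx_j) cov(x_i, x_j),

the cross terms appearing only when the inputs covary.  Specializations:
the ratio of two measurements, multiplicative (log-fold) errors on binding
constants and selectivities, the standard errors of Cohen's d and the
coefficient of variation, and the "missing error" obtained by subtracting
known components from an observed total in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import InconsistentErrorBudgetError, InsufficientDataError, MolciError

__all__ = [
    "Measurement",
    "EffectSize",
    "propagate",
    "finite_difference_sensitivities",
    "ratio_se",
    "log_fold_ci",
    "log_fold_factor",
    "effect_size_se",
    "missing_error",
]


@dataclass(frozen=True)
class Measurement:
    """A value with its standard error."""

    value: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.se) or self.se < 0:
            raise MolciError("se must be finite and >= 0")

    @property
    def variance(self) -> float:
        return self.se * self.se


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d (mu/sigma, single-sample form) or its reciprocal c_V."""

    n: int
    d: float | None = None
    cv: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError("effect size SE needs n >= 2")
        if self.d is None and self.cv is None:
            raise MolciError("provide d or cv")
        if self.d is not None and self.cv is not None:
            if abs(self.d * self.cv - 1.0) > 1e-12:
                raise MolciError("d and cv must satisfy d*cv = 1")


def propagate(sensitivities: Sequence[float], variances: Sequence[float],
              covariances: np.ndarray | None = None) -> float:
    """First-order variance of a function of noisy inputs.

    ``covariances`` is the full off-diagonal covariance structure (a
    symmetric matrix whose diagonal is ignored in favor of ``variances``);
    omitted means independent inputs.
    """
    a = np.asarray(sensitivities, dtype=float)
    v = np.asarray(variances, dtype=float)
    if a.shape != v.shape or a.ndim != 1:
        raise MolciError("sensitivities and variances must be equal-length 1-D")
    if np.any(v < 0):
        raise MolciError("variances must be >= 0")
    total = float((a * a * v).sum())
    if covariances is not None:
        c = np.asarray(covariances, dtype=float)
        if c.shape != (a.size, a.size):
            raise MolciError("covariance matrix shape mismatch")
        if not np.allclose(c, c.T, rtol=1e-10, atol=1e-12):
            raise MolciError("covariance matrix must be symmetric")
        off = c - np.diag(np.diag(c))
        total += float(a @ off @ a)
    return total


def finite_difference_sensitivities(func: Callable[[np.ndarray], float],
                                    x0: Sequence[float]) -> np.ndarray:
    """Central-difference dX/dx_i for a black-box function.

    Step per coordinate: max(1e-6, 1e-6*|x_i|).
    """
    x0 = np.asarray(x0, dtype=float)
    out = np.empty_like(x0)
    for i in range(x0.size):
        h = max(1e-6, 1e-6 * abs(x0[i]))
        hi, lo = x0.copy(), x0.copy()
        hi[i] += h
        lo[i] -= h
        out[i] = (func(hi) - func(lo)) / (2.0 * h)
    return out


def ratio_se(y: Measurement, z: Measurement) -> Measurement:
    """First-order SE of the ratio y/z.

    var(R) = var(y)/z^2 + y^2 var(z)/z^4.  A first-order result: accuracy
    degrades as the denominator's coefficient of variation grows (keep
    se(z)/|z| below ~0.2).
    """
    if z.value == 0.0:
        raise MolciError("ratio undefined for z = 0")
    var = y.variance / z.value ** 2 + (y.value ** 2 / z.value ** 4) * z.variance
    return Measurement(value=y.value / z.value, se=math.sqrt(var))


def log_fold_factor(fold_error_per_term: float, n_terms: int, t: float) -> float:
    """Multiplicative CI factor for a product/ratio of fold-uncertain terms.

    Each term uncertain to a factor ``fold`` contributes an SD of
    log10(fold) in log10 units; n independent terms combine to
    sqrt(n)*log10(fold), and the CI on the original scale is
    [S/factor, S*factor] with factor = 10^(t * sqrt(n) * log10(fold)).
    """
    if n_terms < 1:
        raise MolciError("n_terms must be >= 1")
    if fold_error_per_term <= 1.0:
        raise MolciError("fold error must exceed 1")
    sd_log = math.log10(fold_error_per_term)
    return 10.0 ** (t * math.sqrt(n_terms) * sd_log)


# alias matching the interval-construction reading of the operation
log_fold_ci = log_fold_factor


def effect_size_se(es: EffectSize) -> tuple[float, float]:
    """(SE(d), SE(c_V)).

    var(d) = (1 + sqrt(2) d^2)/N, from propagating the independent errors
    of a mean and an SD through d = mu/sigma; SE(c_V) = c_V^2 * SE(d) by
    the reciprocal relation.
    """
    d = es.d if es.d is not None else 1.0 / es.cv
    cv = es.cv if es.cv is not None else (math.inf if d == 0 else 1.0 / d)
    se_d = math.sqrt((1.0 + math.sqrt(2.0) * d * d) / es.n)
    se_cv = cv * cv * se_d if math.isfinite(cv) else math.inf
    return se_d, se_cv


def missing_error(total: float, known: Sequence[float]) -> float:
    """The unexplained component: sqrt(total^2 - sum known_i^2)."""
    if total < 0:
        raise MolciError("total error must be >= 0")
    s = total * total - sum(k * k for k in known)
    if s < -1e-12 * max(total * total, 1.0):
        raise InconsistentErrorBudgetError(
            "stated components exceed the observed total error"
        )
    return math.sqrt(max(s, 0.0))
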