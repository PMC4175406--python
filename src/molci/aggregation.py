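"""Combining measurements and decomposing benchmark-set error.

Two distinct situations:

* **Same quantity measured several ways** (e.g. one pKa from three assays):
  the minimum-variance unbiased combination is the inverse-variance
  weighted mean, with SE^2 the harmonic sum 1/sum(1/e_i^2).

* **One metric averaged over many benchmark systems** (e.g. mean AUC over a
  screening benchmark): the observed SE of the mean mixes the true
  between-system spread with each system's finite-sample noise Err_i.
  Subtracting the noise in quadrature estimates the *intrinsic* SE — what
  the spread would be with unlimited actives/decoys per system:

      SE_intrinsic = sqrt(SE_observed^2 - sum Err_i^2 / (N(N-1))).

  The decomposition also yields a criterion for whether adding a new,
  noisy system (error Err_new) helps the mean:

      include iff  sigma_intrinsic^2 + 2*sigma_system^2 > Err_new^2,

  with sigma_intrinsic^2 = N*SE_intrinsic^2 and
  sigma_system^2 = sum Err_i^2/(N-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ConfidenceInterval, resolve_multiplier
from .exceptions import InsufficientDataError, MolciError
from .propagation import Measurement

__all__ = [
    "SystemResult",
    "ErrorDecomposition",
    "AddSystemDecision",
    "weighted_mean_ci",
    "weighted_variance",
    "intrinsic_se",
    "add_system_criterion",
    "hanley_system_error_sq",
]


@dataclass(frozen=True)
class SystemResult:
    """Per-system metric (e.g. an AUC) with its standard error."""

    metric: float
    err: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.err) or self.err < 0:
            raise MolciError("err must be finite and >= 0")


@dataclass(frozen=True)
class ErrorDecomposition:
    se_observed: float
    se_intrinsic: float
    sigma2_intrinsic: float      # N * se_intrinsic^2
    sigma2_system: float         # sum Err_i^2 / (N-1)
    n: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class AddSystemDecision:
    include: bool
    include_approx: bool         # sigma_intrinsic^2 > err_new^2 alone
    threshold: float             # sigma_intrinsic^2 + 2*sigma_system^2
    err_new_sq: float


def weighted_mean_ci(ms: Sequence[Measurement], level: float = 0.95,
                     multiplier: float | None = None) -> ConfidenceInterval:
    """Inverse-variance weighted mean with harmonic-sum SE.

    A measurement with se = 0 is exact: it is returned as the answer with
    zero SE (it dominates the weights completely).
    """
    if not ms:
        raise InsufficientDataError("need at least one measurement")
    exact = [m for m in ms if m.se == 0.0]
    if exact:
        v = exact[0].value
        return ConfidenceInterval(
            estimate=v, lower=v, upper=v, level=level,
            method="weighted-mean", df=max(len(ms) - 1, 1),
            warnings=("a zero-SE measurement dominates; returned exactly",),
        )
    w = np.array([1.0 / m.se ** 2 for m in ms])
    x = np.array([m.value for m in ms])
    mean = float((w * x).sum() / w.sum())
    se = math.sqrt(1.0 / w.sum())
    df = max(len(ms) - 1, 1)
    t = resolve_multiplier(level, df, multiplier)
    return ConfidenceInterval(
        estimate=mean, lower=mean - t * se, upper=mean + t * se,
        level=level, method="weighted-mean", df=df,
    )


def weighted_mean_se(ms: Sequence[Measurement]) -> float:
    """SE of the inverse-variance weighted mean: sqrt(1/sum 1/e_i^2)."""
    if any(m.se == 0.0 for m in ms):
        return 0.0
    return math.sqrt(1.0 / sum(1.0 / m.se ** 2 for m in ms))


def weighted_variance(values: Sequence[float], weights: Sequence[float]) -> float:
    """Unbiased weighted sample variance.

    prefactor sum(W) / ((sum W)^2 - sum W^2), times
    sum W_i (x_i - <x>)^2 with <x> the weighted mean.  Reduces to the
    ordinary N-1 sample variance for equal weights.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise MolciError("values and weights must be equal-length 1-D")
    if np.any(w < 0):
        raise MolciError("weights must be >= 0")
    if np.count_nonzero(w > 0) < 2:
        raise InsufficientDataError("need at least two positive weights")
    sw = w.sum()
    sw2 = (w * w).sum()
    mean = (w * x).sum() / sw
    return float(sw / (sw * sw - sw2) * (w * (x - mean) ** 2).sum())


def intrinsic_se(systems: Sequence[SystemResult]) -> ErrorDecomposition:
    """Split the SE of a benchmark mean into intrinsic and per-system parts."""
    n = len(systems)
    if n < 3:
        raise InsufficientDataError("decomposition needs >= 3 systems")
    metrics = np.array([s.metric for s in systems])
    errs = np.array([s.err for s in systems])
    se_obs = float(metrics.std(ddof=1) / math.sqrt(n))
    noise = float((errs ** 2).sum() / (n * (n - 1)))
    radicand = se_obs ** 2 - noise
    warnings: tuple[str, ...] = ()
    if radicand < 0.0:
        se_intr = 0.0
        warnings = ("per-system noise exceeds observed variance; "
                    "intrinsic SE floored at zero",)
    else:
        se_intr = math.sqrt(radicand)
    return ErrorDecomposition(
        se_observed=se_obs, se_intrinsic=se_intr,
        sigma2_intrinsic=n * se_intr ** 2,
        sigma2_system=float((errs ** 2).sum() / (n - 1)),
        n=n, warnings=warnings,
    )


def add_system_criterion(decomp: ErrorDecomposition, err_new: float) -> AddSystemDecision:
    """Does adding a system with error err_new reduce the mean's noise?"""
    if err_new < 0:
        raise MolciError("err_new must be >= 0")
    threshold = decomp.sigma2_intrinsic + 2.0 * decomp.sigma2_system
    e2 = err_new * err_new
    return AddSystemDecision(
        include=threshold > e2,
        include_approx=decomp.sigma2_intrinsic > e2,
        threshold=threshold, err_new_sq=e2,
    )


def hanley_system_error_sq(auc: float, n_active: int) -> float:
    """Expected squared AUC error of a system from its AUC and active count.

    The Hanley active-term with decoys assumed in excess:
    AUC^2 (1-AUC) / ((1+AUC) N_active).
    """
    if n_active < 1:
        raise MolciError("n_active must be >= 1")
    if not (0.0 <= auc <= 1.0):
        raise MolciError("auc must lie in [0, 1]")
    return auc * auc * (1.0 - auc) / ((1.0 + auc) * n_active)
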