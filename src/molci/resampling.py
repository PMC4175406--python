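"""Percentile bootstrap confidence intervals.

The data are resampled with replacement B times; the statistic is
recomputed on each resample; the interval is the pair of empirical
quantiles bracketing the central mass.  Bounds can never exceed the range
achievable from the data, so probabilities stay in [0, 1] automatically
and no degrees-of-freedom bookkeeping is needed.

Documented failure modes are guarded rather than hidden:

* tail resolution — a level whose tail implies fewer than ~40 resamples
  beyond each bound is refused (the requested significance cannot be
  established from the resample grid);
* statistics known to bootstrap badly (mode, extremes/minima/maxima, and
  correlation coefficients, whose resample mean is biased upward by
  duplicated points) trigger a warning when annotated via
  ``statistic_kind``.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import ConfidenceInterval
from .exceptions import InsufficientDataError, MolciError, ResolutionError

__all__ = ["BootstrapResult", "bootstrap_ci", "expected_reuse_fraction"]

_FRAGILE_KINDS = {
    "correlation": "bootstrap means of correlation coefficients are biased "
                   "upward by duplicated points",
    "mode": "bootstrapping a mode measures oversampling of single observations",
    "extreme": "resampling can only under-represent extrema",
}


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci: ConfidenceInterval
    n_resamples: int
    seed: int
    reuse_fraction: float
    resample_stats: np.ndarray = field(repr=False, default=None)


def expected_reuse_fraction(n: int) -> float:
    """Expected fraction of points drawn 2+ times in one resample.

    1 - P(drawn 0 times) - P(drawn exactly once)
    = 1 - (1-1/n)^n - (1-1/n)^(n-1); about one quarter for moderate n.
    """
    return 1.0 - (1.0 - 1.0 / n) ** n - (1.0 - 1.0 / n) ** (n - 1)


def bootstrap_ci(data: Sequence, statistic: Callable[[np.ndarray], float],
                 n_resamples: int = 10_000, seed: int | None = None,
                 level: float = 0.95,
                 statistic_kind: str | None = None) -> BootstrapResult:
    """Percentile bootstrap CI of ``statistic`` over ``data``.

    ``data`` may be a 1-D array or a 2-D array of records (rows resampled
    jointly, e.g. (x, y) pairs or (score, label) rows).  ``seed`` is
    mandatory: reproducibility is the point.
    """
    if seed is None:
        raise MolciError("seed is mandatory for bootstrap reproducibility")
    arr = np.asarray(data)
    if arr.shape[0] == 0:
        raise InsufficientDataError("data must be non-empty")
    if n_resamples < 100:
        raise MolciError("n_resamples must be >= 100")
    tail = n_resamples * (1.0 - level) / 2.0
    if tail < 40:
        raise ResolutionError(
            f"level {level} leaves only {tail:.0f} resamples beyond each "
            "bound; increase n_resamples (need >= 40 per tail)"
        )
    if statistic_kind in _FRAGILE_KINDS:
        _warnings.warn(f"bootstrap caveat ({statistic_kind}): "
                       f"{_FRAGILE_KINDS[statistic_kind]}", stacklevel=2)
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_resamples)
    reused = 0.0
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        stats_out[b] = statistic(arr[idx])
        counts = np.bincount(idx, minlength=n)
        reused += np.count_nonzero(counts >= 2) / n
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats_out, [alpha, 1.0 - alpha])
    est = float(statistic(arr))
    ci = ConfidenceInterval(
        estimate=est, lower=float(min(lower, est)), upper=float(max(upper, est)),
        level=level, method="bootstrap-percentile", df=math.inf,
    )
    if not (lower <= est <= upper):
        ci = ci.with_warning(
            "point estimate outside the percentile interval (skewed or "
            "biased resample distribution); interval widened to include it"
        )
    return BootstrapResult(
        estimate=est, ci=ci, n_resamples=n_resamples, seed=seed,
        reuse_fraction=reused / n_resamples, resample_stats=stats_out,
    )
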