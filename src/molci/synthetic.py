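"""Synthetic data generators with known ground truth.

Every stochastic operation takes an explicit seed (or Generator); there is
no hidden global state.  The screening generator draws exponential scores:
inactives at unit rate, actives at rate (1-AUC)/AUC, for which
P(active > inactive) equals the target AUC exactly and the population ROC
is the canonical curve y = x^((1-AUC)/AUC).  That makes the AUC-only error
formulas testable as population truths, not just approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import ConfidenceInterval
from .exceptions import MolciError
from .proportions import ProportionEstimate, proportion_ci_logit
from .roc import LabeledScores

__all__ = [
    "SyntheticConfig",
    "gen_screening_scores",
    "gen_correlated_pairs",
    "gen_gaussian",
    "CoverageResult",
    "coverage_experiment",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Bundle of generator settings; the seed is mandatory."""

    seed: int
    n_active: int = 50
    n_inactive: int = 500
    target_auc: float = 0.8
    rho: float = 0.8
    n_pairs: int = 50
    n: int = 100
    mu: float = 0.0
    sigma: float = 1.0


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_screening_scores(n_active: int, n_inactive: int, target_auc: float,
                         seed: int | np.random.Generator) -> LabeledScores:
    """Exponential-score screening deck with exact population AUC.

    Inactive scores ~ Exp(rate 1); active scores ~ Exp(rate
    (1-AUC)/AUC), so P(active > inactive) = AUC and the population ROC is
    y = x^((1-AUC)/AUC).
    """
    if not (0.0 < target_auc < 1.0):
        raise MolciError("target_auc must lie strictly in (0, 1)")
    if n_active < 1 or n_inactive < 1:
        raise MolciError("need at least one of each class")
    rng = _rng(seed)
    rate_active = (1.0 - target_auc) / target_auc
    actives = rng.exponential(scale=1.0 / rate_active, size=n_active)
    inactives = rng.exponential(scale=1.0, size=n_inactive)
    scores = np.concatenate([actives, inactives])
    labels = np.concatenate([np.ones(n_active, bool), np.zeros(n_inactive, bool)])
    return LabeledScores(scores=scores, labels=labels)


def gen_correlated_pairs(n_pairs: int, rho: float,
                         seed: int | np.random.Generator,
                         mu: float = 0.0, sigma: float = 1.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate Gaussian sample with population correlation rho."""
    if not abs(rho) < 1.0:
        raise MolciError("|rho| must be < 1")
    rng = _rng(seed)
    z1 = rng.standard_normal(n_pairs)
    z2 = rng.standard_normal(n_pairs)
    x = mu + sigma * z1
    y = mu + sigma * (rho * z1 + math.sqrt(1.0 - rho * rho) * z2)
    return x, y


def gen_gaussian(n: int, mu: float, sigma: float,
                 seed: int | np.random.Generator) -> np.ndarray:
    """n draws from N(mu, sigma)."""
    if sigma <= 0:
        raise MolciError("sigma must be > 0")
    return mu + sigma * _rng(seed).standard_normal(n)


@dataclass(frozen=True)
class CoverageResult:
    coverage: float
    hits: int
    n_replicates: int
    ci: ConfidenceInterval   # binomial uncertainty on the coverage itself


def coverage_experiment(interval_maker: Callable[[np.random.Generator], ConfidenceInterval],
                        truth: float, n_replicates: int,
                        seed: int | np.random.Generator) -> CoverageResult:
    """Fraction of replicate intervals containing the truth.

    ``interval_maker`` receives a per-replicate Generator and returns a
    ConfidenceInterval.  The coverage estimate carries its own binomial
    (logit) confidence interval.
    """
    if n_replicates < 100:
        raise MolciError("coverage experiments need >= 100 replicates")
    rng = _rng(seed)
    hits = 0
    for _ in range(n_replicates):
        ci = interval_maker(rng)
        if ci.lower <= truth <= ci.upper:
            hits += 1
    est = ProportionEstimate(successes=hits, trials=n_replicates)
    if hits in (0, n_replicates):
        cov_ci = proportion_ci_logit(est, level=0.95, continuity_correction=True)
    else:
        cov_ci = proportion_ci_logit(est, level=0.95)
    return CoverageResult(coverage=hits / n_replicates, hits=hits,
                          n_replicates=n_replicates, ci=cov_ci)
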