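"""ROC curves, AUC, and AUC uncertainty.

The AUC equals the probability that a randomly chosen active outscores a
randomly chosen inactive, ties counting one half.  Two variance estimates
are provided:

* **DeLong** (needs the primary score data): the AUC is an average of
  per-active placement probabilities p_i (fraction of inactives each active
  beats); its variance combines the spread of the p_i across actives with
  the mirror-image spread across inactives,

      Var_total = Var(p_active)/N_active + Var(p_inactive)/N_inactive.

* **Hanley** (needs only the AUC value w and the class counts): assumes the
  canonical exponential-score ROC family y = x^((1-w)/w), under which

      Var(p_active)   = w^2 (1-w) / (1+w)
      Var(p_inactive) = w (1-w)^2 / (2-w).

Because the two variance components carry different sample sizes, the
degrees of freedom for the t multiplier come from the Welch–Satterthwaite
rule; with an excess of inactives this tends to N_active - 1.

Confidence intervals are built on the logit scale so the bounds respect
[0, 1]: transform w, scale the SE by 1/(w(1-w)), add +/- t*SE, transform
back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ConfidenceInterval, ErrorComponent, resolve_multiplier, welch_satterthwaite
from .exceptions import InsufficientDataError, MolciError, SingleClassError

__all__ = [
    "LabeledScores",
    "RocCurve",
    "AucEstimate",
    "auc",
    "roc_curve",
    "delong_variance",
    "hanley_se",
    "hanley_curve",
    "auc_effective_df",
    "auc_ci",
]


@dataclass(frozen=True)
class LabeledScores:
    """Scores with binary activity labels for one screening experiment.

    ``higher_is_better=False`` flips the sign of the scores on ingest so
    that, internally, larger always means more active-like.
    """

    scores: np.ndarray
    labels: np.ndarray
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise MolciError("scores and labels must be equal-length 1-D arrays")
        if not np.all(np.isfinite(scores)):
            raise MolciError("scores must be finite")
        if not self.higher_is_better:
            scores = -scores
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "higher_is_better", True)

    @property
    def actives(self) -> np.ndarray:
        return self.scores[self.labels]

    @property
    def inactives(self) -> np.ndarray:
        return self.scores[~self.labels]

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())

    @property
    def n_inactive(self) -> int:
        return int((~self.labels).sum())

    def require_both_classes(self) -> None:
        if self.n_active == 0 or self.n_inactive == 0:
            raise SingleClassError("need at least one active and one inactive")

    def swapped_labels(self) -> "LabeledScores":
        return LabeledScores(self.scores.copy(), ~self.labels)


@dataclass(frozen=True)
class RocCurve:
    """Piecewise-linear ROC: points (f, g), inactive vs active fraction."""

    f: np.ndarray
    g: np.ndarray


@dataclass(frozen=True)
class AucEstimate:
    """AUC with its variance components and effective degrees of freedom.

    ``n_inactive=None`` is the "unbounded decoys" sentinel: the inactive
    variance term is dropped entirely (appropriate when decoys are in vast
    excess and their sampling noise is negligible).
    """

    auc: float
    var_active: float
    var_inactive: float
    n_active: int
    n_inactive: int | None
    se: float
    eff_df: float
    method: str = ""
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _placement(probes: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """For each probe score, fraction of reference scores it beats (ties 1/2)."""
    ref = np.sort(reference)
    left = np.searchsorted(ref, probes, side="left")
    right = np.searchsorted(ref, probes, side="right")
    return (left + 0.5 * (right - left)) / ref.size


def auc(data: LabeledScores) -> float:
    """Fraction of (active, inactive) pairs with the active ranked higher."""
    data.require_both_classes()
    return float(_placement(data.actives, data.inactives).mean())


def roc_curve(data: LabeledScores) -> RocCurve:
    """ROC from (0,0) to (1,1); tied scores form single diagonal steps."""
    data.require_both_classes()
    order = np.argsort(-data.scores, kind="stable")
    lab = data.labels[order].astype(float)
    s = data.scores[order]
    # group tied scores into single steps
    boundaries = np.nonzero(np.diff(s))[0] + 1
    tp = np.concatenate([[0.0], np.add.reduceat(lab, np.concatenate([[0], boundaries])).cumsum()])
    fp = np.concatenate([[0.0], np.add.reduceat(1.0 - lab, np.concatenate([[0], boundaries])).cumsum()])
    return RocCurve(f=fp / data.n_inactive, g=tp / data.n_active)


def delong_variance(data: LabeledScores) -> AucEstimate:
    """AUC variance from the primary data via placement probabilities."""
    data.require_both_classes()
    na, ni = data.n_active, data.n_inactive
    if na < 2 or ni < 2:
        raise InsufficientDataError("DeLong variance needs >= 2 of each class")
    p_act = _placement(data.actives, data.inactives)
    p_inact = _placement(data.inactives, data.actives)
    w = float(p_act.mean())
    var_active = float(((p_act - w) ** 2).sum() / (na - 1))
    var_inactive = float(((p_inact - (1.0 - w)) ** 2).sum() / (ni - 1))
    se = math.sqrt(var_active / na + var_inactive / ni)
    warnings: tuple[str, ...] = ()
    if var_active == 0.0 and var_inactive == 0.0:
        eff_df = float(na - 1)
        warnings = ("zero variance (perfect separation); eff_df set to N_active - 1",)
    else:
        eff_df = welch_satterthwaite([
            c for c in (
                ErrorComponent(var_active / na, na - 1) if var_active > 0 else None,
                ErrorComponent(var_inactive / ni, ni - 1) if var_inactive > 0 else None,
            ) if c is not None
        ])
    return AucEstimate(
        auc=w, var_active=var_active, var_inactive=var_inactive,
        n_active=na, n_inactive=ni, se=se, eff_df=eff_df,
        method="delong", warnings=warnings,
    )


def hanley_se(auc_value: float, n_active: int,
              n_inactive: int | None = None) -> AucEstimate:
    """Expected AUC standard error from the AUC value alone.

    Assumes the canonical ROC family; ``n_inactive=None`` drops the inactive
    term (decoys treated as unbounded).
    """
    if n_active < 1:
        raise InsufficientDataError("need n_active >= 1")
    if not (0.0 <= auc_value <= 1.0):
        raise MolciError("auc must lie in [0, 1]")
    w = auc_value
    if w in (0.0, 1.0):
        return AucEstimate(
            auc=w, var_active=0.0, var_inactive=0.0, n_active=n_active,
            n_inactive=n_inactive, se=0.0, eff_df=float(max(n_active - 1, 1)),
            method="hanley",
            warnings=("degenerate AUC on the boundary; zero SE is optimistic",),
        )
    var_active = w * w * (1.0 - w) / (1.0 + w)
    var_inactive = w * (1.0 - w) ** 2 / (2.0 - w)
    total = var_active / n_active
    if n_inactive is not None:
        if n_inactive < 1:
            raise InsufficientDataError("n_inactive must be >= 1 (or None for unbounded)")
        total += var_inactive / n_inactive
        eff_df = auc_effective_df(w, n_active, n_inactive) if (
            n_active >= 2 and n_inactive >= 2) else float(max(n_active - 1, 1))
    else:
        eff_df = float(max(n_active - 1, 1))
    return AucEstimate(
        auc=w, var_active=var_active,
        var_inactive=0.0 if n_inactive is None else var_inactive,
        n_active=n_active, n_inactive=n_inactive,
        se=math.sqrt(total), eff_df=eff_df, method="hanley",
    )


def hanley_curve(auc_value: float, x: float | np.ndarray) -> float | np.ndarray:
    """Canonical ROC family y = x^((1-w)/w) with area w."""
    if not (0.0 < auc_value <= 1.0):
        raise MolciError("auc must lie in (0, 1]")
    if auc_value == 1.0:
        return np.where(np.asarray(x) > 0, 1.0, 0.0) if np.ndim(x) else (1.0 if x > 0 else 0.0)
    exponent = (1.0 - auc_value) / auc_value
    return np.asarray(x) ** exponent if np.ndim(x) else float(x ** exponent)


def auc_effective_df(auc_value: float, n_active: int, n_inactive: int) -> float:
    """Welch–Satterthwaite df for the Hanley variance decomposition.

    nu = (a*Ni + b*Na)^2 / ((a*Ni)^2/(Na-1) + (b*Na)^2/(Ni-1))
    with a = w/(1+w), b = (1-w)/(2-w).  Approaches N_active - 1 when
    inactives are in great excess.
    """
    if n_active < 2 or n_inactive < 2:
        raise InsufficientDataError("effective df needs >= 2 of each class")
    if not (0.0 < auc_value < 1.0):
        raise MolciError("auc must lie strictly in (0, 1)")
    w = auc_value
    alpha = w / (1.0 + w)
    beta = (1.0 - w) / (2.0 - w)
    num = (alpha * n_inactive + beta * n_active) ** 2
    den = ((alpha * n_inactive) ** 2 / (n_active - 1)
           + (beta * n_active) ** 2 / (n_inactive - 1))
    return num / den


def auc_ci(auc_value: float, n_active: int, n_inactive: int | None = None,
           level: float = 0.95, multiplier: float | None = None,
           se: float | None = None, eff_df: float | None = None,
           transform: str = "logit") -> ConfidenceInterval:
    """Asymmetric AUC interval via the logit transform.

    The Hanley SE (or a caller-supplied ``se``, e.g. from DeLong) is scaled
    onto the logit axis by 1/(w(1-w)), symmetric t bounds are built there,
    and the bounds are mapped back through the logistic function, keeping
    them inside (0, 1).

    ``transform="none"`` returns the naive symmetric interval w +/- t*SE
    instead; near the boundaries its bounds can escape [0, 1], in which
    case the interval is flagged ``valid=False`` (the logit form is the
    fix).
    """
    if not (0.0 <= auc_value <= 1.0):
        raise MolciError("auc must lie in [0, 1]")
    w = auc_value
    if w in (0.0, 1.0):
        return ConfidenceInterval(
            estimate=w, lower=w, upper=w, level=level, method="auc-logit",
            df=float(max(n_active - 1, 1)), valid=True,
            warnings=("degenerate AUC on the boundary; zero-width interval",),
        )
    if se is None or eff_df is None:
        est = hanley_se(w, n_active, n_inactive)
        se = est.se if se is None else se
        eff_df = est.eff_df if eff_df is None else eff_df
    t = resolve_multiplier(level, eff_df, multiplier)
    if transform == "none":
        lower, upper = w - t * se, w + t * se
        valid = 0.0 <= lower and upper <= 1.0
        warnings = () if valid else (
            "symmetric bounds exit [0, 1]; use the logit transform",)
        return ConfidenceInterval(
            estimate=w, lower=lower, upper=upper, level=level,
            method="auc-gaussian", df=eff_df, valid=valid, warnings=warnings,
        )
    if transform != "logit":
        raise MolciError(f"transform must be 'logit' or 'none', got {transform!r}")
    f = math.log(w / (1.0 - w))
    se_f = se / (w * (1.0 - w))
    lower = 1.0 / (1.0 + math.exp(-(f - t * se_f)))
    upper = 1.0 / (1.0 + math.exp(-(f + t * se_f)))
    return ConfidenceInterval(
        estimate=w, lower=lower, upper=upper, level=level,
        method="auc-logit", df=eff_df,
    )
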