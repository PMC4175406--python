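"""Virtual-screening enrichment and its error bars.

Two definitions coexist in the literature:

* **ROC enrichment** e(f) = g/f — the fraction of actives recovered (g)
  when a fraction f of *inactives* has been passed.  It is intrinsic: it
  does not depend on the ratio R = inactives/actives in the assembled
  screening deck.
* **Traditional enrichment** E — actives recovered at a given fraction of
  the whole *database*, divided by that fraction.  It saturates at
  min(1/fraction, 1 + R), so its value is partly an artifact of deck
  composition.

The product e*f = g is the probability an active is found before a fraction
f of inactives; its variance combines the binomial noise of g and of f, the
latter scaled by the squared ROC slope S at the operating point:

    var(ef) = g(1-g)/A + S^2 * f(1-f)/I.

S comes either from the canonical ROC family (S = (g/f)(1 + log e/log f))
or from a finite difference of g around f.  Asymmetric bounds are built by
logit-transforming g = ef, then dividing the back-transformed bounds by f,
which keeps the enrichment interval inside (0, 1/f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ConfidenceInterval, ErrorComponent, resolve_multiplier, welch_satterthwaite
from .exceptions import BoundaryError, MolciError, ResolutionError
from .roc import LabeledScores

__all__ = [
    "EnrichmentPoint",
    "TraditionalEnrichment",
    "max_enrichment",
    "roc_enrichment",
    "hanley_slope",
    "finite_difference_slope",
    "roc_enrichment_variance",
    "roc_enrichment_ci",
    "to_traditional",
    "from_traditional",
    "traditional_variance",
    "traditional_enrichment_ci",
]


@dataclass(frozen=True)
class EnrichmentPoint:
    """One operating point of a ROC curve with deck composition attached."""

    f: float            # inactive fraction at the threshold
    g: float            # active fraction recovered
    n_active: int       # A
    n_inactive: int     # I

    def __post_init__(self) -> None:
        if not (0.0 < self.f <= 1.0):
            raise MolciError("f must lie in (0, 1]")
        if not (0.0 <= self.g <= 1.0):
            raise MolciError("g must lie in [0, 1]")

    @property
    def e(self) -> float:
        """ROC enrichment g/f."""
        return self.g / self.f

    @property
    def ratio(self) -> float:
        """R = inactives / actives."""
        return self.n_inactive / self.n_active


@dataclass(frozen=True)
class TraditionalEnrichment:
    """Database-fraction enrichment E with its saturation context."""

    E: float
    database_fraction: float
    ratio: float

    def __post_init__(self) -> None:
        cap = max_enrichment(self.database_fraction, self.ratio)
        if self.E > cap * (1.0 + 1e-9):
            raise MolciError(
                f"E={self.E} exceeds the saturation cap {cap} at "
                f"fraction={self.database_fraction}, R={self.ratio}"
            )


def max_enrichment(fraction: float, ratio: float) -> float:
    """Saturation bound min(1/fraction, 1+R) on traditional enrichment."""
    if not (0.0 < fraction <= 1.0):
        raise MolciError("fraction must lie in (0, 1]")
    if ratio < 0:
        raise MolciError("ratio must be >= 0")
    return min(1.0 / fraction, 1.0 + ratio)


def _active_fraction_at(data: LabeledScores, f: float) -> tuple[float, float]:
    """(f_used, g): g evaluated at the score of the ceil(f*I)-th inactive.

    The discrete convention: the threshold is the f*I-th highest inactive
    score (rounded up); actives strictly above it count fully, actives tied
    with it count one half, mirroring the AUC tie rule.
    """
    inact = np.sort(data.inactives)[::-1]
    ni = inact.size
    if f * ni < 1.0 - 1e-9:
        raise ResolutionError(
            f"f={f} is below the resolution 1/{ni} of the inactive set"
        )
    k = min(math.ceil(f * ni - 1e-9), ni)
    threshold = inact[k - 1]
    act = data.actives
    above = np.count_nonzero(act > threshold)
    ties = np.count_nonzero(act == threshold)
    g = (above + 0.5 * ties) / act.size
    return k / ni, g


def roc_enrichment(data: LabeledScores, f: float) -> EnrichmentPoint:
    """ROC enrichment point at inactive fraction f (threshold walk)."""
    data.require_both_classes()
    f_used, g = _active_fraction_at(data, f)
    return EnrichmentPoint(f=f_used, g=g,
                           n_active=data.n_active, n_inactive=data.n_inactive)


def hanley_slope(e: float, f: float) -> float:
    """ROC slope at (f, g=ef) under the canonical curve family.

    S = (g/f)(1 + log e / log f); equals the analytic derivative of
    y = x^((1-w)/w) at the operating point, and 1 at chance (e = 1).
    """
    if e <= 0:
        raise MolciError("e must be > 0")
    if not (0.0 < f < 1.0):
        raise MolciError("f must lie strictly in (0, 1) for the slope formula")
    return (e) * (1.0 + math.log(e) / math.log(f))


def finite_difference_slope(data: LabeledScores, f: float, delta: float = 0.005) -> float:
    """Central-difference ROC slope (g(f+d) - g(f-d)) / (2d).

    ``delta`` shrinks automatically near the edges of (0, 1).
    """
    d = min(delta, f / 2.0, (1.0 - f) / 2.0)
    if d <= 0:
        raise MolciError("f too close to the boundary for a finite difference")
    f_lo, g_lo = _active_fraction_at(data, f - d)
    f_hi, g_hi = _active_fraction_at(data, f + d)
    if f_hi == f_lo:
        raise ResolutionError("finite-difference step below data resolution")
    return (g_hi - g_lo) / (f_hi - f_lo)


def roc_enrichment_variance(point: EnrichmentPoint, slope: float) -> float:
    """var(e) = (g(1-g)/A + S^2 f(1-f)/I) / f^2."""
    g, f = point.g, point.f
    var_ef = (g * (1.0 - g) / point.n_active
              + slope * slope * f * (1.0 - f) / point.n_inactive)
    return var_ef / (f * f)


def roc_enrichment_ci(point: EnrichmentPoint, level: float = 0.95,
                      slope_mode: str = "hanley",
                      data: LabeledScores | None = None,
                      delta: float = 0.005,
                      multiplier: float | None = None) -> ConfidenceInterval:
    """Asymmetric CI on ROC enrichment via the logit of g = e*f.

    ``slope_mode="hanley"`` uses the canonical-curve slope from (e, f)
    alone; ``"finite_difference"`` estimates the slope from the score data
    (``data`` required).  Degrees of freedom follow Welch–Satterthwaite on
    the active and inactive variance contributions.
    """
    g, f = point.g, point.f
    if g in (0.0, 1.0):
        raise BoundaryError("g on the boundary; enrichment CI undefined")
    if slope_mode == "hanley":
        slope = hanley_slope(point.e, f) if f < 1.0 else 1.0
    elif slope_mode == "finite_difference":
        if data is None:
            raise MolciError("finite_difference slope needs the score data")
        slope = finite_difference_slope(data, f, delta)
    else:
        raise MolciError(f"unknown slope_mode {slope_mode!r}")
    a_term = g * (1.0 - g) / point.n_active
    i_term = slope * slope * f * (1.0 - f) / point.n_inactive
    components = [ErrorComponent(a_term, point.n_active - 1)]
    if i_term > 0:
        components.append(ErrorComponent(i_term, point.n_inactive - 1))
    eff_df = welch_satterthwaite(components)
    t = resolve_multiplier(level, eff_df, multiplier)
    se_g = math.sqrt(a_term + i_term)
    # logit-transform the probability g = e*f, then map bounds back and
    # rescale to enrichment units by dividing by f
    z = math.log(g / (1.0 - g))
    se_z = se_g / (g * (1.0 - g))
    g_lo = 1.0 / (1.0 + math.exp(-(z - t * se_z)))
    g_hi = 1.0 / (1.0 + math.exp(-(z + t * se_z)))
    return ConfidenceInterval(
        estimate=point.e, lower=g_lo / f, upper=g_hi / f, level=level,
        method=f"roc-enrichment-logit-{slope_mode}", df=eff_df,
    )


def to_traditional(point: EnrichmentPoint) -> TraditionalEnrichment:
    """Convert a ROC-enrichment operating point to database-fraction form.

    The database fraction screened when a fraction f of inactives and g of
    actives have been passed is F = (gA + fI)/(A + I) = (g + fR)/(1 + R);
    E = g/F.
    """
    R = point.ratio
    if R == 0:
        raise MolciError("conversion undefined for R = 0 (no inactives)")
    F = (point.g + point.f * R) / (1.0 + R)
    return TraditionalEnrichment(E=point.g / F, database_fraction=F, ratio=R)


def from_traditional(trad: TraditionalEnrichment,
                     n_active: int, n_inactive: int) -> EnrichmentPoint:
    """Inverse conversion: recover (f, g) from (E, F, R)."""
    R = trad.ratio
    if R == 0:
        raise MolciError("conversion undefined for R = 0")
    g = trad.E * trad.database_fraction
    f = ((1.0 + R) * trad.database_fraction - g) / R
    return EnrichmentPoint(f=f, g=g, n_active=n_active, n_inactive=n_inactive)


def traditional_variance(var_e: float, E: float, ratio: float) -> float:
    """var(E) = var(e) (1+R-E)^4 / ((1+R)^2 R^2)."""
    if ratio == 0:
        raise MolciError("variance conversion undefined for R = 0")
    return var_e * (1.0 + ratio - E) ** 4 / ((1.0 + ratio) ** 2 * ratio ** 2)


def traditional_enrichment_ci(point: EnrichmentPoint, level: float = 0.95,
                              slope_mode: str = "hanley",
                              data: LabeledScores | None = None,
                              multiplier: float | None = None) -> ConfidenceInterval:
    """Symmetric CI on traditional enrichment via the variance conversion.

    E = E +/- t * (1+R-E)^2 / ((1+R) R) * sqrt(var(e)).
    """
    trad = to_traditional(point)
    roc_ci = roc_enrichment_ci(point, level=level, slope_mode=slope_mode,
                               data=data, multiplier=multiplier)
    slope = (hanley_slope(point.e, point.f) if slope_mode == "hanley"
             else finite_difference_slope(data, point.f))
    var_e = roc_enrichment_variance(point, slope)
    R = trad.ratio
    t = resolve_multiplier(level, roc_ci.df, multiplier)
    half = t * (1.0 + R - trad.E) ** 2 / ((1.0 + R) * R) * math.sqrt(var_e)
    cap = max_enrichment(trad.database_fraction, R)
    upper = trad.E + half
    lower = trad.E - half
    warnings: tuple[str, ...] = ()
    valid = True
    if lower < 0 or upper > cap:
        valid = False
        warnings = (f"symmetric bounds exit [0, {cap:.4g}] (saturation cap); "
                    "interpret with the ROC-enrichment logit interval",)
    return ConfidenceInterval(
        estimate=trad.E, lower=lower, upper=upper, level=level,
        method=f"traditional-enrichment-{slope_mode}", df=roc_ci.df,
        valid=valid, warnings=warnings,
    )
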