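# Methods

This note records the statistical models behind `molci`, the conventions
and defaults chosen where the classical literature is ambiguous, what the
synthetic generators do and do not emulate, and known limitations.

## The general recipe

Every interval in the package follows one pattern: an estimate, a variance
for it, a degrees-of-freedom accounting, a Student-t multiplier, and — for
bounded quantities — a transform to an unbounded scale before the
symmetric ± step. Intervals are returned as a `ConfidenceInterval`
carrying the method tag and the df actually used; bounds that escape the
natural range of a quantity are never clipped silently but flagged
`valid=False`, because the breakage is diagnostic (it means the symmetric
approximation is the wrong tool at that sample size).

### Multiplier convention

The exact two-tailed Student-t quantile at the relevant df is the default
everywhere. A global `paper_compat` switch (and per-call `multiplier`
arguments) substitutes the round 2.0 that back-of-the-envelope 95% error
bars traditionally use; several classical worked examples are only
reproduced bit-for-bit under that convention, so it is exposed rather than
hidden. For the Fisher correlation interval the default multiplier is the
normal quantile (the transformed statistic is asymptotically normal and
carries no clean finite-sample df); a numeric multiplier reproduces
t-based conventions.

### Effective degrees of freedom

When a variance is a sum of components with different sample sizes
(AUC: actives and inactives; enrichment: the same), the t multiplier's df
comes from Welch–Satterthwaite,
ν = (Σvᵢ)²/Σ(vᵢ²/νᵢ) with vᵢ = Varᵢ/Nᵢ. Fractional df are accepted by all
quantile functions, so ν is never rounded. For the Hanley AUC variance the
rule reduces to a closed form in (AUC, N_active, N_inactive) with
α = w/(1+w), β = (1−w)/(2−w); with decoys in excess it approaches
N_active − 1, which is also the df used when the inactive term is dropped
entirely.

## Module notes

### Proportions

The Bernoulli variance p(1−p) drops the exact N/(N−1) prefactor by
default (an `exact_prefactor` flag restores it). The Gaussian interval is
reported untruncated with a validity flag; the logit interval
[p/(p+λ(1−p)), p/(p+λ⁻¹(1−p))], λ = exp(t/√(p(1−p)N)), is the
boundary-safe form and converges to the Gaussian one as N grows (they
agree to 1e−3 at N = 10⁶). Observed p of exactly 0 or 1 is an error for
the logit form unless the Laplace-style (m+½)/(N+1) correction is
requested — that correction is a pragmatic extension, not part of the
classical treatment. At small N the logit interval is conservative for
discreteness reasons: at p = 0.1, N = 50 its exact coverage (binomial
enumeration over m) is 0.975, not 0.95.

### AUC

AUC is computed from placement probabilities (fraction of inactives each
active beats, ties ½), which is also exactly what the DeLong variance
needs: Var(p_active) and Var(p_inactive) are the N−1 sample variances of
the per-active and per-inactive placements about w and 1−w. The Hanley
variance needs only (w, N_active, N_inactive) and assumes the canonical
one-parameter ROC family y = x^((1−w)/w) — the family generated by
exponential score distributions. `n_inactive=None` is an explicit
"unbounded decoys" sentinel that drops the inactive term; the classical
one-term SE examples require it. Confidence intervals logit-transform w,
scale the SE by 1/(w(1−w)) (the transform's derivative), and map the
symmetric bounds back, so AUC bounds always respect (0, 1). Simulations in
the test suite confirm the DeLong and Hanley SEs agree within 25% relative
on canonical-model decks (AUC 0.7, 50/500) and that the logit interval's
coverage is nominal at AUC 0.8, 50/500.

### Enrichment

Two definitions are kept deliberately distinct. ROC enrichment
e(f) = g/f is intrinsic; traditional enrichment E (per database fraction)
saturates at min(1/fraction, 1+R) and is only reported together with that
cap. The discrete threshold convention — the classical sources never state
one — is: g is evaluated at the score of the ⌈fI⌉-th ranked inactive,
actives tied with the threshold counting ½ (mirroring the AUC tie rule),
and f is reported as the realized ⌈fI⌉/I. Requests below the 1/I
resolution raise rather than extrapolate.

The variance treats ef = g as a probability whose noise has two sources:
var(ef) = g(1−g)/A + S²·f(1−f)/I, where S is the ROC slope at the
operating point. S defaults to the canonical-curve form
S = (g/f)(1 + log e/log f) (exactly the derivative of y = x^c on-curve);
a central finite difference of g at f ± δ (δ = 0.005 by default, shrunk
near boundaries) is available when the data should speak for themselves.
Asymmetric bounds logit-transform g, back-transform, and divide by f, so
the enrichment interval lives in (0, 1/f). Conversion to traditional form
uses the database fraction F = (g + fR)/(1+R) from the definitions, and
var(E) = var(e)(1+R−E)⁴/((1+R)²R²); the symmetric traditional interval is
checked against [0, cap] and flagged when it escapes.

### Correlation

`r_confidence_interval` returns tanh(arctanh(r) ± m/√(N−3)). The
significance threshold uses the slope-test identity t/√(N−2+t²) with t at
df = N−2 (the large-N variant t/√(N−3) is exposed for comparison). The
small-sample correction r(1−(1−r²)/(2(N−1))) *shrinks* the estimate; note
that the empirical sampling bias of r is downward, so this is a
convention inherited from the classical treatment rather than a bias
repair — the test suite verifies that the *magnitude* of the term matches
the empirical bias at ρ = 0.5, n = 10. Spearman's ρ is Pearson's r on
mid-ranks; its Fisher interval replaces N−3 with (N−3)/1.06, widening the
interval to reflect the rank statistic's extra variance.

### Regression

β = σ_xy/σ_x² and α = ȳ − βx̄, with the residual mean square on N−2 df.
The pointwise band is the band for the *fitted mean*:
ŷ ± t√((x₀−x̄)²var(β) + s²/N); centering absorbs the (α, β) covariance.
A `predictive=True` flag adds one extra residual variance for a
new-observation band — an extension beyond the mean band, labeled as
such. The approximate band t·(RMSE/√N)·√(1+12(x₀−x̄)²/L²) (L = x range,
RMSE over all N points) agrees with the exact band within ~10% for
uniformly spaced designs inside the data range, which the tests check at
n = 20.

### Dispersion

The Gaussian variance interval s² ± √2·t·s²/√(N−1) is the large-N
approximation; at N = 8 its lower bound is negative, and the interval is
returned in exactly that broken state (variance-scale lower bound,
`valid=False`) because hiding the failure would defeat its diagnostic
purpose. The exact interval divides (N−1)s² by the central χ² quantiles.
`df_convention` selects those quantiles at N−1 (statistically standard,
the default) or at N — the latter reproduces classical printed table
lookups that index by the number of variables; the multiplier (N−1)s²
is the same under both. The two conventions differ by ~2% at N = 50 and
the χ² interval converges to the Gaussian one at large N.

### Propagation and combination

`propagate` is the first-order sensitivity formula with optional
covariances (the caller supplies analytic sensitivities; a central
finite-difference helper with step max(1e−6, 1e−6|x|) covers black-box
functions). Log-fold errors use base-10 throughout: a "factor of 10"
uncertainty is an SD of 1 in log₁₀ units, n independent terms combine as
√n, and the CI factor is 10^(t·√n·log₁₀(fold)). Cohen's d here is the
single-sample μ/σ form with SE √((1+√2·d²)/N), and SE(c_V) = c_V²·SE(d)
by the reciprocal relation; the underlying independence of the sample
mean and SD holds for Gaussian data (checked by simulation). The ratio SE
is first-order and degrades as cv of the denominator grows; the tests
validate it at cv = 0.1 (2% agreement with Monte Carlo) — at cv = 0.2 the
true spread is already ~20% larger than the first-order value, so treat
the formula as a lower bound there.

Inverse-variance weighting applies when several measurements target the
*same* quantity; a zero-SE measurement legitimately dominates and is
returned exactly, with a note. The weighted variance uses the unbiased
prefactor ΣW/((ΣW)² − ΣW²), which reduces to 1/(N−1) for equal weights.
The benchmark decomposition subtracts per-system noise in quadrature from
the observed SE of the mean; a negative radicand (noise estimate exceeds
observed spread, expected occasionally under sampling) floors the
intrinsic SE at zero with a warning rather than erroring. Per-system AUC
errors default to the Hanley active-term with decoys assumed in excess.

### Bootstrap

Percentile method only (BCa is future work). The seed is mandatory.
Guards: a requested level must leave at least 40 resamples beyond each
bound (coarser tails cannot be established from the resample grid);
statistics annotated as `correlation`, `mode`, or `extreme` trigger
warnings describing the documented failure modes. The reuse diagnostic —
fraction of points drawn twice or more, expected
1 − (1−1/n)ⁿ − (1−1/n)ⁿ⁻¹ ≈ 26% — is reported per result.

## Synthetic data

The screening generator draws inactive scores from Exp(1) and active
scores from Exp((1−AUC)/AUC), for which P(active > inactive) equals the
target AUC exactly and the population ROC is exactly the canonical curve.
This makes the AUC-only formulas testable as population truths rather
than approximations. What it does not emulate: multimodal or sigmoidal
score distributions, correlated scores within chemical series, label
noise ("false false positives"), or score ties — so passing tests show
the machinery is correct under the canonical model, not that real docking
scores follow it. Near f = 0 the canonical curve's slope diverges and the
empirical ROC there is governed by extreme order statistics; curve-match
tests therefore compare for f ≥ 0.01.

The pairs generator is exactly bivariate Gaussian; real QSAR residuals
are often heavier-tailed, and the Fisher interval's coverage under such
tails is not established here.

## Problem sizes in the test suite

Coverage experiments use 2000 replicates (AUC logit at 50/500, OLS slope
at n = 100, t interval at n = 10) or 5000 (Fisher at n = 50, χ² SD at
n = 8, proportion logit at N = 50), which puts the binomial noise on an
empirical coverage near 0.95 at about ±0.005–0.010 — small against the
[0.93, 0.97] acceptance band. Agreement and recovery checks use 200–500
replicates; the generator fidelity check uses one 5000/5000 deck. These
sizes were chosen so each stochastic test pins its claim at ~3σ or better
while the whole suite stays interactive.

## Known limitations

* All intervals are frequentist; no Bayesian machinery.
* DeLong here gives a variance, not the paired-AUC comparison covariance.
* The enrichment slope from the canonical curve inherits that model; use
  the finite-difference mode when the measured curve is clearly
  non-canonical.
* The traditional-enrichment interval is symmetric (via the variance
  conversion) and can clip against the saturation cap; the ROC-enrichment
  logit interval is the better-behaved object.
* Welch–Satterthwaite is itself an approximation; with very unequal
  component dfs the t multiplier is approximate in the second decimal.
* `unbiased_r` follows the classical shrinkage convention discussed above.
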