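# molci

Confidence intervals and error bars for the metrics molecular modelers
actually report: docking success rates, ROC AUC, virtual-screening
enrichment, Pearson/Spearman correlation, regression slopes and prediction
bands, RMSE, propagated and combined errors, and benchmark-set error
decomposition — with a percentile bootstrap as the non-parametric
cross-check.

Most computational-chemistry papers quote an AUC of 0.82 or an RMSE of
1.4 kcal/mol without any statement of uncertainty. The statistics needed to
fix that are classical but scattered, and the naive symmetric interval
±2·SE is wrong for bounded quantities: it happily reports an AUC upper
bound of 1.03 or a negative variance. `molci` packages the correct
machinery:

* **Proportions** — Gaussian interval p ± t·√(p(1−p)/N), and the logit
  interval [p/(p+λ(1−p)), p/(p+λ⁻¹(1−p))], λ = exp(t/√(p(1−p)N)), whose
  bounds always stay inside (0, 1).
* **ROC AUC** — AUC as P(active outranks inactive), ties ½. Variance from
  the primary data (DeLong: Var(p_active)/N_a + Var(p_inactive)/N_i) or
  from the AUC alone (Hanley: Var_a = w²(1−w)/(1+w), Var_i = w(1−w)²/(2−w),
  assuming the canonical ROC family y = x^((1−w)/w)). Effective degrees of
  freedom from Welch–Satterthwaite; intervals built on the logit scale.
* **Enrichment** — ROC enrichment e(f) = g/f (intrinsic, independent of
  the inactive:active ratio R) with var(ef) = g(1−g)/A + S²·f(1−f)/I, the
  saturation cap min(1/fraction, 1+R) on traditional enrichment, and exact
  conversion between the two definitions.
* **Correlation** — Fisher transform F = arctanh(r), SE 1/√(N−3),
  asymmetric back-transformed intervals, the minimum significant r
  (t/√(N−2+t²)), the small-sample correction r(1−(1−r²)/(2(N−1))), a
  Spearman variant, and Theil's adjusted R².
* **Regression** — OLS with var(β) = s²/Σ(x−x̄)², var(α) = var(β)·Σx²/N,
  and pointwise bands ŷ ± t·√((x−x̄)²var(β) + s²/N) plus the
  RMSE/√N·√(1+12(x−x̄)²/L²) approximation.
* **Dispersion** — the Gaussian variance interval s² ± √2·t·s²/√(N−1)
  (which visibly breaks at small N) and the exact χ² interval
  (N−1)s²/χ²_hi < σ² < (N−1)s²/χ²_lo.
* **Error propagation & combination** — Σ(∂X/∂xᵢ)²var(xᵢ) with optional
  covariances, ratio SEs, log-fold (base-10) multiplicative errors, SEs of
  Cohen's d and the coefficient of variation, missing-error budgets,
  inverse-variance weighted means with SE² = 1/Σ(1/eᵢ²), unbiased weighted
  variance, and the intrinsic/system decomposition
  SE∞ = √(SE² − ΣErrᵢ²/(N(N−1))) with the add-a-noisy-system criterion
  σ²_intrinsic + 2σ²_system > Err²_new.
* **Bootstrap** — percentile intervals with guards for the known failure
  modes (tail resolution, correlation bias, extremes, modes).
* **Synthetic data** — exponential-score screening decks whose population
  ROC is exactly the canonical curve, bivariate Gaussian pairs, and a
  coverage-experiment harness, all seeded.

## Worked example

An AUC of 0.9 measured with only ten actives and a large excess of decoys:

```python
>>> from molci import hanley_se, auc_ci
>>> hanley_se(0.9, n_active=10).se
0.06529286250990105
>>> auc_ci(0.9, n_active=10, multiplier=2.0)
ConfidenceInterval(estimate=0.9, lower=0.6783658614365928,
                   upper=0.9746222481054618, level=0.95,
                   method='auc-logit', df=9.0, valid=True, warnings=())
>>> auc_ci(0.9, n_active=10, multiplier=2.0, transform="none")
ConfidenceInterval(estimate=0.9, lower=0.769414274980198,
                   upper=1.030585725019802, level=0.95,
                   method='auc-gaussian', df=9.0, valid=False,
                   warnings=('symmetric bounds exit [0, 1]; use the logit transform',))
```

The Hanley standard error is 0.065. The naive symmetric interval
[0.77, 1.03] overshoots 1 and is flagged invalid; the logit-transformed
interval [0.68, 0.97] is asymmetric (the uncertainty swings to the low
side) and stays inside [0, 1].

The same machinery from the shell:

```bash
$ molci rmse-ci --rmse 2.0 --n 8 --method chi2 --df-convention n
{"estimate": 2.0, "lower": 1.2636644011078386, "upper": 3.58407913776461,
 "level": 0.95, "method": "chi2-n", "df": 8, "valid": true, "warnings": [],
 "metric": "rmse"}
```

An RMSE of 2.0 from eight points really means σ could be anywhere from
1.26 to 3.58 — and the upper arm is much longer than the lower, which no
symmetric error bar can express.

## Layout

```
src/molci/
  core.py          quantiles, sample summaries, Welch–Satterthwaite
  proportions.py   Gaussian and logit intervals for probabilities
  roc.py           ROC curves, AUC, DeLong/Hanley variance, logit CIs
  enrichment.py    ROC & traditional enrichment, variances, conversion
  correlation.py   Fisher-transform intervals, significance, Spearman
  regression.py    OLS coefficients, CIs, prediction bands
  dispersion.py    Gaussian and chi-squared SD/RMSE intervals
  propagation.py   sensitivity propagation, ratios, log-fold, effect sizes
  aggregation.py   weighted means/variance, benchmark decomposition
  resampling.py    percentile bootstrap with failure-mode guards
  synthetic.py     seeded generators with known ground truth
  io.py, cli.py    CSV I/O, JSON records, the `molci` command
```

See `docs/methods.md` for the statistical background, parameter
conventions, and known limitations.
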