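import math

import numpy as np
import pytest

from molci import (
    ErrorComponent,
    LabeledScores,
    auc,
    auc_ci,
    auc_effective_df,
    delong_variance,
    hanley_curve,
    hanley_se,
    roc_curve,
    welch_satterthwaite,
)
from molci.exceptions import InsufficientDataError, SingleClassError
from .conftest import brute_force_auc


def _random_scores(rng, n_active, n_inactive, ties=False):
    scores = rng.normal(size=n_active + n_inactive)
    if ties:
        scores = np.round(scores, 1)  # force tied values
    labels = np.zeros(n_active + n_inactive, bool)
    labels[:n_active] = True
    return LabeledScores(scores=scores, labels=labels)


class TestAuc:
    def test_four_point_enumeration(self, four_point_scores):
        assert auc(four_point_scores) == pytest.approx(0.75)

    def test_single_tie_counts_one_half(self):
        data = LabeledScores(np.array([2.0, 2.0]), np.array([True, False]))
        assert auc(data) == pytest.approx(0.5)

    def test_perfect_separation(self):
        data = LabeledScores(np.array([3.0, 2.0, 1.0, 0.0]),
                             np.array([True, True, False, False]))
        assert auc(data) == 1.0

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_pairwise_oracle_on_random_instances(self, rng, ties):
        for _ in range(20):
            na, ni = rng.integers(2, 16, size=2)
            data = _random_scores(rng, na, ni, ties=ties)
            expected = brute_force_auc(data.actives, data.inactives)
            assert auc(data) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        data = _random_scores(rng, 30, 70, ties=True)
        assert auc(data) == pytest.approx(
            roc_auc_score(data.labels, data.scores), abs=1e-12)

    def test_label_swap_complement(self, rng):
        data = _random_scores(rng, 10, 20, ties=False)
        assert auc(data) + auc(data.swapped_labels()) == pytest.approx(1.0)

    def test_higher_is_better_flag(self, four_point_scores):
        flipped = LabeledScores(-four_point_scores.scores,
                                four_point_scores.labels, higher_is_better=False)
        assert auc(flipped) == pytest.approx(0.75)

    def test_single_class_error(self):
        with pytest.raises(SingleClassError):
            auc(LabeledScores(np.array([1.0, 2.0]), np.array([True, True])))


class TestRocCurve:
    def test_endpoints_and_monotonicity(self, rng):
        data = _random_scores(rng, 15, 40, ties=True)
        curve = roc_curve(data)
        assert curve.f[0] == 0.0 and curve.g[0] == 0.0
        assert curve.f[-1] == 1.0 and curve.g[-1] == 1.0
        assert np.all(np.diff(curve.f) >= 0) and np.all(np.diff(curve.g) >= 0)

    def test_area_by_trapezoid_matches_auc(self, rng):
        data = _random_scores(rng, 12, 33, ties=True)
        curve = roc_curve(data)
        assert np.trapezoid(curve.g, curve.f) == pytest.approx(auc(data), abs=1e-12)


class TestDelong:
    def test_four_point_hand_evaluation(self, four_point_scores):
        est = delong_variance(four_point_scores)
        assert est.auc == pytest.approx(0.75)
        assert est.var_active == pytest.approx(0.125)
        assert est.var_inactive == pytest.approx(0.125)
        assert est.se == pytest.approx(0.3536, abs=1e-4)

    def test_perfect_separation_zero_variance(self):
        data = LabeledScores(np.array([4.0, 3.0, 2.0, 1.0]),
                             np.array([True, True, False, False]))
        est = delong_variance(data)
        assert est.se == 0.0
        assert est.warnings

    def test_inactive_placements_complement_identity(self, rng):
        from molci.roc import _placement
        data = _random_scores(rng, 8, 21, ties=True)
        p_inact = _placement(data.inactives, data.actives)
        assert p_inact.mean() == pytest.approx(1.0 - auc(data), abs=1e-12)

    def test_se_squared_is_sum_of_scaled_components(self, rng):
        data = _random_scores(rng, 9, 17)
        est = delong_variance(data)
        assert est.se**2 == pytest.approx(
            est.var_active / est.n_active + est.var_inactive / est.n_inactive,
            rel=1e-12)

    def test_needs_two_of_each(self):
        with pytest.raises(InsufficientDataError):
            delong_variance(LabeledScores(np.array([2.0, 1.0, 0.0]),
                                          np.array([True, False, False])))


class TestHanley:
    def test_reference_se_unbounded_inactives(self):
        est = hanley_se(0.9, 10)
        assert est.se == pytest.approx(0.065, abs=5e-4)

    def test_finite_inactives_adds_small_term(self):
        est = hanley_se(0.9, 10, 1000)
        # active term 4.263e-3 plus inactive term 8.18e-6
        assert est.se == pytest.approx(math.sqrt(4.2632e-3 + 8.18e-6), abs=1e-4)
        assert est.se == pytest.approx(0.0654, abs=5e-4)

    def test_symmetry_at_half(self):
        est = hanley_se(0.5, 20, 20)
        assert est.var_active == pytest.approx(est.var_inactive)

    def test_degenerate_auc(self):
        est = hanley_se(1.0, 10)
        assert est.se == 0.0 and est.warnings

    def test_curve_examples(self):
        assert hanley_curve(0.5, 0.3) == pytest.approx(0.3)
        assert hanley_curve(0.9, 1.0) == 1.0
        assert hanley_curve(0.75, 0.1) == pytest.approx(0.4642, abs=1e-4)

    def test_curve_area_equals_auc(self):
        # integral of x^((1-w)/w) over [0,1] is w
        x = np.linspace(0, 1, 200_001)
        for w in (0.6, 0.75, 0.9):
            area = np.trapezoid(hanley_curve(w, x), x)
            assert area == pytest.approx(w, abs=1e-5)


class TestEffectiveDf:
    def test_excess_inactives_approaches_n_active_minus_1(self):
        nu = auc_effective_df(0.8, 20, 10**6)
        assert nu == pytest.approx(19.0, rel=1e-3)

    def test_symmetric_case_algebra(self):
        # auc=0.5: alpha = beta = 1/3, nu = 2(n-1)
        for n in (5, 20, 80):
            assert auc_effective_df(0.5, n, n) == pytest.approx(2 * (n - 1))

    def test_matches_welch_satterthwaite_on_hanley_components(self):
        w, na, ni = 0.75, 20, 1000
        est = hanley_se(w, na, ni)
        nu_ws = welch_satterthwaite([
            ErrorComponent(est.var_active / na, na - 1),
            ErrorComponent(est.var_inactive / ni, ni - 1),
        ])
        assert auc_effective_df(w, na, ni) == pytest.approx(nu_ws, rel=1e-12)


class TestAucCI:
    def test_logit_interval_reference_case(self):
        ci = auc_ci(0.9, 10, None, multiplier=2.0)
        assert ci.lower == pytest.approx(0.68, abs=0.005)
        assert ci.upper == pytest.approx(0.97, abs=0.005)

    def test_untransformed_interval_breaks_above_one(self):
        ci = auc_ci(0.9, 10, None, multiplier=2.0, transform="none")
        assert ci.upper == pytest.approx(1.03, abs=0.005)
        assert not ci.valid

    def test_symmetric_about_half(self):
        ci = auc_ci(0.5, 200, 200)
        assert ci.lower + ci.upper == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_auc_zero_width(self):
        ci = auc_ci(1.0, 10)
        assert ci.lower == ci.upper == 1.0
        assert ci.warnings

    def test_delong_se_can_drive_the_interval(self, rng):
        data = _random_scores(rng, 25, 75)
        est = delong_variance(data)
        ci = auc_ci(est.auc, est.n_active, est.n_inactive,
                    se=est.se, eff_df=est.eff_df)
        assert 0.0 < ci.lower < est.auc < ci.upper < 1.0
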