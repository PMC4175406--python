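import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molci import (
    EnrichmentPoint,
    LabeledScores,
    from_traditional,
    gen_screening_scores,
    hanley_slope,
    max_enrichment,
    roc_enrichment,
    roc_enrichment_ci,
    to_traditional,
)
from molci.enrichment import (
    finite_difference_slope,
    roc_enrichment_variance,
    traditional_enrichment_ci,
    traditional_variance,
)
from molci.exceptions import BoundaryError, MolciError, ResolutionError


class TestMaxEnrichment:
    def test_excess_inactives(self):
        # 10 actives / 990 inactives at 10%: cap is the reciprocal fraction
        assert max_enrichment(0.1, 99) == 10.0

    def test_saturation_by_ratio(self):
        # with R = 4 the deck composition caps enrichment at 5, not 10
        assert max_enrichment(0.1, 4) == 5.0

    def test_whole_database(self):
        assert max_enrichment(1.0, 123.0) == 1.0


class TestRocEnrichment:
    def test_four_point_threshold_walk(self, four_point_scores):
        point = roc_enrichment(four_point_scores, 0.5)
        assert point.f == pytest.approx(0.5)
        assert point.g == pytest.approx(0.5)
        assert point.e == pytest.approx(1.0)

    def test_chance_scores_give_unit_enrichment(self, rng):
        data = gen_screening_scores(2000, 2000, 0.5, rng)
        point = roc_enrichment(data, 0.1)
        assert point.e == pytest.approx(1.0, abs=0.35)

    def test_perfect_ranking_maximum(self):
        scores = np.concatenate([np.arange(10, 20), np.arange(10)]).astype(float)
        labels = np.arange(20) < 10
        point = roc_enrichment(LabeledScores(scores, labels), 0.5)
        assert point.g == 1.0
        assert point.e == pytest.approx(1.0 / point.f)

    def test_resolution_error(self, four_point_scores):
        with pytest.raises(ResolutionError):
            roc_enrichment(four_point_scores, 0.2)


class TestSlope:
    def test_chance_slope_is_one(self):
        assert hanley_slope(1.0, 0.1) == pytest.approx(1.0)

    def test_hand_value(self):
        assert hanley_slope(2.0, 0.1) == pytest.approx(1.398, abs=1e-3)

    @pytest.mark.parametrize("w,f", [(0.7, 0.05), (0.8, 0.1), (0.9, 0.2)])
    def test_matches_analytic_derivative_of_canonical_curve(self, w, f):
        # y = x^c has dy/dx = c x^(c-1); the slope formula must agree on-curve
        c = (1 - w) / w
        g = f**c
        analytic = c * f ** (c - 1)
        assert hanley_slope(g / f, f) == pytest.approx(analytic, rel=1e-6)

    def test_finite_difference_approximates_hanley_on_model_data(self, rng):
        data = gen_screening_scores(4000, 40000, 0.8, rng)
        point = roc_enrichment(data, 0.1)
        fd = finite_difference_slope(data, 0.1, delta=0.02)
        assert fd == pytest.approx(hanley_slope(point.e, point.f), rel=0.35)


class TestRocEnrichmentCI:
    def test_variance_composition(self):
        point = EnrichmentPoint(f=0.1, g=0.4, n_active=50, n_inactive=500)
        S = hanley_slope(point.e, point.f)
        var_ef = 0.4 * 0.6 / 50 + S**2 * 0.1 * 0.9 / 500
        assert roc_enrichment_variance(point, S) == pytest.approx(
            var_ef / 0.1**2, rel=1e-12)

    def test_unbounded_inactives_limit(self):
        point = EnrichmentPoint(f=0.1, g=0.4, n_active=50, n_inactive=10**9)
        S = hanley_slope(point.e, point.f)
        assert roc_enrichment_variance(point, S) == pytest.approx(
            0.4 * 0.6 / (50 * 0.01), rel=1e-4)

    def test_bounds_inside_zero_to_max(self):
        point = EnrichmentPoint(f=0.1, g=0.4, n_active=50, n_inactive=500)
        ci = roc_enrichment_ci(point)
        assert 0.0 < ci.lower <= ci.estimate <= ci.upper < 1.0 / point.f

    def test_boundary_g_rejected(self):
        with pytest.raises(BoundaryError):
            roc_enrichment_ci(EnrichmentPoint(f=0.1, g=1.0, n_active=10,
                                              n_inactive=100))

    def test_bootstrap_interval_overlaps_analytic(self, rng):
        # analytic CI vs percentile bootstrap on canonical-model data
        overlaps = 0
        reps = 200
        for _ in range(reps):
            data = gen_screening_scores(50, 1000, 0.8, rng)
            point = roc_enrichment(data, 0.1)
            if point.g in (0.0, 1.0):
                continue
            ci = roc_enrichment_ci(point)
            rows = np.column_stack([data.scores, data.labels.astype(float)])
            boots = np.empty(400)
            for b in range(400):
                idx = rng.integers(0, rows.shape[0], rows.shape[0])
                rs = rows[idx]
                d = LabeledScores(rs[:, 0], rs[:, 1] > 0.5)
                if d.n_active == 0 or d.n_inactive == 0:
                    boots[b] = np.nan
                    continue
                boots[b] = roc_enrichment(d, 0.1).e
            lo, hi = np.nanquantile(boots, [0.025, 0.975])
            if ci.lower <= hi and lo <= ci.upper:
                overlaps += 1
        assert overlaps / reps >= 0.95

    def test_intrinsic_to_deck_ratio(self, rng):
        # ROC enrichment means agree across decks with R=10 vs R=100
        means = []
        for n_inactive in (500, 5000):
            vals = [roc_enrichment(gen_screening_scores(50, n_inactive, 0.8, rng),
                                   0.1).e for _ in range(120)]
            means.append(np.mean(vals))
        assert means[0] == pytest.approx(means[1], rel=0.1)


class TestTraditionalConversion:
    def test_reference_definition(self):
        # 20% of actives at 10% of the database is an enrichment of 2.0;
        # with R = 10, F = (0.2 + 0.09*10)/11 = 0.1
        trad = to_traditional(EnrichmentPoint(f=0.09, g=0.2,
                                              n_active=100, n_inactive=1000))
        assert trad.database_fraction == pytest.approx(0.1, rel=1e-5)
        assert trad.E == pytest.approx(2.0, rel=1e-5)

    def test_chance_performance_unit_enrichment(self):
        trad = to_traditional(EnrichmentPoint(f=0.3, g=0.3,
                                              n_active=50, n_inactive=500))
        assert trad.E == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=100)
    @given(f=st.floats(0.01, 0.9), g=st.floats(0.01, 0.99),
           na=st.integers(5, 200), ni=st.integers(5, 2000))
    def test_round_trip_identity(self, f, g, na, ni):
        point = EnrichmentPoint(f=f, g=g, n_active=na, n_inactive=ni)
        back = from_traditional(to_traditional(point), na, ni)
        assert back.f == pytest.approx(f, abs=1e-10)
        assert back.g == pytest.approx(g, abs=1e-10)

    def test_variance_conversion_formula(self):
        assert traditional_variance(0.5, 2.0, 10.0) == pytest.approx(
            0.5 * (1 + 10 - 2.0) ** 4 / (11**2 * 100), rel=1e-12)

    def test_r_zero_undefined(self):
        with pytest.raises(MolciError):
            traditional_variance(0.5, 2.0, 0.0)

    def test_saturation_cap_respected_on_simulated_decks(self, rng):
        for _ in range(30):
            data = gen_screening_scores(20, 100, float(rng.uniform(0.55, 0.95)), rng)
            point = roc_enrichment(data, float(rng.uniform(0.05, 0.5)))
            trad = to_traditional(point)
            cap = max_enrichment(trad.database_fraction, trad.ratio)
            assert trad.E <= cap + 1e-9

    def test_traditional_ci_runs_and_reports_cap_breaks(self, rng):
        data = gen_screening_scores(50, 500, 0.8, rng)
        point = roc_enrichment(data, 0.1)
        ci = traditional_enrichment_ci(point)
        assert ci.estimate == pytest.approx(to_traditional(point).E)
        assert ci.df > 0
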