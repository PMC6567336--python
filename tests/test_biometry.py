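"""Model fits, the relative-error metric, and the printed-coefficient checks."""

import math

import numpy as np
import pytest

from seapen import (
    ColonyRecord,
    CubicWeightModel,
    RankDeficiencyError,
    ValidationError,
    fit_cubic_weight,
    fit_dry_weight,
    fit_linear_size,
    fit_weight_surface,
    generate_colonies,
    leaf_count_for_size,
    leaf_count_for_weight,
    predict_dry_weight,
    predict_fresh_weight,
    predict_length,
    predict_surface_weight,
    rachis_length,
    rms_relative_error,
)
from seapen.biometry import DryWeightModel, LinearSizeModel, SurfaceWeightModel

RACHIS = (2.6, -1.1)
TOTAL = (5.8, 8.1)
FRESH_CUBIC = (-0.0013, 0.076, -1.170, 5.342)
SURFACE = (2.28e-4, -0.023, 0.826, 0.039, -9.182)
DRY_CUBIC = (0.062, -0.412, 1.134, -0.416)


class TestPerRecordHelpers:
    def test_rachis_is_total_minus_peduncle(self):
        record = ColonyRecord("x", 20, 18, 135.7, 79.6, 2.5)
        assert rachis_length(record) == pytest.approx(56.1)

    def test_zero_peduncle_gives_rachis_equal_total(self):
        record = ColonyRecord("x", 20, 18, 135.7, 0.0, 2.5)
        assert rachis_length(record) == 135.7

    @pytest.mark.parametrize(
        "left,right,size_n,weight_n",
        [(20, 18, 20, 19.0), (20, 20, 20, 20.0), (0, 5, 5, 2.5), (21, 20, 21, 20.5)],
    )
    def test_side_count_conventions(self, left, right, size_n, weight_n):
        record = ColonyRecord("x", left, right, 135.7, 79.6, 2.5)
        assert leaf_count_for_size(record) == size_n
        assert leaf_count_for_weight(record) == weight_n


class TestRmsRelativeError:
    def test_perfect_predictions_give_zero(self):
        assert rms_relative_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_single_pair(self):
        assert rms_relative_error([1.1], [1.0]) == pytest.approx(0.1)

    def test_matches_literal_loop_oracle(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(1, 5, 10)
        obs = rng.uniform(1, 5, 10)
        total = 0.0
        for p, o in zip(pred, obs):
            total += ((p - o) / o) ** 2
        oracle = math.sqrt(total / len(obs))
        assert rms_relative_error(pred, obs) == pytest.approx(oracle, rel=1e-12)

    def test_zero_observation_is_a_domain_error(self):
        with pytest.raises(ValidationError):
            rms_relative_error([1.0], [0.0])


class TestLinearSizeFit:
    def test_exact_line_recovers_printed_rachis_coefficients(self):
        n = np.arange(10, 30)
        pairs = list(zip(n, 2.6 * n - 1.1))
        model = fit_linear_size(pairs)
        assert model.slope == pytest.approx(2.6, abs=1e-12)
        assert model.intercept == pytest.approx(-1.1, abs=1e-10)
        assert model.rms_relative_error == pytest.approx(0.0, abs=1e-12)
        assert model.correlation == pytest.approx(1.0)

    def test_unit_diagonal(self):
        model = fit_linear_size([(1, 1), (2, 2), (3, 3)])
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        pairs = [(14, 33.1), (17, 44.9), (20, 48.2), (23, 61.0), (26, 63.5)]
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        m = len(pairs)
        slope = (m * (x * y).sum() - x.sum() * y.sum()) / (
            m * (x * x).sum() - x.sum() ** 2
        )
        intercept = (y.sum() - slope * x.sum()) / m
        model = fit_linear_size(pairs)
        assert model.slope == pytest.approx(slope, rel=1e-10)
        assert model.intercept == pytest.approx(intercept, rel=1e-10)

    def test_degenerate_predictor_raises(self):
        with pytest.raises(RankDeficiencyError):
            fit_linear_size([(5, 1.0), (5, 2.0), (5, 3.0)])

    @pytest.mark.parametrize(
        "coef,n,expected",
        [(RACHIS, 22, 56.1), (TOTAL, 0, 8.1), (TOTAL, 22, 135.7)],
    )
    def test_predict_length_at_printed_coefficients(self, coef, n, expected):
        model = LinearSizeModel(
            slope=coef[0], intercept=coef[1],
            rms_relative_error=0.0, correlation=1.0, n_fit=0, slope_stderr=0.0,
        )
        assert predict_length(model, n) == pytest.approx(expected)


class TestCubicWeightFit:
    def test_exact_cubic_recovered_to_eight_digits(self):
        n = np.arange(16, 31, dtype=float)
        w = np.polyval(FRESH_CUBIC, n)
        model = fit_cubic_weight(list(zip(n, w)))
        for got, expected in zip(model.coefficients, FRESH_CUBIC):
            assert got == pytest.approx(expected, rel=1e-8)
        assert model.rms_relative_error == pytest.approx(0.0, abs=1e-10)

    def test_printed_coefficients_at_22_leaves(self):
        model = CubicWeightModel(*FRESH_CUBIC, rms_relative_error=0.46)
        assert predict_fresh_weight(model, 22) == pytest.approx(2.5436, abs=5e-3)

    def test_small_colony_prediction_is_not_applicable(self):
        model = CubicWeightModel(*FRESH_CUBIC, rms_relative_error=0.46)
        assert predict_fresh_weight(model, 10) is None
        assert predict_fresh_weight(model, 15) is None
        assert predict_fresh_weight(model, 16) is not None

    def test_negative_extrapolation_clamped_to_zero(self):
        model = CubicWeightModel(-1.0, 0.0, 0.0, 0.0, rms_relative_error=0.0,
                                 validity_min_n=15)
        assert predict_fresh_weight(model, 20) == 0.0

    def test_predictions_increase_up_to_the_cubic_maximum(self):
        # Dense evaluation shows the default cubic peaks near n = 28.1,
        # so strict monotonicity holds on 16..28 (not beyond).
        model = CubicWeightModel(*FRESH_CUBIC, rms_relative_error=0.46)
        values = [predict_fresh_weight(model, n) for n in range(16, 29)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_synthetic_fit_error_tracks_generating_noise(self, default_gen):
        colonies = generate_colonies(default_gen, 168, np.random.default_rng(21))
        pairs = [(leaf_count_for_weight(c), c.fresh_weight) for c in colonies]
        model = fit_cubic_weight(pairs)
        assert 0.35 <= model.rms_relative_error <= 0.60


class TestSurfaceFit:
    def test_printed_coefficients_at_mean_colony(self):
        model = SurfaceWeightModel(*SURFACE, rms_relative_error=0.387)
        assert predict_surface_weight(model, 22, 56.1) == pytest.approx(2.474, abs=5e-3)

    def test_exact_surface_recovered(self):
        rng = np.random.default_rng(2)
        n = rng.uniform(15, 30, 40)
        lr = 2.6 * n - 1.1 + rng.normal(0, 5, 40)
        w = (
            SURFACE[0] * n ** 3 + SURFACE[1] * n ** 2 + SURFACE[2] * n
            + SURFACE[3] * lr + SURFACE[4]
        )
        model = fit_weight_surface(list(zip(n, lr, w)))
        got = (model.a3, model.a2, model.a1, model.b1, model.a0)
        for g, e in zip(got, SURFACE):
            assert g == pytest.approx(e, rel=1e-7)

    def test_collinear_rachis_is_rank_deficient(self):
        n = np.arange(15, 25, dtype=float)
        lr = 2.6 * n - 1.1          # exactly linear in n
        w = np.polyval(FRESH_CUBIC, n)
        with pytest.raises(RankDeficiencyError):
            fit_weight_surface(list(zip(n, lr, w)))

    def test_surface_rss_never_exceeds_cubic_rss(self, default_gen):
        # The surface nests the cubic, so its fitting criterion (absolute
        # squared error) can only improve on the same data.
        colonies = generate_colonies(default_gen, 168, np.random.default_rng(22))
        n = np.array([leaf_count_for_weight(c) for c in colonies])
        lr = np.array([rachis_length(c) for c in colonies])
        w = np.array([c.fresh_weight for c in colonies])
        cubic = fit_cubic_weight(list(zip(n, w)))
        surface = fit_weight_surface(list(zip(n, lr, w)))
        rss_cubic = np.sum((np.polyval(cubic.coefficients, n) - w) ** 2)
        pred_surface = (
            surface.a3 * n ** 3 + surface.a2 * n ** 2 + surface.a1 * n
            + surface.b1 * lr + surface.a0
        )
        rss_surface = np.sum((pred_surface - w) ** 2)
        assert rss_surface <= rss_cubic + 1e-9


class TestDryWeightFit:
    def test_printed_coefficients_at_mean_fresh_weight(self):
        model = DryWeightModel(*DRY_CUBIC, rms_relative_error=0.192)
        assert predict_dry_weight(model, 2.39) == pytest.approx(0.787, abs=5e-3)

    def test_exact_cubic_pairs_recovered(self):
        wf = np.linspace(0.5, 6.0, 30)
        wd = np.polyval(DRY_CUBIC, wf)
        model = fit_dry_weight(list(zip(wf, wd)))
        for got, expected in zip(model.coefficients, DRY_CUBIC):
            assert got == pytest.approx(expected, rel=1e-8)
        assert model.rms_relative_error == pytest.approx(0.0, abs=1e-10)

    def test_synthetic_subset_error_tracks_generating_noise(self, default_gen):
        colonies = generate_colonies(default_gen, 600, np.random.default_rng(23))
        pairs = [
            (c.fresh_weight, c.dry_weight)
            for c in colonies
            if c.dry_weight is not None and c.fresh_weight > 0.5
        ][:54]
        model = fit_dry_weight(pairs)
        assert 0.10 <= model.rms_relative_error <= 0.35


class TestFitInvariants:
    def test_stored_error_matches_recomputation_on_training_data(self, default_gen):
        colonies = generate_colonies(default_gen, 168, np.random.default_rng(24))
        pairs = [(leaf_count_for_weight(c), c.fresh_weight) for c in colonies]
        model = fit_cubic_weight(pairs)
        n = np.array([p[0] for p in pairs])
        w = np.array([p[1] for p in pairs])
        keep = n > model.validity_min_n
        recomputed = rms_relative_error(
            np.polyval(model.coefficients, n[keep]), w[keep]
        )
        assert model.rms_relative_error == pytest.approx(recomputed, rel=1e-12)

    def test_coefficient_perturbation_never_reduces_rss(self, default_gen):
        colonies = generate_colonies(default_gen, 168, np.random.default_rng(25))
        n = np.array([leaf_count_for_weight(c) for c in colonies])
        w = np.array([c.fresh_weight for c in colonies])
        model = fit_cubic_weight(list(zip(n, w)))
        base = np.array(model.coefficients)
        rss0 = np.sum((np.polyval(base, n) - w) ** 2)
        for index in range(4):
            for factor in (0.99, 1.01):
                probe = base.copy()
                probe[index] *= factor
                assert np.sum((np.polyval(probe, n) - w) ** 2) >= rss0
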