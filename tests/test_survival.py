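"""Unit and property tests for the clonogenic survival chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radioassay.survival import (
    ClonogenicRecord,
    CountSummary,
    LQFitResult,
    PlatingEfficiency,
    SurvivalPoint,
    dose_uncertainty,
    fit_lq,
    isoeffective_dose,
    lq_survival,
    plating_efficiency,
    pool_survival_points,
    reduce_clonogenic,
    summarize_counts,
    surviving_fraction,
)

RNG = np.random.default_rng(20180118)


def mc_ratio_se(num_mean, num_se, den_mean, den_se, n=200_000, seed=0):
    """Monte-Carlo oracle for the SE of a ratio of two Gaussian means."""
    rng = np.random.default_rng(seed)
    num = rng.normal(num_mean, num_se, n)
    den = rng.normal(den_mean, den_se, n)
    return float((num / den).std(ddof=1))


class TestSummarizeCounts:
    @pytest.mark.parametrize(
        "counts, mean, se",
        [
            # observed SEM 0 is floored at sqrt(mean/n) = sqrt(100/4)
            ([100, 100, 100, 100], 100.0, 5.0),
            # observed SEM 10 exceeds the floor sqrt(100/2) ~ 7.07
            ([90, 110], 100.0, 10.0),
        ],
    )
    def test_mean_and_floored_se(self, counts, mean, se):
        s = summarize_counts(counts)
        assert s.mean == pytest.approx(mean)
        assert s.se == pytest.approx(se)
        assert s.n == len(counts)

    def test_all_zero_counts_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = summarize_counts([0])
        assert s.mean == 0 and s.se == 0

    def test_floor_can_be_disabled(self):
        assert summarize_counts([100] * 4, apply_poisson_floor=False).se == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            summarize_counts([])


class TestPlatingEfficiency:
    def test_ratio_of_means_zero_error(self):
        pe = plating_efficiency(CountSummary(58, 0, 4), CountSummary(100, 0, 4))
        assert pe.pe == pytest.approx(0.58)
        assert pe.se_pe == 0.0

    def test_single_term_propagation(self):
        pe = plating_efficiency(CountSummary(58, 2, 4), CountSummary(100, 0, 4))
        assert pe.se_pe == pytest.approx(0.02)

    def test_propagation_matches_monte_carlo(self):
        pe = plating_efficiency(CountSummary(58, 2, 4), CountSummary(100, 5, 4))
        oracle = mc_ratio_se(58, 2, 100, 5, seed=1)
        assert pe.se_pe == pytest.approx(oracle, rel=0.02)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            plating_efficiency(CountSummary(58, 2, 4), CountSummary(0, 0, 4))


class TestSurvivingFraction:
    def test_self_normalization_at_zero_dose(self):
        col, cel = CountSummary(58, 2, 4), CountSummary(100, 0, 4)
        pe = plating_efficiency(col, cel)
        pt = surviving_fraction(col, cel, pe, dose=0.0)
        assert pt.sf == pytest.approx(1.0)

    def test_exact_inputs_give_exact_sf(self):
        pt = surviving_fraction(
            CountSummary(25, 0, 4), CountSummary(100, 0, 4),
            PlatingEfficiency(0.5, 0.0), dose=2.0,
        )
        assert pt.sf == pytest.approx(0.5) and pt.se_sf == 0.0

    def test_propagation_matches_monte_carlo(self):
        pe = PlatingEfficiency(0.58, 0.02)
        pt = surviving_fraction(
            CountSummary(10, 1, 4), CountSummary(1000, 0, 4), pe, dose=3.0
        )
        rng = np.random.default_rng(2)
        n = 200_000
        sf_draws = rng.normal(10, 1, n) / 1000 / rng.normal(0.58, 0.02, n)
        assert pt.se_sf == pytest.approx(float(sf_draws.std(ddof=1)), rel=0.02)

    def test_zero_colonies_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            pt = surviving_fraction(
                CountSummary(0, 0, 4), CountSummary(1000, 0, 4),
                PlatingEfficiency(0.5, 0.0), dose=6.0,
            )
        assert pt.degenerate


class TestLQSurvival:
    def test_zero_dose_identity(self):
        assert lq_survival(0.0, 0.7, 0.05) == 1.0

    def test_hand_values(self):
        assert lq_survival(1.0, 0.705, 0.0) == pytest.approx(math.exp(-0.705))
        assert lq_survival(2.0, 0.314, 0.035) == pytest.approx(math.exp(-0.768))

    @given(
        alpha=st.floats(0.01, 2), beta=st.floats(0, 0.5),
        lo=st.floats(0, 10), step=st.floats(1e-3, 5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_strictly_decreasing_in_dose(self, alpha, beta, lo, step):
        assert lq_survival(lo + step, alpha, beta) < lq_survival(lo, alpha, beta)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            lq_survival(-1.0, 0.5, 0.0)


def _model_points(alpha, beta, doses=(0.5, 1, 2, 3, 4), se=0.0):
    return [
        SurvivalPoint(d, lq_survival(d, alpha, beta), se * lq_survival(d, alpha, beta))
        for d in doses
    ]


class TestFitLQ:
    def test_noise_free_lq_round_trip(self):
        fit = fit_lq(_model_points(0.5, 0.05))
        assert fit.model_form == "linear_quadratic"
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.beta == pytest.approx(0.05, abs=1e-6)

    def test_noise_free_exponential_flagged(self):
        fit = fit_lq(_model_points(0.705, 0.0))
        assert fit.model_form == "pure_exponential"
        assert fit.beta == 0.0 and fit.sigma_beta == 0.0
        assert fit.alpha == pytest.approx(0.705, abs=1e-6)

    def test_force_pure_exponential(self):
        fit = fit_lq(_model_points(0.5, 0.05), force_pure_exponential=True)
        assert fit.model_form == "pure_exponential"

    def test_estimates_invariant_under_uniform_se_rescaling(self):
        # clearly quadratic curve with mild perturbations so the model-form
        # selection is stable under the rescaling as well
        pts = _model_points(0.4, 0.1, se=0.005)
        noisy = [
            SurvivalPoint(p.dose, p.sf * f, p.se_sf)
            for p, f in zip(pts, [1.002, 0.998, 1.003, 0.997, 1.001])
        ]
        scaled = [SurvivalPoint(p.dose, p.sf, 10 * p.se_sf) for p in noisy]
        f1, f2 = fit_lq(noisy), fit_lq(scaled)
        assert f1.model_form == f2.model_form == "linear_quadratic"
        assert f1.alpha == pytest.approx(f2.alpha, rel=1e-6)
        assert f1.beta == pytest.approx(f2.beta, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_lq(_model_points(0.5, 0.05, doses=(1, 2)))


class TestIsoeffectiveDose:
    def test_level_one_gives_zero_dose(self, mid_sobp_test):
        assert isoeffective_dose(mid_sobp_test, 1.0) == 0.0

    def test_pure_exponential_closed_form(self, mid_sobp_test):
        assert isoeffective_dose(mid_sobp_test, 0.1) == pytest.approx(
            math.log(10) / 0.705
        )

    def test_quadratic_root_matches_bisection(self, mid_sobp_ref):
        lo, hi = 0.0, 50.0
        for _ in range(200):  # bisection on the forward model to 1e-10 Gy
            mid = (lo + hi) / 2
            if lq_survival(mid, 0.314, 0.035) > 0.1:
                lo = mid
            else:
                hi = mid
        assert isoeffective_dose(mid_sobp_ref, 0.1) == pytest.approx(lo, abs=1e-8)
        assert isoeffective_dose(mid_sobp_ref, 0.1) == pytest.approx(4.783, abs=1e-3)

    @given(
        alpha=st.floats(0.05, 2), beta=st.floats(0, 0.3), dose=st.floats(0.01, 10)
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_through_survival(self, alpha, beta, dose):
        fit = LQFitResult(alpha, 0, beta, 0, "linear_quadratic", 5, 0)
        sf = lq_survival(dose, alpha, beta)
        if sf > 1e-300:
            assert isoeffective_dose(fit, sf) == pytest.approx(dose, abs=1e-8)

    def test_flat_curve_rejected(self):
        flat = LQFitResult(0, 0, 0, 0, "linear_quadratic", 5, 0)
        with pytest.raises(ValueError):
            isoeffective_dose(flat, 0.5)


class TestDoseUncertainty:
    def test_zero_parameter_errors_give_zero(self):
        fit = LQFitResult(0.3, 0.0, 0.03, 0.0, "linear_quadratic", 5, 0)
        assert dose_uncertainty(fit, 3.0) == 0.0

    def test_pure_exponential_reduction(self, mid_sobp_test):
        d = 3.0
        assert dose_uncertainty(mid_sobp_test, d) == pytest.approx(
            d * 0.033 / 0.705
        )

    def test_matches_finite_difference_oracle(self, mid_sobp_ref):
        level = 0.1
        d = isoeffective_dose(mid_sobp_ref, level)
        h = 1e-7
        grads = []
        for da, db in ((h, 0), (0, h)):
            up = LQFitResult(0.314 + da, 0, 0.035 + db, 0, "linear_quadratic", 5, 0)
            dn = LQFitResult(0.314 - da, 0, 0.035 - db, 0, "linear_quadratic", 5, 0)
            grads.append(
                (isoeffective_dose(up, level) - isoeffective_dose(dn, level)) / (2 * h)
            )
        oracle = math.sqrt((grads[0] * 0.022) ** 2 + (grads[1] * 0.007) ** 2)
        assert dose_uncertainty(mid_sobp_ref, d) == pytest.approx(oracle, abs=1e-6)


class TestReduceAndPool:
    def test_reduce_yields_unity_at_zero_dose(self):
        records = [
            ClonogenicRecord(d, 1000, c, f"r{i}", "cond")
            for d, counts in [(0.0, [580, 600, 590, 610]), (2.0, [200, 210, 190, 205])]
            for i, c in enumerate(counts)
        ]
        points = reduce_clonogenic(records)["cond"]
        assert points[0].dose == 0.0 and points[0].sf == pytest.approx(1.0)
        assert 0 < points[1].sf < 1

    def test_missing_zero_dose_rejected(self):
        with pytest.raises(ValueError, match="0 Gy"):
            reduce_clonogenic([ClonogenicRecord(2.0, 100, 50)])

    def test_pooling_is_inverse_variance_weighted(self):
        a = [SurvivalPoint(1.0, 0.5, 0.01)]
        b = [SurvivalPoint(1.0, 0.6, 0.02)]
        pooled = pool_survival_points([a, b])[0]
        w1, w2 = 1 / 0.01**2, 1 / 0.02**2
        assert pooled.sf == pytest.approx((0.5 * w1 + 0.6 * w2) / (w1 + w2))
        assert pooled.se_sf == pytest.approx(1 / math.sqrt(w1 + w2))

    def test_pooling_exact_points_plain_mean(self):
        pooled = pool_survival_points(
            [[SurvivalPoint(1.0, 0.5, 0.0)], [SurvivalPoint(1.0, 0.7, 0.0)]]
        )[0]
        assert pooled.sf == pytest.approx(0.6) and pooled.se_sf == 0.0
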