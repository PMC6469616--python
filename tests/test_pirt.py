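"""Model fits: exactness, symmetry, oracle equivalence, fraction curves."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import ma_brute
from pirtfield import (
    PirtFit,
    fit_major_axis,
    fit_quadratic,
    fraction_curve,
    maintenance_fraction,
    predict_rsb,
)
from pirtfield.errors import ConfigurationError, InputError, UndefinedSlopeError

MU = np.linspace(0.01, 0.2, 22)


class TestMajorAxisFit:
    def test_exact_line_recovered_to_machine_precision(self):
        fit = fit_major_axis(MU, 0.32 + 8.0 * MU, interval_method="none")
        assert fit.b == pytest.approx(8.0, abs=1e-12)
        assert fit.rm == pytest.approx(0.32, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_swapping_axes_inverts_the_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        y = 2.0 * x + rng.normal(0, 1, 40)
        fxy = fit_major_axis(x, y, interval_method="none")
        fyx = fit_major_axis(y, x, interval_method="none")
        assert fyx.b == pytest.approx(1.0 / fxy.b, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_perpendicular_distance_minimiser(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 30)
        x = rng.uniform(0, 1, n)
        y = rng.normal(0.5, 1.0, n) + rng.uniform(-3, 3) * x
        fit = fit_major_axis(x, y, interval_method="none")
        slope, intercept = ma_brute(x, y)
        assert fit.b == pytest.approx(slope, abs=1e-6)
        assert fit.rm == pytest.approx(intercept, abs=1e-6)

    def test_ols_slope_attenuated_relative_to_major_axis(self):
        """With error on x, OLS attenuates; the major axis does not."""
        rng = np.random.default_rng(3)
        x_true = rng.uniform(0, 1, 200)
        y = 1.5 * x_true + rng.normal(0, 0.3, 200)
        x_obs = x_true + rng.normal(0, 0.3, 200)
        ols = np.polyfit(x_obs, y, 1)[0]
        ma = fit_major_axis(x_obs, y, interval_method="none").b
        assert abs(ols) <= abs(ma)

    def test_bootstrap_interval_brackets_estimate(self):
        rng = np.random.default_rng(4)
        y = 0.32 + 8.0 * MU + rng.normal(0, 0.05, MU.size)
        fit = fit_major_axis(MU, y, n_boot=500, seed=0)
        assert fit.rm_interval[0] <= fit.rm <= fit.rm_interval[1]
        assert fit.b_interval[0] <= fit.b <= fit.b_interval[1]

    def test_analytic_interval_available_behind_flag(self):
        rng = np.random.default_rng(5)
        y = 0.32 + 8.0 * MU + rng.normal(0, 0.05, MU.size)
        fit = fit_major_axis(MU, y, interval_method="major-axis-analytic")
        assert fit.rm_interval[0] < fit.rm < fit.rm_interval[1]
        assert fit.b_interval[0] < fit.b < fit.b_interval[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            fit_major_axis([0.1, 0.1, 0.1], [1.0, 2.0, 3.0], interval_method="none")
        with pytest.raises(InputError):
            fit_major_axis([0.1, 0.2], [1.0, 2.0], interval_method="none")
        with pytest.raises(UndefinedSlopeError):
            fit_major_axis([-1.0, 0.0, 1.0], [1.0, 0.0, 1.0], interval_method="none")

    def test_bootstrap_without_seed_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_major_axis(MU, 0.32 + 8.0 * MU)

    def test_negative_intercept_warned_not_clamped(self):
        rng = np.random.default_rng(6)
        y = -0.5 + 8.0 * MU + rng.normal(0, 0.01, MU.size)
        with pytest.warns(UserWarning, match="negative"):
            fit = fit_major_axis(MU, y, interval_method="none")
        assert fit.rm < 0


class TestQuadraticFit:
    def test_exact_parabola_recovered(self):
        fit = fit_quadratic(MU, 0.58 + 28.7 * MU**2, n_boot=0)
        assert fit.rm == pytest.approx(0.58, abs=1e-12)
        assert fit.b == pytest.approx(28.7, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response_gives_pure_maintenance(self):
        fit = fit_quadratic(MU, np.full(MU.size, 0.7), n_boot=0)
        assert fit.rm == pytest.approx(0.7)
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_trimmed_range_brackets_estimate(self):
        rng = np.random.default_rng(7)
        y = 0.58 + 28.7 * MU**2 + rng.normal(0, 0.08, MU.size)
        fit = fit_quadratic(MU, y, n_boot=500, seed=1)
        assert fit.rm_interval[0] <= fit.rm <= fit.rm_interval[1]
        assert fit.b_interval[0] <= fit.b <= fit.b_interval[1]

    def test_degenerate_mu_rejected(self):
        with pytest.raises(InputError):
            fit_quadratic([0.1, 0.1, 0.1], [1.0, 1.1, 0.9], n_boot=0)


LIN_FIT = PirtFit(form="linear", rm=0.32, b=8.0, r2=0.45, n=22)
QUAD_FIT = PirtFit(form="quadratic", rm=0.58, b=28.7, r2=0.57, n=22)


class TestPrediction:
    @pytest.mark.parametrize(
        "fit, mu, expected",
        [
            (LIN_FIT, 0.14, 1.44),
            (LIN_FIT, 0.0, 0.32),
            (QUAD_FIT, 0.06, 0.68332),
            (QUAD_FIT, 0.0, 0.58),
        ],
    )
    def test_point_predictions(self, fit, mu, expected):
        assert predict_rsb(fit, mu) == pytest.approx(expected)

    def test_negative_mu_rejected(self):
        with pytest.raises(InputError):
            predict_rsb(LIN_FIT, -0.01)


class TestMaintenanceFraction:
    def test_linear_fraction_at_low_growth(self):
        # over 40% of respiration is maintenance below mu = 0.06
        assert maintenance_fraction(LIN_FIT, 0.06) == pytest.approx(0.40, abs=1e-12)

    def test_quadratic_fraction_at_low_growth(self):
        assert maintenance_fraction(QUAD_FIT, 0.06) == pytest.approx(0.849, abs=5e-4)

    def test_all_maintenance_at_zero_growth(self):
        for fit in (LIN_FIT, QUAD_FIT):
            assert maintenance_fraction(fit, 0.0) == 1.0

    @given(
        rm=st.floats(0.05, 2.0),
        b=st.floats(0.5, 50.0),
        form=st.sampled_from(["linear", "quadratic"]),
    )
    def test_strictly_decreasing_to_zero(self, rm, b, form):
        fit = PirtFit(form=form, rm=rm, b=b, r2=1.0, n=10)
        grid = np.linspace(0.0, 5.0, 200)
        frac = np.asarray(maintenance_fraction(fit, grid))
        assert frac[0] == 1.0
        assert np.all(np.diff(frac) < 0)
        # vanishes as growth dominates
        assert maintenance_fraction(fit, 1e4 * rm / b) < 0.01

    def test_curve_container(self):
        curve = fraction_curve(QUAD_FIT, np.linspace(0.0, 0.28, 15))
        assert curve.form == "quadratic"
        assert np.all((curve.fraction > 0) & (curve.fraction <= 1))


class TestParameterRecoveryNoiseless:
    def test_both_fitters_recover_generating_parameters(self):
        from pirtfield import TransectSpec, make_transect

        for form, rm, b, fitter in [
            ("linear", 0.32, 8.0, fit_major_axis),
            ("quadratic", 0.58, 28.7, fit_quadratic),
        ]:
            spec = TransectSpec(model_form=form, true_rm=rm, true_b=b,
                                residual_sd=0.0, mu_noise_sd=0.0, seed=9)
            table = make_transect(spec).table
            rsb = (table["r_bulk"] / table["abundance"] * 1e9).to_numpy()
            kwargs = {"interval_method": "none"} if form == "linear" else {"n_boot": 0}
            fit = fitter(table["true_mu"].to_numpy(), rsb, **kwargs)
            assert fit.rm == pytest.approx(rm, abs=1e-8)
            assert fit.b == pytest.approx(b, abs=1e-8)
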