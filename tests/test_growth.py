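"""Exponential fitting, doubling times, group comparison, Nash calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c1flux.errors import CalibrationError, DomainError, FitError
from c1flux.growth import (
    GrowthCurve,
    calibrate_nash,
    compare_groups,
    doubling_time,
    fit_exponential,
    invert_nash,
    pool_fits,
)
from c1flux.synth import GrowthScenario, gen_growth_curve


class TestFitExponential:
    @pytest.mark.parametrize("mu", [0.036, 0.25, 0.7])
    def test_exact_on_noiseless_exponential(self, mu):
        t = np.linspace(0, np.log(25) / mu, 40)
        curve = GrowthCurve(t, 0.02 * np.exp(mu * t))
        fit = fit_exponential(curve)
        assert fit.mu == pytest.approx(mu, abs=1e-12)
        assert fit.n0 == pytest.approx(0.02, rel=1e-9)
        assert fit.mu_sd == pytest.approx(0.0, abs=1e-9)

    def test_exact_regardless_of_window_bounds(self):
        """On a pure exponential the window choice cannot change the fit."""
        mu = 0.25
        t = np.linspace(0, 12, 30)
        curve = GrowthCurve(t, 0.02 * np.exp(mu * t))
        for od_min, od_max in [(0.04, 0.5), (0.05, 0.3), (0.1, 0.4)]:
            fit = fit_exponential(curve, od_min=od_min, od_max=od_max)
            assert fit.mu == pytest.approx(mu, abs=1e-12)

    def test_recovery_on_noisy_synthetic_curves(self):
        """Each seeded fit recovers the generating rate within 2 SE; the
        ensemble mean is within one ensemble SD."""
        mu_true = 0.036
        mus = []
        for seed in range(20):
            curve = gen_growth_curve(
                GrowthScenario(mu=mu_true, noise_cv=0.03, seed=seed)
            )
            fit = fit_exponential(curve)
            assert abs(fit.mu - mu_true) <= 2 * fit.mu_sd
            mus.append(fit.mu)
        mus = np.asarray(mus)
        assert abs(mus.mean() - mu_true) <= max(mus.std(ddof=1), 1e-12)

    def test_decreasing_od_is_a_fit_failure(self):
        t = np.linspace(0, 10, 12)
        curve = GrowthCurve(t, 0.4 * np.exp(-0.2 * t))
        with pytest.raises(FitError):
            fit_exponential(curve)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match=">= 6"):
            fit_exponential(GrowthCurve([0, 1, 2], [0.1, 0.2, 0.4]))

    def test_od_outside_operating_range_is_a_fit_failure(self):
        t = np.linspace(0, 5, 10)
        curve = GrowthCurve(t, np.full(10, 0.001))
        with pytest.raises(FitError, match="fit range"):
            fit_exponential(curve)

    def test_curve_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            GrowthCurve([0, 2, 1], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="positive"):
            GrowthCurve([0, 1, 2], [0.1, -0.2, 0.3])

    def test_pool_fits(self):
        curves = [
            gen_growth_curve(GrowthScenario(mu=0.036, noise_cv=0.03, seed=s))
            for s in range(3)
        ]
        pooled = pool_fits([fit_exponential(c) for c in curves])
        assert pooled.n == 3
        assert pooled.mean == pytest.approx(0.036, rel=0.05)


class TestDoublingTime:
    def test_printed_value(self):
        # 0.0012 h^-1 corresponds to the ~580 h (24 day) doubling time
        assert doubling_time(0.0012) == pytest.approx(577.62, rel=1e-3)
        assert doubling_time(0.0012) == pytest.approx(580, rel=0.02)

    def test_ln2_gives_one_hour(self):
        assert doubling_time(np.log(2)) == pytest.approx(1.0, rel=1e-12)

    def test_quarter_rate(self):
        assert doubling_time(0.25) == pytest.approx(np.log(2) / 0.25, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            doubling_time(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_identity_mu_times_doubling_is_ln2(self, mu):
        assert doubling_time(mu) * mu == pytest.approx(np.log(2), rel=1e-12)


class TestCompareGroups:
    def test_pantothenate_groups_not_significant(self):
        p = compare_groups((0.037, 0.007, 9), (0.035, 0.005, 9))
        assert p > 0.4

    def test_methionine_groups_highly_significant(self):
        p = compare_groups((0.047, 0.004, 18), (0.036, 0.006, 18))
        assert p < 1e-5

    def test_identical_groups_p_one(self):
        assert compare_groups((0.04, 0.0, 5), (0.04, 0.0, 5)) == 1.0
        assert compare_groups((0.04, 0.005, 5), (0.04, 0.005, 5)) == pytest.approx(1.0)

    def test_symmetric_and_scale_invariant(self):
        a, b = (0.047, 0.004, 18), (0.036, 0.006, 18)
        assert compare_groups(a, b) == pytest.approx(compare_groups(b, a))
        a10 = (0.47, 0.04, 18)
        b10 = (0.36, 0.06, 18)
        assert compare_groups(a, b) == pytest.approx(compare_groups(a10, b10))

    def test_student_variant_available(self):
        p_welch = compare_groups((0.037, 0.007, 9), (0.035, 0.005, 9))
        p_student = compare_groups(
            (0.037, 0.007, 9), (0.035, 0.005, 9), equal_var=True
        )
        assert p_student > 0.4 and p_welch != p_student

    def test_tiny_groups_rejected(self):
        with pytest.raises(DomainError):
            compare_groups((0.04, 0.0, 1), (0.05, 0.01, 5))


class TestNash:
    def test_exact_line_recovered_and_inverted(self):
        standards = [(c, 1.2 * c + 0.05) for c in np.linspace(0, 1, 6)]
        cal = calibrate_nash(standards)
        assert cal.slope == pytest.approx(1.2, rel=1e-9)
        assert cal.intercept == pytest.approx(0.05, abs=1e-9)
        inv = invert_nash(cal, 0.65)
        assert inv.mM == pytest.approx(0.5, rel=1e-9)
        assert inv.in_range

    def test_calibrate_invert_identity_on_collinear_standards(self):
        standards = [(c, 0.9 * c + 0.02) for c in np.linspace(0, 1, 5)]
        cal = calibrate_nash(standards)
        for c, a in standards:
            assert invert_nash(cal, a).mM == pytest.approx(c, abs=1e-9)

    def test_out_of_range_flagged_but_returned(self):
        cal = calibrate_nash([(c, 1.2 * c + 0.05) for c in np.linspace(0, 1, 5)])
        inv = invert_nash(cal, 1.2 * 1.5 + 0.05)  # 1.5 mM-equivalent
        assert inv.mM == pytest.approx(1.5, rel=1e-9)
        assert not inv.in_range

    def test_non_monotone_standards_rejected(self):
        with pytest.raises(CalibrationError, match="monotone"):
            calibrate_nash([(0.0, 0.1), (0.5, 0.8), (1.0, 0.4)])

    def test_too_few_standards_rejected(self):
        with pytest.raises(CalibrationError, match=">= 3"):
            calibrate_nash([(0.0, 0.1), (1.0, 1.2)])
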