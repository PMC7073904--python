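"""FBA and phase-plane properties: the analytic slope oracle, envelope
invariances, mass-balance residuals, and the flux/growth derivations."""

import numpy as np
import pytest

from c1flux.errors import DomainError, InfeasibleError
from c1flux.growth import GrowthMeasurement
from c1flux.medium import build_medium
from c1flux.phase_plane import (
    FluxEstimate,
    derive_flux,
    derive_max_growth,
    fba,
    phase_plane,
)


class TestFBA:
    def test_toy_all_nutrients_grows(self, toy_factory):
        model, ans = toy_factory(b=0.7)
        sol = fba(model, build_medium(model, "thy"))
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(ans.max_mu, rel=1e-6)

    def test_toy_no_formaldehyde_no_growth(self, toy_factory):
        model, _ = toy_factory(b=0.7)
        medium = build_medium(model, "thy")
        medium.uptake.pop("EX_fald_e")
        assert fba(model, medium).objective_value == pytest.approx(0, abs=1e-9)

    def test_steady_state_residual_below_tolerance(self, toy_factory, base_curated):
        """max|S.v| <= 1e-9, checked against our own S matrix."""
        model, _ = toy_factory(b=0.7, n_filler=5)
        assert fba(model, build_medium(model, "thy")).residual <= 1e-9
        sol = fba(base_curated, build_medium(base_curated, "thy"))
        assert sol.residual <= 1e-9


class TestPhasePlaneOracle:
    @pytest.mark.parametrize("b", [0.1, 0.54, 0.7, 5, 20])
    def test_slope_equals_biomass_mlthf_coefficient(self, toy_factory, b):
        """The lower envelope's slope is the biomass C1 coefficient exactly."""
        model, ans = toy_factory(b=b)
        pp = phase_plane(model, build_medium(model, "thy"), "THFSPONT")
        assert pp.slope == pytest.approx(ans.slope, rel=1e-6)
        assert pp.intercept == pytest.approx(0, abs=1e-9)
        assert not pp.intercept_flagged

    def test_decoys_do_not_affect_envelope(self, toy_factory):
        slopes = []
        for seed in (0, 7):
            model, _ = toy_factory(b=0.7, n_filler=6, seed=seed)
            pp = phase_plane(model, build_medium(model, "thy"), "THFSPONT")
            slopes.append(pp.slope)
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-9)

    def test_envelope_min_below_max_and_monotone(self, toy_factory):
        model, _ = toy_factory(b=0.7)
        pp = phase_plane(model, build_medium(model, "thy"), "THFSPONT")
        feas = pp.feasible
        assert np.all(pp.min_flux[feas] <= pp.max_flux[feas] + 1e-9)
        assert np.all(np.diff(pp.min_flux[feas]) >= -1e-9)


class TestPhasePlaneCore:
    def test_methionine_never_increases_slope(self, base_curated):
        pp_thy = phase_plane(base_curated, build_medium(base_curated, "thy"), "THFSPONT")
        pp_met = phase_plane(
            base_curated, build_medium(base_curated, "thy_met"), "THFSPONT"
        )
        assert pp_met.slope <= pp_thy.slope + 1e-9
        assert pp_met.slope < pp_thy.slope  # strictly less: met is a C1 sink

    def test_pantothenate_barely_changes_the_phase_plane(self, base_curated):
        pp_thy = phase_plane(base_curated, build_medium(base_curated, "thy"), "THFSPONT")
        pp_pan = phase_plane(
            base_curated, build_medium(base_curated, "thy_pan"), "THFSPONT"
        )
        assert pp_pan.slope == pytest.approx(pp_thy.slope, rel=0.01)

    def test_slope_invariant_to_carbon_supply(self, base_curated):
        """Doubling the glucose bound moves the feasible range, not the
        stoichiometric slope."""
        slopes = []
        for gu in (10.0, 20.0):
            med = build_medium(base_curated, "thy", glucose_uptake=gu)
            slopes.append(phase_plane(base_curated, med, "THFSPONT").slope)
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-9)

    def test_serine_cycle_slope_much_steeper(self, base_curated, serine_model):
        pp_thy = phase_plane(base_curated, build_medium(base_curated, "thy"), "THFSPONT")
        pp_ser = phase_plane(
            serine_model, build_medium(serine_model, "formaldehyde_only"), "THFSPONT"
        )
        assert pp_ser.slope > 20
        assert pp_ser.slope > 10 * pp_thy.slope
        assert not pp_ser.intercept_flagged


class TestPhasePlaneErrors:
    def test_unknown_reaction(self, toy_factory):
        model, _ = toy_factory()
        with pytest.raises(KeyError, match="NOPE"):
            phase_plane(model, build_medium(model, "thy"), "NOPE")

    def test_bad_grid_rejected(self, toy_factory):
        model, _ = toy_factory()
        med = build_medium(model, "thy")
        with pytest.raises(DomainError, match="grid"):
            phase_plane(model, med, "THFSPONT", growth_grid=[0.1, 0.05, 0.2])
        with pytest.raises(DomainError, match="grid"):
            phase_plane(model, med, "THFSPONT", growth_grid=[0.1, 0.2])

    def test_entirely_infeasible_grid_advises_shrink(self, toy_factory):
        model, ans = toy_factory(b=0.7)
        med = build_medium(model, "thy")
        grid = np.array([1.1, 1.2, 1.3]) * ans.max_mu
        with pytest.raises(InfeasibleError, match="shrink"):
            phase_plane(model, med, "THFSPONT", growth_grid=grid)


class TestDerivations:
    @pytest.fixture
    def pp07(self, toy_factory):
        model, _ = toy_factory(b=0.7)
        return phase_plane(model, build_medium(model, "thy"), "THFSPONT")

    def test_flux_from_measured_growth(self, pp07):
        fe = derive_flux(pp07, GrowthMeasurement(0.036, 0.006, 18))
        assert fe.flux == pytest.approx(0.7 * 0.036, rel=1e-6)
        assert fe.sd == pytest.approx(0.7 * 0.006, rel=1e-6)

    def test_zero_growth_returns_intercept(self, pp07):
        fe = derive_flux(pp07, GrowthMeasurement(0.0, 0.0, 1))
        assert fe.flux == pytest.approx(pp07.intercept, abs=1e-9)

    def test_growth_outside_feasible_range_rejected(self, pp07):
        with pytest.raises(DomainError, match="outside"):
            derive_flux(pp07, GrowthMeasurement(1e4, 0.01, 3))

    def test_max_growth_arithmetic(self, toy_factory):
        model, _ = toy_factory(b=20.0)
        pp = phase_plane(model, build_medium(model, "formaldehyde_only"), "THFSPONT")
        g = derive_max_growth(pp, FluxEstimate(0.025, 0.0))
        assert g.mean == pytest.approx(0.00125, rel=1e-6)

    def test_round_trip_flux_growth_identity(self, pp07):
        g_in = GrowthMeasurement(0.036, 0.006, 18)
        fe = derive_flux(pp07, g_in)
        g_out = derive_max_growth(pp07, fe)
        assert g_out.mean == pytest.approx(g_in.mean, rel=1e-9)
        assert g_out.sd == pytest.approx(g_in.sd, rel=1e-9)

    def test_nonpositive_slope_rejected(self, pp07):
        pp07.slope = 0.0
        with pytest.raises(DomainError, match="slope"):
            derive_max_growth(pp07, FluxEstimate(0.025, 0.004))

    @pytest.mark.parametrize("sd", [0.0, 0.002, 0.006, 0.05])
    def test_error_propagation_is_exactly_linear(self, pp07, sd):
        fe = derive_flux(pp07, GrowthMeasurement(0.036, sd, 18))
        assert fe.sd == pytest.approx(pp07.slope * sd, rel=1e-12, abs=1e-15)
        if sd > 0:
            g = derive_max_growth(pp07, fe)
            assert g.sd == pytest.approx(fe.sd / pp07.slope, rel=1e-12)
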