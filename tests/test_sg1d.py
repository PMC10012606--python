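import math

import numpy as np
import pytest

from csfsg import (
    FUSolution,
    InvalidParameterError,
    MicrovilliGeometry,
    NumericsConfig,
    SolverError,
    TransportParameters,
    build_flux_profile,
    production_rate,
    small_peclet_estimate,
    solve_fu,
    solve_legacy_db,
)
from csfsg.presets import FIXED_CASES, case_to_model_inputs, mean_parameter_values

from fd_oracle import solve_fd


# ----------------------------------------------------------------- flux ----


class TestFluxProfile:
    def test_baseline_flux_central_fixture(self, central_case):
        geom, params = central_case
        flux = build_flux_profile(geom, params)
        assert flux.phi0 == pytest.approx(7.281e-7, rel=1e-3)
        assert flux.boost_factor == 0.5
        assert flux.boost_extent == pytest.approx(geom.d_cm / 2.0, rel=1e-14)

    @pytest.mark.parametrize("name", sorted(FIXED_CASES))
    def test_lateral_integral_identity(self, name):
        """φ0 (π d l + π d²/4) N recovers ρ Q_meas C0 at machine precision."""
        geom, params = case_to_model_inputs(FIXED_CASES[name])
        flux = build_flux_profile(geom, params)
        d, l = geom.d_cm, geom.l_mv_cm
        lateral = flux.phi0 * (math.pi * d * l + math.pi * d * d / 4.0) * geom.N
        assert lateral == pytest.approx(
            params.rho * params.Q_meas_cm3s * params.C0, rel=1e-13
        )

    def test_boosted_region_carries_the_base_share(self, central_case):
        geom, params = central_case
        flux = build_flux_profile(geom, params)
        a = flux.boost_extent
        assert flux(a / 2.0) == pytest.approx(1.5 * flux.phi0)
        assert flux(2.0 * a) == pytest.approx(flux.phi0)

    def test_zero_measured_production_means_zero_flux(self, central_case):
        geom, params = central_case
        params = TransportParameters(
            D=params.D, C0=params.C0, rho=params.rho, Lp=params.Lp,
            l_prot=params.l_prot, Q_meas=0.0,
        )
        flux = build_flux_profile(geom, params)
        assert flux.phi0 == 0.0
        assert flux(geom.l_mv_cm / 2.0) == 0.0

    def test_stubby_unit_clamps_boost_and_keeps_identity(self):
        # a channel shorter than half its diameter: boost spans everything
        geom = MicrovilliGeometry(r_mv=0.09, l_mv=0.01, sigma=12.5, A_app=3.66)
        params = TransportParameters(
            D=1.15e-5, C0=0.307, rho=1.0, Lp=1.44e-5, l_prot=0.0, Q_meas=6.8
        )
        flux = build_flux_profile(geom, params)
        assert flux.clamped
        assert flux.boost_extent == pytest.approx(geom.l_mv_cm)
        d, l, a = geom.d_cm, geom.l_mv_cm, flux.boost_extent
        lateral = flux.phi0 * math.pi * d * (l + a / 2.0) * geom.N
        assert lateral == pytest.approx(
            params.rho * params.Q_meas_cm3s * params.C0, rel=1e-13
        )


# ------------------------------------------------------------- BVP solve ----


class TestSolveFU:
    def test_conservation_and_boundary_structure(self, fixed_case):
        """Mass closure, water balance and the imposed boundary behaviour."""
        name, (geom, params) = fixed_case
        sol = solve_fu(geom, params)
        assert sol.converged
        assert sol.solute_residual < 1e-4
        assert sol.water_residual < 1e-6
        assert abs(sol.u[0]) < 1e-12 * abs(sol.u[-1])
        # impermeable base: concentration peaks there with zero slope
        assert np.argmax(sol.C) == 0
        h = 1e-6 * geom.l_mv_cm
        C_near = sol.dense(np.array([0.0, h]))[0]
        dC0 = (C_near[1] - C_near[0]) / h
        assert abs(dC0) * geom.l_mv_cm < 1e-4 * (sol.C[0] - params.C0)
        assert np.all(sol.C >= params.C0 - 1e-12)
        assert np.all(np.diff(sol.u) >= -1e-18)
        # zero protected length pins the tip to bulk osmolality
        assert sol.C[-1] == pytest.approx(params.C0, rel=1e-10)

    def test_matches_small_peclet_estimate_without_protected_pool(
        self, fixed_case
    ):
        name, (geom, params) = fixed_case
        est = small_peclet_estimate(geom, params)
        sol = solve_fu(geom, params)
        assert sol.Q_SG == pytest.approx(est, rel=0.05)

    def test_estimate_is_modest_upper_bound_with_protected_pool(self, mean_case):
        """With l_prot = 77.5 µm the dilution term C·du/dz, dropped by the
        linearization, trims production by ~10%, so the closed form is an
        upper bound rather than a 1%-accurate surrogate."""
        geom, params = mean_case
        est = small_peclet_estimate(geom, params)
        sol = solve_fu(geom, params)
        assert sol.converged and sol.tip_peclet < 0.01
        assert 1.0 < est / sol.Q_SG < 1.15

    def test_independent_fd_oracle_agrees_on_physiological_case(self, mean_case):
        geom, params = mean_case
        flux = build_flux_profile(geom, params)
        sol = solve_fu(geom, params, flux)
        z, C, u, _ = solve_fd(
            geom.l_mv_cm, geom.d_cm, params.D, params.C0, params.rho,
            params.Lp, params.l_prot_cm, lambda zz: np.asarray(flux(zz), float),
            n=8001, relax=0.5, tol=1e-10,
        )
        assert u[-1] == pytest.approx(float(sol.u[-1]), rel=1e-3)
        assert C[0] == pytest.approx(float(sol.C[0]), rel=1e-4)

    def test_zero_permeability_gives_pure_diffusion(self, central_case):
        geom, params = central_case
        params = TransportParameters(
            D=params.D, C0=params.C0, rho=params.rho, Lp=0.0,
            l_prot=params.l_prot, Q_meas=params.Q_meas,
        )
        flux = build_flux_profile(geom, params)
        sol = solve_fu(geom, params, flux)
        assert sol.converged
        assert np.all(sol.u == 0.0)
        assert sol.Q_SG == 0.0
        # diffusion-only base elevation: C(0)-C0 = (4 φ0 l²/(ρ d D)) (G(1)+λF(1))
        l, d = geom.l_mv_cm, geom.d_cm
        ahat = flux.boost_extent / l
        Cs = 4.0 * flux.phi0 * l * l / (params.rho * d * params.D)
        G1 = 0.5 + ahat / 2.0 - ahat**2 / 4.0  # ∫0^1 F for the boosted shape
        lam = params.l_prot_cm / l
        expected = Cs * (G1 + lam * (1.0 + ahat / 2.0))
        assert sol.C[0] - params.C0 == pytest.approx(expected, rel=1e-3)

    def test_zero_flux_rests_isotonic(self, central_case):
        geom, params = central_case
        params = TransportParameters(
            D=params.D, C0=params.C0, rho=params.rho, Lp=params.Lp,
            l_prot=params.l_prot, Q_meas=0.0,
        )
        sol = solve_fu(geom, params)
        assert np.all(sol.C == params.C0)
        assert np.all(sol.u == 0.0)
        assert sol.Q_SG == 0.0

    @pytest.mark.parametrize(
        "name, factors",
        [
            ("Lp", (0.5, 1.0, 2.0, 4.0)),
            ("l_prot", (0.0, 0.5, 1.0, 1.5)),
            ("Q_meas", (0.25, 0.5, 1.0, 2.0)),
            ("l_mv", (0.5, 1.0, 1.5, 2.0)),
        ],
    )
    def test_production_monotone_in_drivers(self, name, factors):
        """More permeability, deeper pools, more pumping or longer channels
        all increase standing-gradient production."""
        base = mean_parameter_values()
        ref = base[name] if base[name] > 0 else 77.5
        q = []
        for fac in factors:
            values = dict(base)
            values[name] = ref * fac
            geom, params = case_to_model_inputs(values)
            q.append(solve_fu(geom, params).Q_SG)
        assert np.all(np.diff(q) > 0)

    def test_mesh_independence(self, mean_case):
        geom, params = mean_case
        q1 = solve_fu(geom, params, numerics=NumericsConfig(mesh_size=48)).Q_SG
        q2 = solve_fu(geom, params, numerics=NumericsConfig(mesh_size=96)).Q_SG
        assert q2 == pytest.approx(q1, rel=1e-3)

    def test_full_model_protected_length_response(self):
        """The full solver bends slightly below the linearized response:
        monotone, concave, and within a few percent of a straight line."""
        base = mean_parameter_values()
        grid = np.array([0.0, 31.0, 62.0, 93.0, 124.0, 155.0])
        q = []
        for lp in grid:
            values = dict(base, l_prot=lp)
            geom, params = case_to_model_inputs(values)
            q.append(solve_fu(geom, params).Q_SG)
        q = np.array(q)
        assert np.all(np.diff(q) > 0)
        coef = np.polyfit(grid, q, 1)
        r2 = 1.0 - np.sum((q - np.polyval(coef, grid)) ** 2) / np.sum(
            (q - q.mean()) ** 2
        )
        assert r2 > 0.99


class TestSmallPecletEstimate:
    def test_linear_in_permeability(self, central_case):
        geom, params = central_case
        doubled = TransportParameters(
            D=params.D, C0=params.C0, rho=params.rho, Lp=2.0 * params.Lp,
            l_prot=params.l_prot, Q_meas=params.Q_meas,
        )
        assert small_peclet_estimate(geom, doubled) == pytest.approx(
            2.0 * small_peclet_estimate(geom, params), rel=1e-13
        )

    def test_exactly_linear_in_protected_length(self, central_case):
        geom, params = central_case
        flux = build_flux_profile(geom, params)
        l, d = geom.l_mv_cm, geom.d_cm
        ahat = flux.boost_extent / l
        delta_um = 10.0
        slope = (
            16.0 * params.Lp * flux.phi0 / (params.rho * d * d * params.D)
            * l * l * (1.0 + ahat / 2.0)
        ) * geom.N * geom.A_CS_cm2 * 6.0e4  # per cm of protected length
        q0 = small_peclet_estimate(geom, params)
        params2 = TransportParameters(
            D=params.D, C0=params.C0, rho=params.rho, Lp=params.Lp,
            l_prot=params.l_prot + delta_um, Q_meas=params.Q_meas,
        )
        q1 = small_peclet_estimate(geom, params2)
        assert q1 - q0 == pytest.approx(slope * delta_um * 1e-4, rel=1e-12)

    def test_warns_outside_small_peclet_regime(self, central_case):
        geom, params = central_case
        hot = TransportParameters(
            D=params.D, C0=params.C0, rho=params.rho, Lp=200 * params.Lp,
            l_prot=2000.0, Q_meas=params.Q_meas,
        )
        with pytest.warns(UserWarning, match="Péclet"):
            small_peclet_estimate(geom, hot)


class TestProductionRate:
    def test_matches_tip_velocity_arithmetic(self):
        geom = MicrovilliGeometry(r_mv=0.104, l_mv=1.875, sigma=15.3, A_app=3.85)
        z = np.linspace(0.0, geom.l_mv_cm, 5)
        sol = FUSolution(
            z=z, C=np.full(5, 0.3129), u=np.linspace(0.0, 1e-6, 5),
            Q_FU=0.0, Q_SG=0.0, solute_residual=0.0, water_residual=0.0,
            tip_peclet=0.0, status="converged",
        )
        assert production_rate(sol, geom) == pytest.approx(0.0614, rel=1e-2)

    def test_zero_velocity_zero_production(self):
        geom = MicrovilliGeometry(r_mv=0.09, l_mv=2.0, sigma=12.5, A_app=3.66)
        z = np.linspace(0.0, geom.l_mv_cm, 5)
        sol = FUSolution(
            z=z, C=np.full(5, 0.307), u=np.zeros(5),
            Q_FU=0.0, Q_SG=0.0, solute_residual=0.0, water_residual=0.0,
            tip_peclet=0.0, status="converged",
        )
        assert production_rate(sol, geom) == 0.0

    def test_refuses_unconverged_solution(self):
        geom = MicrovilliGeometry(r_mv=0.09, l_mv=2.0, sigma=12.5, A_app=3.66)
        z = np.linspace(0.0, geom.l_mv_cm, 5)
        sol = FUSolution(
            z=z, C=np.full(5, 0.307), u=np.zeros(5),
            Q_FU=0.0, Q_SG=0.0, solute_residual=np.nan, water_residual=np.nan,
            tip_peclet=0.0, status="failed",
        )
        with pytest.raises(SolverError):
            production_rate(sol, geom)


# ------------------------------------------------------------ legacy case ----


class TestLegacyChannel:
    def test_profile_shapes(self):
        """Classic standing-gradient shape: hypertonic closed end, osmolality
        relaxing to bulk at the open tip, velocity growing monotonically."""
        sol = solve_legacy_db()
        assert sol.converged
        assert sol.C[0] > sol.C[-1]
        assert sol.C[-1] == pytest.approx(0.3, rel=1e-10)
        assert np.all(np.diff(sol.C) <= 1e-15)
        assert abs(sol.u[0]) < 1e-12 * abs(sol.u[-1])
        assert np.all(np.diff(sol.u) >= -1e-18)
        assert sol.solute_residual < 1e-4
        assert sol.water_residual < 1e-6

    def test_agrees_with_brute_force_grid_oracle(self):
        sol = solve_legacy_db()
        z, C, u, _ = solve_fd(
            l=0.01, d=1e-5, D=1e-5, C0=0.3, rho=1.0, Lp=2e-4, l_prot=0.0,
            phi_fn=lambda zz: np.where(zz <= 0.1 * 0.01, 1e-5, 0.0),
            n=10001, relax=0.3, tol=1e-10,
        )
        assert float(sol.u[-1]) == pytest.approx(u[-1], rel=5e-3)
        assert float(sol.C[0]) == pytest.approx(C[0], rel=5e-3)

    def test_zero_flux_is_isotonic_rest(self):
        sol = solve_legacy_db({"phi": 0.0})
        assert np.all(sol.C == 0.3)
        assert np.all(sol.u == 0.0)


# --------------------------------------------------------------- numerics ----


class TestNumericsConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(InvalidParameterError):
            NumericsConfig(tol=0.0)
        with pytest.raises(InvalidParameterError):
            NumericsConfig(mesh_size=8)

    def test_explicit_flux_equals_implicit(self, central_case):
        geom, params = central_case
        flux = build_flux_profile(geom, params)
        assert solve_fu(geom, params, flux).Q_SG == pytest.approx(
            solve_fu(geom, params).Q_SG, rel=1e-12
        )
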