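"""Unit and property tests for the analytic steady-state cluster model."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import clusterflux as cf
from clusterflux.cluster_model import (
    RegionPiece,
    ValidationError,
    enzyme_density,
)

from conftest import random_parameterization


class TestPartition:
    def test_no_cluster_at_gamma_zero(self):
        p = cf.partition_enzymes(100, 0.0)
        assert p.n1 == 0.0 and p.n2 == 100.0

    @pytest.mark.parametrize("N,gamma,n1,n2", [(100, 3, 75, 25), (100, 10, None, None)])
    def test_excess_ratio_arithmetic(self, N, gamma, n1, n2):
        p = cf.partition_enzymes(N, gamma)
        assert p.n1 + p.n2 == pytest.approx(N, rel=1e-12)
        if n1 is not None:
            assert (p.n1, p.n2) == (pytest.approx(n1), pytest.approx(n2))
        assert p.n1 / p.n2 == pytest.approx(gamma, rel=1e-12)

    def test_conservation_over_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = rng.uniform(0, 1e6)
            g = rng.uniform(0, 1e4)
            p = cf.partition_enzymes(N, g)
            assert p.n1 + p.n2 == pytest.approx(N, rel=1e-12)

    @pytest.mark.parametrize("bad", [{"N_total": -1}, {"gamma": -0.5}, {"gamma": math.inf}])
    def test_invalid_inputs_name_field(self, bad):
        kwargs = {"N_total": 10, "gamma": 1.0, **bad}
        with pytest.raises(ValidationError) as err:
            cf.partition_enzymes(**kwargs)
        (field,) = bad
        assert field in str(err.value)


class TestEffectiveActivities:
    def test_collapse_at_gamma_zero(self, small_geometry):
        p = cf.partition_enzymes(1000, 0.0)
        a_drop, a_cluster = cf.effective_activities(p, small_geometry, k=1e-3)
        assert a_cluster == pytest.approx(a_drop)

    def test_ratio_from_direct_arithmetic(self):
        # independent evaluation: 1 + gamma * (R2/R1)^3 at gamma=100, R2/R1=20
        geom = cf.BasinGeometry(R1=0.1, R2=2.0, R0=4.0)
        p = cf.partition_enzymes(500, 100.0)
        a_drop, a_cluster = cf.effective_activities(p, geom, k=2e-3)
        assert a_cluster / a_drop == pytest.approx(1 + 100 * 20**3, rel=1e-9)

    def test_all_in_cluster_limit(self, small_geometry):
        k, N = 1e-3, 1000
        p = cf.partition_enzymes(N, 1e12)
        _, a_cluster = cf.effective_activities(p, small_geometry, k)
        assert a_cluster == pytest.approx(k * N / small_geometry.v_cluster, rel=1e-9)


class TestEnzymeDensity:
    def test_density_values_and_integral(self):
        geom = cf.BasinGeometry(R1=0.1, R2=2.0, R0=4.0)
        p = cf.partition_enzymes(1000, 9.0)
        d = enzyme_density(p, geom)
        assert d.rho_cluster == pytest.approx(
            100 / geom.v_drop + 900 / geom.v_cluster, rel=1e-12
        )
        assert d.rho_bulk == 0.0
        integral = (
            d.rho_cluster * geom.v_cluster
            + d.rho_droplet * (geom.v_drop - geom.v_cluster)
        )
        assert integral == pytest.approx(1000, rel=1e-9)

    def test_uniform_at_gamma_zero(self, small_geometry):
        d = enzyme_density(cf.partition_enzymes(500, 0.0), small_geometry)
        assert d.rho_cluster == d.rho_droplet
        assert d(small_geometry.R0) == 0.0


class TestSteadyState:
    def test_no_enzyme_gives_homeostatic_fields(self, small_geometry):
        params = cf.KineticParams(k=1e-3, D=50, alpha0=1, beta=0.5, c0_star=80, N_total=0)
        sol = cf.solve_steady_state(small_geometry, params, gamma=5.0)
        r = np.linspace(0, small_geometry.R0, 33)
        c0, c1 = cf.evaluate_profile(sol, r)
        np.testing.assert_allclose(c0, 80.0, rtol=1e-9)
        np.testing.assert_allclose(c1, 0.0, atol=1e-12)

    def test_continuity_of_value_and_flux(self, small_geometry, small_params):
        sol = cf.solve_steady_state(small_geometry, small_params, gamma=10.0)
        for fld in (sol.substrate, sol.product):
            for edge, (i, j) in (
                (small_geometry.R1, (0, 1)),
                (small_geometry.R2, (1, 2)),
            ):
                vi = float(fld.pieces[i].value(edge))
                vj = float(fld.pieces[j].value(edge))
                assert vi == pytest.approx(vj, rel=1e-8)
                di = float(fld.pieces[i].deriv(edge))
                dj = float(fld.pieces[j].deriv(edge))
                assert di == pytest.approx(dj, rel=1e-8, abs=1e-10 * abs(vi))

    def test_governing_equation_residual_at_probe_radii(
        self, small_geometry, small_params
    ):
        """Both ODEs hold pointwise in every region (checked by differencing)."""
        sol = cf.solve_steady_state(small_geometry, small_params, gamma=10.0)
        p = small_params
        rho = enzyme_density(sol.partition, small_geometry).per_region
        bp = small_geometry.breakpoints
        for i in range(3):
            r = np.linspace(bp[i], bp[i + 1], 52)[1:-1]
            h = (bp[i + 1] - bp[i]) * 1.5e-3
            for fld, resid_fn in (
                (
                    sol.substrate,
                    lambda c, lap, rr: p.D * lap
                    - p.k * rho[i] * c
                    - p.alpha0 * (c - p.c0_star),
                ),
                (
                    sol.product,
                    lambda c, lap, rr: p.D * lap
                    + p.k * rho[i] * sol.substrate(rr)
                    - p.beta * c,
                ),
            ):
                piece = fld.pieces[i]
                c = piece.value(r)
                # spherical Laplacian via central differences of u = r*c
                u = lambda x: x * piece.value(x)
                lap = (u(r + h) - 2 * u(r) + u(r - h)) / (h * h) / r
                resid = resid_fn(c, lap, r)
                scale = max(np.max(np.abs(p.beta * c)), np.max(np.abs(p.alpha0 * c)), 1e-12)
                assert np.max(np.abs(resid)) / scale < 1e-4  # FD-limited accuracy

    def test_fields_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            geom, params, gamma = random_parameterization(rng)
            sol = cf.solve_steady_state(geom, params, gamma)
            r = np.linspace(0, geom.R0, 200)
            c0, c1 = cf.evaluate_profile(sol, r)
            assert np.all(c0 >= -1e-9 * params.c0_star)
            assert np.all(c1 >= -1e-9 * max(c1.max(), 1.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_flux_balances(self, seed):
        """alpha0*int(c0*-c0) = int k n c0 = beta*int c1 under zero flux."""
        geom, params, gamma = random_parameterization(np.random.default_rng(seed))
        sol = cf.solve_steady_state(geom, params, gamma)
        assert cf.product_balance_residual(sol) < 1e-6
        assert cf.substrate_balance_residual(sol) < 1e-6

    def test_well_mixed_limit_recovers_closed_form(self):
        # depletion number k*N/(v_drop*alpha0) ~ 4e-4, large D: uniform fields
        geom = cf.BasinGeometry(R1=0.3, R2=1.0, R0=1.001)
        params = cf.KineticParams(
            k=1.66e-3, D=1e4, alpha0=100.0, beta=1.0, c0_star=50.0, N_total=100
        )
        assert params.k * params.N_total / (geom.v_drop * params.alpha0) < 1e-3
        sol = cf.solve_steady_state(geom, params, gamma=2.0)
        c1_mean = sol.product.region_mean(0, geom.R0) * geom.v_basin / geom.v_drop
        expected = params.k * params.N_total * params.c0_star / (params.beta * geom.v_drop)
        assert c1_mean == pytest.approx(expected, rel=0.01)

    def test_beta_zero_with_zero_flux_has_no_steady_state(self, small_geometry):
        params = cf.KineticParams(k=1e-3, D=50, alpha0=1, beta=0.0, c0_star=80, N_total=100)
        with pytest.raises(ValidationError, match="beta"):
            cf.solve_steady_state(small_geometry, params, gamma=1.0)

    def test_resonance_perturbation_warns(self):
        # pick alpha0 so that the bulk substrate rate equals beta exactly
        geom = cf.BasinGeometry(R1=0.5, R2=2.0, R0=4.0)
        params = cf.KineticParams(
            k=1e-3, D=50.0, alpha0=0.5, beta=0.5, c0_star=100.0, N_total=1e4
        )
        # resonance occurs in the droplet region where kappa0^2 = (k*n+a0)/D
        # equals beta/D only if k*n = 0; force it in the bulk-free droplet by
        # using gamma -> all enzymes clustered leaves droplet density ~ 0
        with pytest.warns(RuntimeWarning, match="resonant"):
            sol = cf.solve_steady_state(geom, params, gamma=1e14)
        assert cf.product_balance_residual(sol) < 1e-5

    def test_excess_substrate_mode_clamps_substrate(self, small_geometry, small_params):
        sol = cf.solve_steady_state(
            small_geometry, small_params, gamma=10.0, substrate_mode="excess"
        )
        r = np.linspace(0, small_geometry.R0, 50)
        c0, c1 = cf.evaluate_profile(sol, r)
        np.testing.assert_allclose(c0, small_params.c0_star, rtol=1e-12)
        # product balance still holds with the clamped source
        decay = small_params.beta * sol.product.shell_integral(0, small_geometry.R0)
        prod = cf.total_production_rate(sol)
        assert decay == pytest.approx(prod, rel=1e-6)

    def test_clamped_outer_boundary_pins_values(self, small_geometry, small_params):
        sol = cf.solve_steady_state(
            small_geometry, small_params, gamma=5.0, boundary="clamped"
        )
        assert float(sol.substrate(small_geometry.R0)) == pytest.approx(
            small_params.c0_star, rel=1e-8
        )
        assert abs(float(sol.product(small_geometry.R0))) < 1e-10


class TestProfileAndAverages:
    def test_profile_outside_basin_rejected(self, small_geometry, small_params):
        sol = cf.solve_steady_state(small_geometry, small_params, gamma=1.0)
        with pytest.raises(ValidationError):
            cf.evaluate_profile(sol, [small_geometry.R0 * 1.5])

    def test_product_profile_decreases_from_center(self):
        # excess-substrate mode keeps production maximal in the innermost
        # region (no central depletion), the precondition for monotonicity
        geom, kin = cf.preset("in_vivo")
        sol = cf.solve_steady_state(geom, kin, gamma=100.0, substrate_mode="excess")
        r = np.linspace(0, geom.R0, 300)
        _, c1 = cf.evaluate_profile(sol, r)
        assert np.argmax(c1) == 0
        assert np.all(np.diff(c1) <= 1e-9 * c1[0])

    def test_agreement_with_finite_difference_oracle(self, small_geometry, small_params):
        sol = cf.solve_steady_state(small_geometry, small_params, gamma=10.0)
        fd = cf.solve_fd_steady(small_geometry, small_params, 10.0)
        c0, c1 = cf.evaluate_profile(sol, fd.nodes)
        assert cf.compare_fields(c0, fd.substrate) < 1e-3
        assert cf.compare_fields(c1, fd.product) < 1e-3

    def test_uniform_field_has_unit_ratio(self, small_geometry):
        # no enzyme: substrate uniform at c0*, use substrate averages
        params = cf.KineticParams(k=0, D=50, alpha0=1, beta=0.5, c0_star=42, N_total=0)
        sol = cf.solve_steady_state(small_geometry, params, gamma=0.0)
        pa = cf.phase_averages(sol, species="substrate")
        assert pa.mean_cluster == pytest.approx(42, rel=1e-9)
        assert pa.mean_droplet == pytest.approx(42, rel=1e-9)
        assert pa.droplet_bulk_ratio == pytest.approx(1.0, rel=1e-9)

    def test_closed_form_shell_integrals_match_quadrature(
        self, small_geometry, small_params
    ):
        sol = cf.solve_steady_state(small_geometry, small_params, gamma=10.0)
        g = small_geometry
        for a, b in [(0, g.R1), (g.R1, g.R2), (g.R2, g.R0), (0, g.R0)]:
            exact = sol.product.shell_integral(a, b)
            num, _ = quad(
                lambda r: float(sol.product(r)) * 4 * math.pi * r**2, a, b, limit=200
            )
            assert exact == pytest.approx(num, rel=1e-8)

    def test_basin_mean_decomposes_into_phases(self, small_geometry, small_params):
        sol = cf.solve_steady_state(small_geometry, small_params, gamma=10.0)
        pa = cf.phase_averages(sol)
        g = small_geometry
        whole = sol.product.region_mean(0, g.R0)
        recomposed = (
            pa.mean_droplet * g.v_drop + pa.mean_bulk * (g.v_basin - g.v_drop)
        ) / g.v_basin
        assert whole == pytest.approx(recomposed, rel=1e-8)

    def test_clustering_increases_partition_ratio(self, small_geometry, small_params):
        lo = cf.phase_averages(
            cf.solve_steady_state(small_geometry, small_params, 0.0)
        ).droplet_bulk_ratio
        hi = cf.phase_averages(
            cf.solve_steady_state(small_geometry, small_params, 100.0)
        ).droplet_bulk_ratio
        assert hi >= lo


class TestSweepAndDetection:
    def test_sweep_matches_independent_solves(self, small_geometry, small_params):
        gammas = [0.0, 1.0, 10.0, 100.0]
        sw = cf.gamma_sweep(small_geometry, small_params, gammas)
        for i, g in enumerate(gammas):
            sol = cf.solve_steady_state(small_geometry, small_params, g)
            assert sw.cluster_center_c1[i] == pytest.approx(float(sol.product(0.0)))
            assert sw.droplet_bulk_ratio[i] == pytest.approx(
                cf.phase_averages(sol).droplet_bulk_ratio
            )

    def test_ratio_monotone_nondecreasing_over_sweep(self, small_geometry, small_params):
        gammas = cf.default_gamma_grid(0.1, 500, 24)
        sw = cf.gamma_sweep(small_geometry, small_params, gammas)
        assert np.all(np.diff(sw.droplet_bulk_ratio) >= -1e-9)

    def test_invalid_gamma_grid_rejected(self, small_geometry, small_params):
        with pytest.raises(ValidationError):
            cf.gamma_sweep(small_geometry, small_params, [0.0, 1.0, 1.0])

    def test_logistic_toy_matches_dense_grid_bruteforce(self):
        resp_fn = lambda g: 1.0 / (1.0 + np.exp(-(g - 20.0) / 4.0))
        gammas = np.linspace(0, 60, 61)
        resp = resp_fn(gammas)
        sw = cf.GammaSweepResult(
            gammas=gammas,
            cluster_center_c1=resp,
            droplet_bulk_ratio=resp,
            mean_cluster=resp,
            mean_droplet=resp,
            mean_bulk=resp,
            production_rate=resp,
        )
        op = cf.find_onset_and_plateau(sw)
        # brute force on a dense grid of the continuous curve
        dense = np.linspace(0, 60, 600001)
        rd = resp_fn(dense)
        lo, hi = rd[0], rd[-1]
        onset_bf = dense[np.argmax(rd >= lo + 0.05 * (hi - lo))]
        plateau_bf = dense[np.argmax(rd >= lo + 0.95 * (hi - lo))]
        step = gammas[1] - gammas[0]
        assert abs(op.gamma_onset - onset_bf) <= step
        assert abs(op.gamma_plateau - plateau_bf) <= step
        assert op.gamma_onset <= op.gamma_plateau

    def test_flat_response_flagged_degenerate(self):
        gammas = np.array([0.0, 1.0, 2.0, 3.0])
        flat = np.ones(4)
        sw = cf.GammaSweepResult(gammas, flat, flat, flat, flat, flat, flat)
        op = cf.find_onset_and_plateau(sw)
        assert op.degenerate and op.gamma_onset == op.gamma_plateau == 0.0

    def test_nonmonotone_response_rejected(self):
        gammas = np.array([0.0, 1.0, 2.0, 3.0])
        resp = np.array([0.0, 1.0, 0.5, 2.0])
        sw = cf.GammaSweepResult(gammas, resp, resp, resp, resp, resp, resp)
        with pytest.raises(ValidationError, match="monotone"):
            cf.find_onset_and_plateau(sw)


class TestFitGamma:
    def test_fixed_point_at_bracket_edge(self, small_geometry, small_params):
        r0 = cf.phase_averages(
            cf.solve_steady_state(small_geometry, small_params, 0.0)
        ).droplet_bulk_ratio
        assert cf.fit_gamma(r0, small_geometry, small_params, bracket=(0, 100)) == 0.0

    @pytest.mark.parametrize("gamma_true", [0.5, 3.0, 20.0])
    def test_round_trip_recovers_gamma(self, small_geometry, small_params, gamma_true):
        target = cf.phase_averages(
            cf.solve_steady_state(small_geometry, small_params, gamma_true)
        ).droplet_bulk_ratio
        got = cf.fit_gamma(target, small_geometry, small_params, bracket=(0, 200))
        assert got == pytest.approx(gamma_true, rel=1e-4)

    def test_ratio_above_plateau_reports_achievable_range(
        self, small_geometry, small_params
    ):
        with pytest.raises(ValidationError, match="achievable"):
            cf.fit_gamma(1e6, small_geometry, small_params, bracket=(0, 100))


class TestPresets:
    def test_in_vivo_uses_published_radii(self):
        geom, _ = cf.preset("in_vivo")
        assert geom.R1 == pytest.approx(0.1)
        assert geom.R2 == pytest.approx(2.0)

    def test_in_vitro_droplet_radius_half_mean_diameter(self):
        geom, _ = cf.preset("in_vitro")
        assert geom.R2 == pytest.approx(5.0)

    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValidationError, match="in_vivo"):
            cf.preset("in_silico")

    def test_catalytic_efficiency_converted_to_internal_units(self):
        _, kin = cf.preset("in_vivo")
        # 1 uM^-1 s^-1 = 1/602.2 um^3 copies^-1 s^-1
        assert kin.k == pytest.approx(1.0 / 602.214076, rel=1e-6)


class TestGeometryValidation:
    @pytest.mark.parametrize("radii", [(0, 1, 2), (1, 1, 2), (2, 1, 3), (1, 2, 2)])
    def test_ordering_enforced(self, radii):
        with pytest.raises(ValidationError):
            cf.BasinGeometry(*radii)

    def test_volumes(self):
        g = cf.BasinGeometry(1.0, 2.0, 3.0)
        assert g.v_cluster == pytest.approx(4 / 3 * math.pi, rel=1e-12)
        assert g.v_drop < g.v_basin
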