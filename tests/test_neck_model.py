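"""Unit and property tests for the membrane-neck free-energy model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fisbkit.exceptions import (
    ConfigurationError,
    DomainError,
    NoTransitionError,
)
from fisbkit.neck_model import (
    GridSpec,
    ModelParams,
    NeckGeometry,
    crowding_penalty,
    crowding_penalty_derivative,
    density_residual,
    find_critical_a,
    free_energy,
    lj_potential,
    minimize_free_energy_grid,
    phi_rmax_from_sigma,
    radius_residual,
    reference_params,
    solve_density,
    solve_equilibrium,
    sweep_interaction_strength,
)

# ---------------------------------------------------------------------------
# elementary terms
# ---------------------------------------------------------------------------


class TestLJPotential:
    def test_crossover_and_minimum(self):
        assert lj_potential(2.47, 2.47) == 0.0
        assert lj_potential(2 ** (1 / 6) * 2.47, 2.47) == pytest.approx(
            -0.25, rel=1e-12
        )

    def test_far_field_value(self):
        # (sigma/r)^12 - (sigma/r)^6 at r = 10 sigma
        expected = 0.1**12 - 0.1**6
        assert lj_potential(10.0, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-9.99e-7, rel=2e-3)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            lj_potential(-1.0, 1.0)
        with pytest.raises(DomainError):
            lj_potential(1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        r=st.floats(0.1, 100.0),
        sigma=st.floats(0.1, 10.0),
        k=st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, r, sigma, k):
        assert lj_potential(k * r, k * sigma) == pytest.approx(
            lj_potential(r, sigma), rel=1e-9, abs=1e-12
        )


class TestCrowdingPenalty:
    def test_zero_below_and_at_onset(self, dot_params):
        pr = dot_params.phi_rmax
        assert crowding_penalty(0.5 * pr, dot_params) == 0.0
        assert crowding_penalty(pr, dot_params) == pytest.approx(0.0, abs=1e-15)

    def test_value_just_above_onset(self, dot_params):
        # epsilon (1.1^3 - 1)^2 / 4 with epsilon = 32.78
        pr = dot_params.phi_rmax
        expected = 32.78 * (1.1**3 - 1.0) ** 2 / 4.0
        assert crowding_penalty(1.1 * pr, dot_params) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.898, rel=1e-3)

    def test_derivative_matches_finite_difference(self, dot_params):
        pr = dot_params.phi_rmax
        phi = 1.2 * pr
        h = phi * 1e-6
        fd = (
            crowding_penalty(phi + h, dot_params)
            - crowding_penalty(phi - h, dot_params)
        ) / (2 * h)
        assert crowding_penalty_derivative(phi, dot_params) == pytest.approx(
            fd, rel=1e-6
        )

    def test_derivative_zero_below_onset(self, dot_params):
        pr = dot_params.phi_rmax
        assert crowding_penalty_derivative(0.3 * pr, dot_params) == 0.0
        assert crowding_penalty_derivative(pr, dot_params) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_negative_density_rejected(self, dot_params):
        with pytest.raises(DomainError):
            crowding_penalty(-0.1, dot_params)


class TestPhiRmax:
    def test_reference_value_matches_close_packing(self):
        # 5e4 per um^2 printed for sigma_cis = 2.47 nm
        got_per_um2 = phi_rmax_from_sigma(2.47) * 1e6
        assert got_per_um2 == pytest.approx(5.0e4, rel=0.01)

    def test_unit_sigma(self):
        assert phi_rmax_from_sigma(1.0) == pytest.approx(
            2 ** (2 / 3) / 3**1.5, rel=1e-12
        )

    def test_inverse_square_scaling(self):
        assert phi_rmax_from_sigma(2.0) == pytest.approx(
            phi_rmax_from_sigma(1.0) / 4.0, rel=1e-12
        )


class TestParamsAndGeometry:
    def test_phi_rmax_derived_consistently(self, dot_params):
        assert dot_params.phi_rmax == pytest.approx(
            2 ** (2 / 3) / (3**1.5 * dot_params.sigma_cis**2), abs=1e-12
        )
        assert dot_params.r_max == pytest.approx(
            2 ** (1 / 6) * dot_params.sigma_cis, rel=1e-15
        )

    def test_geometry_identities(self):
        g = NeckGeometry(R=3.0, L=40.0)
        assert g.H * g.R == 1.0
        assert g.area == 2 * math.pi * 3.0 * 40.0

    def test_positivity_enforced(self):
        with pytest.raises(DomainError):
            reference_params(kappa=-1.0)

    def test_from_dict_with_units(self):
        p = ModelParams.from_dict(
            {
                "kappa": 20.0,
                "gamma": {"value": 1e-4, "unit": "N/m"},
                "sigma_trans": 2.47,
                "sigma_cis": 2.47,
                "epsilon": 32.78,
                "a": 1e4,
                "phi0": {"value": 100.0, "unit": "um^-2"},
                "L": 40.0,
            }
        )
        ref = reference_params()
        assert p.gamma == pytest.approx(ref.gamma, rel=1e-12)
        assert p.phi0 == pytest.approx(ref.phi0, rel=1e-12)

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ConfigurationError):
            ModelParams.from_dict({"kappa": 20.0, "bogus": 1.0})


# ---------------------------------------------------------------------------
# free energy and residuals
# ---------------------------------------------------------------------------


class TestFreeEnergy:
    def test_protein_free_closed_form(self, dot_params):
        # a = 0, phi = phi0: entropy and crowding vanish ->
        # pi L kappa / R + 2 pi R gamma (L - R)
        p = replace(dot_params, a=0.0)
        R = 5.0
        expected = (
            math.pi * p.L * p.kappa / R
            + 2 * math.pi * R * p.gamma * (p.L - R)
        )
        assert free_energy(R, p.phi0, p) == pytest.approx(expected, rel=1e-12)

    def test_stationary_in_phi_at_solved_density(self, dot_params):
        R = 3.0
        phi = solve_density(R, dot_params)
        h = phi * 1e-7
        dF = (
            free_energy(R, phi + h, dot_params)
            - free_energy(R, phi - h, dot_params)
        ) / (2 * h)
        area = 2 * math.pi * R * dot_params.L
        # dF/dphi = area * density_residual; both should vanish
        assert abs(dF / area) < 1e-6

    def test_equilibrium_beats_distant_state(self, dot_params):
        state = solve_equilibrium(dot_params, "variational")
        far = free_energy(10 * dot_params.sigma_trans, dot_params.phi0, dot_params)
        assert state.free_energy < far

    def test_domain_errors(self, dot_params):
        with pytest.raises(DomainError):
            free_energy(-1.0, 1e-4, dot_params)
        with pytest.raises(DomainError):
            free_energy(1.0, 0.0, dot_params)


class TestDensityResidualAndSolve:
    def test_closed_form_root_without_attraction(self, dot_params):
        p = replace(dot_params, a=0.0)
        phi = p.phi0 / math.e
        assert phi < p.phi_rmax
        assert density_residual(phi, 5.0, p) == pytest.approx(0.0, abs=1e-12)
        assert solve_density(5.0, p) == pytest.approx(phi, rel=1e-10)

    def test_far_radius_reduces_to_entropy_balance(self, dot_params):
        # V_LJ ~ 0 at R >> sigma, so the root returns to phi0/e
        assert solve_density(150.0, dot_params) == pytest.approx(
            dot_params.phi0 / math.e, rel=1e-6
        )

    def test_solver_output_satisfies_residual(self, dot_params):
        for R in (2.8, 3.5, 6.0, 20.0):
            phi = solve_density(R, dot_params)
            assert abs(density_residual(phi, R, dot_params)) < 1e-8

    def test_crowded_root_at_lj_minimum_vs_bisection_oracle(self, dot_params):
        # independent bisection on the crowded branch
        p = dot_params
        R = p.r_max
        lo, hi = p.phi_rmax, 2.0 * p.phi_rmax
        assert density_residual(lo, R, p) < 0 < density_residual(hi, R, p)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if density_residual(mid, R, p) < 0:
                lo = mid
            else:
                hi = mid
        oracle = 0.5 * (lo + hi)
        assert solve_density(R, p) == pytest.approx(oracle, rel=1e-9)
        assert 1.0 < oracle / p.phi_rmax < 1.2

    def test_residual_increasing_in_crowded_regime(self, dot_params):
        p = dot_params
        phis = np.linspace(1.01 * p.phi_rmax, 3 * p.phi_rmax, 64)
        res = density_residual(phis, p.r_max, p)
        assert np.all(np.diff(res) > 0)


class TestRadiusResidual:
    def test_closed_form_without_protein_terms(self, dot_params):
        p = replace(dot_params, a=0.0)
        R = 5.0
        expected = p.gamma - p.kappa / (2 * R**2) - 2 * p.gamma * R / p.L
        assert radius_residual(R, p.phi0, p, "printed") == pytest.approx(
            expected, rel=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(R=st.floats(2.6, 50.0), phi_frac=st.floats(0.01, 2.0))
    def test_variant_difference_is_lj_cross_term(self, R, phi_frac):
        p = reference_params()
        phi = phi_frac * p.phi_rmax
        diff = radius_residual(R, phi, p, "variational") - radius_residual(
            R, phi, p, "printed"
        )
        expected = p.a * phi**2 * lj_potential(R, p.sigma_trans)
        assert diff == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_variational_matches_finite_difference_of_free_energy(
        self, dot_params
    ):
        p = dot_params
        for R, phi in [(3.0, 1.05 * p.phi_rmax), (6.0, 0.5 * p.phi_rmax)]:
            h = R * 1e-6
            fd = (free_energy(R + h, phi, p) - free_energy(R - h, phi, p)) / (
                2 * h
            )
            got = radius_residual(R, phi, p, "variational")
            assert got == pytest.approx(fd / (2 * math.pi * p.L), rel=1e-6)

    def test_unknown_variant_rejected(self, dot_params):
        with pytest.raises(ConfigurationError):
            radius_residual(3.0, 1e-4, dot_params, "bogus")


# ---------------------------------------------------------------------------
# coupled solvers
# ---------------------------------------------------------------------------


class TestSolveEquilibrium:
    @pytest.mark.parametrize("variant", ["printed", "variational"])
    def test_reference_point_closed_neck(self, dot_params, variant):
        state = solve_equilibrium(dot_params, variant)
        assert not state.neck_open
        assert 2.5 < state.R < 3.5
        assert 0.9 * dot_params.phi_rmax < state.phi < 1.3 * dot_params.phi_rmax
        # both residuals vanish at the solution
        assert abs(density_residual(state.phi, state.R, dot_params)) < 1e-6
        assert abs(
            radius_residual(state.R, state.phi, dot_params, variant)
        ) < 1e-6
        assert state.n_in_neck == pytest.approx(
            2 * math.pi * state.R * dot_params.L * state.phi, rel=1e-12
        )

    def test_strong_attraction_approaches_lj_minimum(self, dot_params):
        # R tends to the trans-potential minimum 2^(1/6) sigma as a grows:
        # it approaches from above through the stability-diagram range and
        # stays within a fraction of a percent of r_max at extreme a
        moderate = solve_equilibrium(replace(dot_params, a=1e3))
        strong = solve_equilibrium(replace(dot_params, a=1e5))
        assert moderate.R > dot_params.r_max
        assert strong.R < moderate.R
        assert abs(strong.R - dot_params.r_max) / dot_params.r_max < 0.01

    def test_weak_attraction_opens_neck(self, dot_params):
        state = solve_equilibrium(replace(dot_params, a=100.0))
        assert state.neck_open
        assert math.isinf(state.R)

    def test_closed_radius_above_repulsive_core(self, dot_params):
        rng = np.random.default_rng(7)
        for _ in range(5):
            f = 1.0 + 0.5 * (2 * rng.random(4) - 1)
            p = replace(
                dot_params,
                kappa=dot_params.kappa * f[0],
                gamma=dot_params.gamma * f[1],
                a=dot_params.a * f[2],
                L=dot_params.L * f[3],
            )
            state = solve_equilibrium(p)
            if not state.neck_open:
                assert state.R >= 2 ** (1 / 6) * p.sigma_trans


class TestGridOracle:
    def test_grid_agrees_with_variational_solver_at_reference(self, dot_params):
        solver = solve_equilibrium(dot_params, "variational")
        grid = minimize_free_energy_grid(dot_params)
        assert grid.R == pytest.approx(solver.R, rel=0.02)

    def test_grid_minimum_dominates_grid_nodes(self, dot_params):
        spec = GridSpec(n_R=48, n_phi=48)
        state = minimize_free_energy_grid(dot_params, spec)
        R_ax, phi_ax = spec.axes(dot_params)
        F = free_energy(R_ax[:, None], phi_ax[None, :], dot_params)
        assert state.free_energy <= F.min() + 1e-9

    def test_no_attraction_minimum_at_open_edge(self, dot_params):
        state = minimize_free_energy_grid(replace(dot_params, a=0.0))
        assert state.neck_open

    def test_degenerate_grid_rejected(self, dot_params):
        with pytest.raises(ConfigurationError):
            minimize_free_energy_grid(dot_params, GridSpec(n_R=2))


class TestSweepAndCritical:
    def test_sweep_structure_and_monotonicity(self, dot_params):
        a_values = np.geomspace(1e2, 1e5, 16)
        sweep = sweep_interaction_strength(a_values, dot_params, "printed")
        assert len(sweep.states) == len(a_values)
        closed = [not s.neck_open for s in sweep.states]
        # single open -> closed transition, open below it
        first = closed.index(True)
        assert not any(closed[:first]) and all(closed[first:])
        radii = [s.R for s in sweep.states if not s.neck_open]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(radii, radii[1:]))
        # density saturates near close packing: across ~2.5 decades of a
        # above the transition, phi stays pinned within tens of percent of
        # phi_rmax (the crowding penalty is steep but finite)
        phis = [s.phi for s in sweep.states if not s.neck_open]
        assert all(
            0.9 * dot_params.phi_rmax < f < 1.5 * dot_params.phi_rmax
            for f in phis
        )
        assert sweep.a_critical is not None
        assert a_values[first - 1] < sweep.a_critical < a_values[first]

    def test_unsorted_sweep_rejected(self, dot_params):
        with pytest.raises(ConfigurationError):
            sweep_interaction_strength([1e4, 1e3], dot_params)

    def test_critical_a_classifies_both_sides(self, dot_params):
        ac = find_critical_a(dot_params, tol=1e-4, bracket=(1e2, 1e4))
        assert ac < 1e4  # the reference point itself is closed
        assert solve_equilibrium(replace(dot_params, a=0.5 * ac)).neck_open
        assert not solve_equilibrium(replace(dot_params, a=2.0 * ac)).neck_open

    def test_no_transition_signalled(self, dot_params):
        with pytest.raises(NoTransitionError):
            find_critical_a(dot_params, bracket=(1e4, 1e5))
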