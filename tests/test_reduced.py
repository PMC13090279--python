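"""Tests of the age-averaged ODE/DDE reductions."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from rolerev import (
    AveragedParameters,
    InitialCondition,
    ModelParameters,
    age_averaged_parameters,
    build_grid,
    dde_delayed_transition,
    initialize_state,
    integrate,
    integrate_reduced,
    mb_integral,
    newton_equilibrium,
    ode_rhs,
)
from rolerev.attractors import dde_equilibrium, ode_equilibrium
from rolerev.rates import base_death_rate


@pytest.fixture(scope="module")
def default_equilibrium():
    """Coexistence equilibrium of the age-structured model at the reference
    parameters (low-prey branch), shared across the module."""
    p = ModelParameters()
    grid = build_grid(0.05, p.tau_star, p.L)
    from scipy.integrate import cumulative_trapezoid
    from rolerev.rates import death_rate
    from rolerev import population_weights

    ages = grid.ages
    S = np.exp(-cumulative_trapezoid(death_rate(0.42, ages, p), ages, initial=0.0))
    w1, w2 = population_weights(grid)
    u0 = (p.a * 0.42 - p.r) / (p.s * float(w1 @ S) - p.b * float(w2 @ S))
    eq = newton_equilibrium(0.42, u0 * S, grid, p, compute_stability=False)
    assert eq.converged
    return p, grid, eq


def li_rhs(t, z, r, a, s, b, k, g, D, m1, m2):
    """The classical three-compartment role-reversal ODE (independent
    implementation used as the reduction's oracle)."""
    x, y1, y2 = z
    return [
        x * (r - a * x + s * y1 - b * y2),
        k * x * y2 - y1 * (g * x + D + m1),
        D * y1 - m2 * y2,
    ]


class TestAveragedParameters:
    def test_near_constant_rates_average_to_themselves(self, rng):
        # with nearly flat base rates the weighted means equal the rate value
        p = ModelParameters(d_ep=1e-9, b_ep=1e-9)
        grid = build_grid(0.1, p.tau_star, p.L)
        U = rng.random(grid.n_nodes) + 0.1
        avg = age_averaged_parameters(U, 1.0, grid, p)
        mu_const = p.d_p * math.exp(1e-9 * (0.0 - p.L))
        assert avg.m1 == pytest.approx(mu_const, rel=1e-6)
        assert avg.m2 == pytest.approx(mu_const, rel=1e-6)
        assert avg.b2 == pytest.approx(2 * p.b_p, rel=1e-6)

    def test_transition_rate_definition(self, params, coarse_grid, rng):
        from rolerev import population_weights

        U = rng.random(coarse_grid.n_nodes) + 0.05
        avg = age_averaged_parameters(U, 1.0, coarse_grid, params)
        w1, _ = population_weights(coarse_grid)
        assert avg.D == pytest.approx(U[coarse_grid.n_mature] / float(w1 @ U))
        assert avg.u_bar_tau_star == U[coarse_grid.n_mature]

    def test_degenerate_density_rejected(self, params, coarse_grid):
        U = np.zeros(coarse_grid.n_nodes)
        U[: coarse_grid.n_mature] = 1.0  # adults absent
        with pytest.raises(ValueError, match="degenerate"):
            age_averaged_parameters(U, 1.0, coarse_grid, params)

    def test_mb_integral_matches_quadrature(self, params):
        num, _ = quad(lambda t: base_death_rate(t, params), 0.0, params.tau_star)
        assert mb_integral(0.0, params.tau_star, params) == pytest.approx(num, rel=1e-10)

    def test_reference_cell_values_in_published_ranges(self, default_equilibrium):
        # the (tau*=1, g=0.2) coexistence equilibrium yields averaged rates
        # inside the ranges reported for the full parameter sweep
        p, grid, eq = default_equilibrium
        avg = age_averaged_parameters(eq.U_star, eq.X_star, grid, p)
        assert 0.353 <= avg.D <= 9.91
        assert 0.0794 <= avg.b2 <= 0.0835
        assert 0.0200 <= avg.m1 <= 0.0219
        assert 0.0363 <= avg.m2 <= 0.0546


class TestOdeReduction:
    AVG = AveragedParameters(
        D=0.89, b2=0.0, m1=0.021, m2=0.043, M_B=0.08, u_bar_tau_star=0.08
    )

    def test_reduces_to_li_system(self, rng):
        # with the adult base birth rate and hunger removed, the rhs is the
        # classical role-reversal ODE at any state
        p = ModelParameters(mu_M=1e-300)
        for _ in range(25):
            x, y1, y2 = rng.random(3) * np.array([40.0, 2.0, 2.0])
            mine = ode_rhs(x, y1, y2, p, self.AVG)
            ref = li_rhs(
                0.0, (x, y1, y2), p.r, p.a, p.s, p.b, p.k, p.g,
                self.AVG.D, self.AVG.m1, self.AVG.m2,
            )
            np.testing.assert_allclose(mine, ref, rtol=1e-12)

    def test_trivial_fixed_points(self, params):
        avg = self.AVG
        assert ode_rhs(0.0, 0.0, 0.0, params, avg) == (0.0, 0.0, 0.0)
        dx, _, _ = ode_rhs(params.r / params.a, 0.0, 0.0, params, avg)
        assert dx == pytest.approx(0.0, abs=1e-12)

    def test_extinction_saddle_eigenvalue(self):
        # Jacobian at the origin (Li limit) has eigenvalue r along the prey axis
        p = ModelParameters(mu_M=1e-300)
        eps = 1e-8
        dx, dy1, dy2 = ode_rhs(eps, 0.0, 0.0, p, self.AVG)
        assert dx / eps == pytest.approx(p.r, rel=1e-6)
        assert dy1 == 0.0 and dy2 == 0.0

    def test_mass_balance_in_transfer(self, params, rng):
        # the juvenile->adult transfer D*y1 moves mass, never creates it:
        # d(y1+y2) = births - deaths exactly
        avg = AveragedParameters(
            D=2.3, b2=0.08, m1=0.02, m2=0.04, M_B=0.08, u_bar_tau_star=0.1
        )
        for _ in range(20):
            x, y1, y2 = rng.random(3) * np.array([40.0, 2.0, 2.0])
            _, dy1, dy2 = ode_rhs(x, y1, y2, params, avg)
            hunger = params.mu_M * math.exp(-params.rho * x)
            births = params.k * x * y2 - math.expm1(-params.zeta * x) * avg.b2 * y2
            deaths = (
                params.g * x * y1 + avg.m1 * y1 + avg.m2 * y2
                + hunger * (y1 + y2)
            )
            assert dy1 + dy2 == pytest.approx(births - deaths, rel=1e-12)

    def test_dynamics_match_independent_li_integration(self):
        p = ModelParameters(mu_M=1e-300)
        z0 = (0.5, 0.1, 1.45)
        T = 100.0
        mine = integrate_reduced("ode", z0, p, self.AVG, T, rtol=1e-10, atol=1e-12)
        ref = solve_ivp(
            li_rhs, (0, T), z0,
            args=(p.r, p.a, p.s, p.b, p.k, p.g, self.AVG.D, self.AVG.m1, self.AVG.m2),
            t_eval=mine.t, rtol=1e-10, atol=1e-12,
        )
        np.testing.assert_allclose(mine.x, ref.y[0], rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(mine.y2, ref.y[2], rtol=1e-5, atol=1e-8)

    def test_equilibrium_is_stationary(self, default_equilibrium):
        p, grid, eq = default_equilibrium
        avg = age_averaged_parameters(eq.U_star, eq.X_star, grid, p)
        z, _, _ = ode_equilibrium((eq.X_star, eq.y1, eq.y2), p, avg)
        tr = integrate_reduced("ode", tuple(z), p, avg, 100.0)
        assert tr.x[-1] == pytest.approx(z[0], rel=1e-6)
        assert tr.y2[-1] == pytest.approx(z[2], rel=1e-6)

    def test_pde_and_ode_equilibria_nearby(self, default_equilibrium):
        # consistency of the reduction: the averaged ODE has an equilibrium
        # close to the age-structured one it was derived from
        p, grid, eq = default_equilibrium
        avg = age_averaged_parameters(eq.U_star, eq.X_star, grid, p)
        z, _, _ = ode_equilibrium((eq.X_star, eq.y1, eq.y2), p, avg)
        assert z[0] == pytest.approx(eq.X_star, rel=0.02)
        assert z[1] == pytest.approx(eq.y1, rel=0.02)
        assert z[2] == pytest.approx(eq.y2, rel=0.02)


class TestDdeReduction:
    def test_transition_collapses_without_prey_coupling(self, params):
        avg = AveragedParameters(
            D=1.0, b2=0.08, m1=0.02, m2=0.04,
            M_B=mb_integral(0.0, params.tau_star, params), u_bar_tau_star=0.1,
        )
        p = params.replace(g=0.0, mu_M=1e-300)
        born = (p.k * 2.0 - math.expm1(-p.zeta * 2.0) * avg.b2) * 0.7
        got = dde_delayed_transition(5.0, 2.0, 0.7, p, avg)
        assert got == pytest.approx(born * math.exp(-avg.M_B), rel=1e-12)

    def test_transition_short_delay_limit(self):
        # tau* -> 0: exponent and M_B vanish, flux equals the newborn flux
        p = ModelParameters(tau_star=1e-8)
        avg = AveragedParameters(
            D=1.0, b2=0.08, m1=0.02, m2=0.04,
            M_B=mb_integral(0.0, p.tau_star, p), u_bar_tau_star=0.1,
        )
        born = (p.k * 2.0 - math.expm1(-p.zeta * 2.0) * avg.b2) * 0.7
        assert dde_delayed_transition(2.0, 2.0, 0.7, p, avg) == pytest.approx(
            born, rel=1e-6
        )

    def test_constant_history_exponent(self, params):
        avg = AveragedParameters(
            D=1.0, b2=0.08, m1=0.02, m2=0.04,
            M_B=mb_integral(0.0, params.tau_star, params), u_bar_tau_star=0.1,
        )
        xbar, y2bar = 3.0, 0.5
        p = params
        born = (p.k * xbar - math.expm1(-p.zeta * xbar) * avg.b2) * y2bar
        expo = (
            -p.g * p.tau_star * xbar - avg.M_B
            - p.mu_M * p.tau_star * math.exp(-p.rho * xbar)
        )
        assert dde_delayed_transition(xbar, xbar, y2bar, p, avg) == pytest.approx(
            born * math.exp(expo), rel=1e-12
        )

    def test_negative_inputs_rejected(self, params):
        avg = AveragedParameters(
            D=1.0, b2=0.08, m1=0.02, m2=0.04, M_B=0.1, u_bar_tau_star=0.1
        )
        with pytest.raises(ValueError):
            dde_delayed_transition(-1.0, 1.0, 1.0, params, avg)

    def test_dde_and_ode_equilibria_differ_but_are_nearby(self, default_equilibrium):
        # the delay survival factor replaces the transition rate D, so the
        # two reductions have distinct (though close) steady states
        p, grid, eq = default_equilibrium
        avg = age_averaged_parameters(eq.U_star, eq.X_star, grid, p)
        z_ode, _, _ = ode_equilibrium((eq.X_star, eq.y1, eq.y2), p, avg)
        z_dde = dde_equilibrium((eq.X_star, eq.y1, eq.y2), p, avg)
        assert np.all(z_dde > 0)
        assert abs(z_dde[0] - z_ode[0]) > 1e-8
        assert z_dde[0] == pytest.approx(z_ode[0], rel=0.5)

    def test_integration_bounded_and_positive(self, default_equilibrium):
        p, grid, eq = default_equilibrium
        avg = age_averaged_parameters(eq.U_star, eq.X_star, grid, p)
        ic = InitialCondition.default(p)
        tr = integrate_reduced(
            "dde", (0.5, 0.1 * p.tau_star, 0.05 * (p.L - p.tau_star)),
            p, avg, 200.0, ic=ic,
        )
        assert tr.status == "completed"
        assert np.all(tr.x >= 0) and np.all(tr.y1 >= 0) and np.all(tr.y2 >= 0)
        assert tr.x.max() <= p.r / p.a * 1.5
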