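"""Tests of the age grid and the characteristics-aligned scheme."""

import numpy as np
import pytest

from rolerev import (
    CommensurabilityError,
    InitialCondition,
    ModelParameters,
    NegativeDensityError,
    RateTables,
    advance_step,
    build_grid,
    build_theory_grid,
    initialize_state,
    integrate,
    integrate_kmre,
    population_sizes,
    population_weights,
)


class TestGrid:
    @pytest.mark.parametrize(
        "h,tau_star,L,n1,nL",
        [(0.0125, 1.0, 30.0, 80, 2400), (0.005, 1.0, 30.0, 200, 6000)],
    )
    def test_node_indices(self, h, tau_star, L, n1, nL):
        g = build_grid(h, tau_star, L)
        assert (g.n_mature, g.n_max) == (n1, nL)
        assert g.tau_star == pytest.approx(tau_star)
        assert g.snap_error < 1e-12

    def test_strict_commensurability(self):
        with pytest.raises(CommensurabilityError):
            build_grid(0.3, 1.0, 30.0, strict=True)
        g = build_grid(0.3, 1.0, 30.0)  # non-strict snaps instead
        assert g.tau_star == pytest.approx(0.9)

    def test_theory_grid_extent(self):
        g = build_theory_grid(0.05, 1.0, tau0_max=10.0, T=2.0)
        assert g.n_max == 240
        assert not g.capped


class TestInitialization:
    def test_reference_initial_condition(self, params, coarse_grid):
        st = initialize_state(InitialCondition.default(params), coarse_grid, params)
        assert st.X == 0.5
        ages = coarse_grid.ages
        assert np.all(st.U[ages < 1.0] == 0.1)
        assert np.all(st.U[ages >= 1.0] == 0.05)

    def test_constant_profile_integrals_exact(self, params, coarse_grid):
        # trapezoid is exact for constants: y1 = c*tau*, y2 = c*(L - tau*)
        c = 0.37
        ic = InitialCondition(x0=1.0, levels=(c,), breaks=(0.0, params.L))
        st = initialize_state(ic, coarse_grid, params)
        assert st.Y1 == pytest.approx(c * params.tau_star, rel=1e-12)
        assert st.Y2 == pytest.approx(c * (params.L - params.tau_star), rel=1e-12)

    def test_zero_profile(self, params, coarse_grid):
        ic = InitialCondition(x0=1.0, levels=(0.0,), breaks=(0.0, params.L))
        st = initialize_state(ic, coarse_grid, params)
        assert st.Y1 == 0.0 and st.Y2 == 0.0

    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError):
            InitialCondition(x0=1.0, levels=(-0.1,), breaks=(0.0, 30.0))

    def test_tabulated_profile_interpolates(self, params, coarse_grid):
        ic = InitialCondition.from_table([0.0, 2.0, 30.0], [0.2, 0.1, 0.0])
        st = initialize_state(ic, coarse_grid, params)
        assert st.U[0] == pytest.approx(0.2)
        assert st.U[20] == pytest.approx(0.15)  # age 1.0, halfway down
        assert st.U[-1] == pytest.approx(0.0)


class TestWeights:
    def test_split_weights_sum_to_full_trapezoid(self, coarse_grid, rng):
        # half weights at the shared maturation node recombine exactly
        w1, w2 = population_weights(coarse_grid)
        w = w1 + w2
        h = coarse_grid.h
        assert w[0] == pytest.approx(0.5 * h)
        assert w[-1] == pytest.approx(0.5 * h)
        np.testing.assert_allclose(w[1:-1], h)
        U = rng.random(coarse_grid.n_nodes)
        y1, y2 = population_sizes(U, coarse_grid)
        assert y1 + y2 == pytest.approx(float(w @ U), rel=1e-14)

    def test_density_above_maturation_only(self, params, coarse_grid):
        # support strictly above tau*: y1 sees only the half-weight node
        U = np.zeros(coarse_grid.n_nodes)
        U[coarse_grid.n_mature :] = 1.0
        y1, _ = population_sizes(U, coarse_grid)
        assert y1 == pytest.approx(0.5 * coarse_grid.h)


class TestAdvanceStep:
    def test_pure_advection_shift(self, params, coarse_grid, rng):
        # with mu = 0 and B = 0 the density shifts one node per step
        tables = RateTables(params, coarse_grid)
        tables.mu = lambda x: np.zeros(coarse_grid.n_nodes)
        tables.B = lambda x: np.zeros(coarse_grid.n_nodes)
        ic = InitialCondition(x0=1.0, levels=(0.3, 0.7), breaks=(0.0, 10.0, 30.0))
        st = initialize_state(ic, coarse_grid, params)
        U0 = st.U.copy()
        for n in range(1, 6):
            st = advance_step(st, coarse_grid, params, tables=tables)
            np.testing.assert_array_equal(st.U[n:], U0[:-n])
            assert np.all(st.U[:n] == 0.0)

    def test_empty_density_logistic_prey_step(self, params):
        # one Euler step of the logistic prey from x=0.5, h=0.005
        grid = build_grid(0.005, params.tau_star, params.L)
        ic = InitialCondition(x0=0.5, levels=(0.0,), breaks=(0.0, params.L))
        st = initialize_state(ic, grid, params)
        st = advance_step(st, grid, params)
        expected = 0.5 * (1 + 0.005 * (0.4 - 0.01 * 0.5))
        assert st.X == pytest.approx(expected, rel=1e-14)

    def test_constant_death_geometric_decay(self, params, coarse_grid):
        m, c = 0.8, 0.01
        tables = RateTables(params, coarse_grid)
        tables.mu = lambda x: np.full(coarse_grid.n_nodes, m)
        tables.B = lambda x: np.zeros(coarse_grid.n_nodes)
        ic = InitialCondition(x0=1.0, levels=(c,), breaks=(0.0, 30.0))
        st = initialize_state(ic, coarse_grid, params)
        n = 20
        for _ in range(n):
            st = advance_step(st, coarse_grid, params, tables=tables)
        h = coarse_grid.h
        assert st.U[n + 3] == pytest.approx(c * (1 - h * m) ** n, rel=1e-12)

    def test_negative_density_signalled(self, params):
        # h*mu > 1 must be caught, not silently propagated
        grid = build_grid(0.5, 1.0, 30.0)
        p = params.replace(mu_M=5.0)
        ic = InitialCondition(x0=1e-6, levels=(0.1,), breaks=(0.0, 30.0))
        st = initialize_state(ic, grid, p)
        with pytest.raises(NegativeDensityError):
            for _ in range(10):
                st = advance_step(st, grid, p)

    def test_clamp_keeps_positivity(self, params):
        grid = build_grid(0.5, 1.0, 30.0)
        p = params.replace(mu_M=5.0)
        ic = InitialCondition(x0=1e-6, levels=(0.1,), breaks=(0.0, 30.0))
        st = initialize_state(ic, grid, p)
        for _ in range(10):
            st = advance_step(st, grid, p, clamp=True)
        assert np.all(st.U >= 0.0) and st.X >= 0.0


class TestIntegrate:
    def test_prey_logistic_fixed_point(self, params, coarse_grid):
        # no predators: prey settles at carrying capacity r/a = 40
        ic = InitialCondition(x0=0.5, levels=(0.0,), breaks=(0.0, params.L))
        st = initialize_state(ic, coarse_grid, params)
        tr = integrate(st, coarse_grid, params, 500.0, record_every=100)
        assert tr.status == "completed"
        assert tr.x[-1] == pytest.approx(params.r / params.a, abs=1e-6)
        assert tr.y1[-1] == 0.0 and tr.y2[-1] == 0.0

    def test_blowup_detected(self, params, coarse_grid):
        # runaway prey growth (no competition brake, strong juvenile feeding)
        p = params.replace(a=1e-6, s=1.0, b=0.1, g=0.01)
        ic = InitialCondition(x0=100.0, levels=(1.0,), breaks=(0.0, p.L))
        st = initialize_state(ic, coarse_grid, p)
        tr = integrate(st, coarse_grid, p, 500.0, blowup_threshold=1000.0)
        assert tr.status == "blowup"
        assert tr.t_end < 500.0
        assert max(tr.x[-1], tr.y1[-1], tr.y2[-1]) > 1000.0

    def test_snapshots_recorded(self, params, coarse_grid, default_state):
        tr = integrate(
            default_state, coarse_grid, params, 10.0, snapshot_times=(0.0, 5.0, 10.0)
        )
        assert set(tr.snapshots) == {0.0, 5.0, 10.0}
        assert all(v.size == coarse_grid.n_nodes for v in tr.snapshots.values())

    def test_positivity_preserved_at_safe_step(self, params, coarse_grid, default_state):
        tr = integrate(default_state, coarse_grid, params, 50.0)
        assert tr.status == "completed"
        assert tr.final_state.U.min() >= 0.0
        assert min(tr.x.min(), tr.y1.min(), tr.y2.min()) >= 0.0

    def test_lagged_and_synchronous_converge_together(self, params):
        # the printed scheme (lagged integrals) and the synchronous variant
        # agree on the state to O(h) after a fixed horizon
        outs = {}
        for lagged in (True, False):
            grid = build_grid(0.01, params.tau_star, params.L)
            st = initialize_state(InitialCondition.default(params), grid, params)
            tables = RateTables(params, grid)
            for _ in range(grid.steps_for(5.0)):
                st = advance_step(st, grid, params, tables=tables, lagged=lagged)
            outs[lagged] = st
        assert outs[True].X == pytest.approx(outs[False].X, rel=2e-2)
        np.testing.assert_allclose(outs[True].U, outs[False].U, rtol=2e-2, atol=1e-12)


class TestKMRERenewal:
    def test_decay_only_matches_exponential(self):
        # mu constant, B = 0: density decays like exp(-mu t) as h -> 0
        mu, T = 0.3, 2.0
        errs = []
        for h in (0.02, 0.01):
            K = int(round(10.0 / h))
            ages = h * np.arange(K + 1)
            u0 = np.exp(-((ages - 3.0) ** 2))
            U = integrate_kmre(u0, np.full(K + 1, mu), np.zeros(K + 1), h, int(T / h))
            n = int(T / h)
            exact = np.exp(-mu * T) * u0[: K + 1 - n]
            errs.append(np.abs(U[n:] - exact).max())
        assert errs[1] < 0.6 * errs[0]  # first-order decay
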