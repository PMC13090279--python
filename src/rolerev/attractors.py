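"""Equilibria and limit cycles of the discretized age-structured model.

The scheme defines a one-step map ``Phi`` on the state ``z = (X, U)``
(prey size and age-density nodes).  Equilibria are zeros of
``F(z) = z - Phi(z)`` found by Newton's method with a forward-difference
Jacobian; stability is the spectral radius of the map Jacobian
``dPhi = I - dF`` (strictly less than one means the equilibrium attracts
the discrete dynamics; ``(lambda - 1)/h`` approximates the continuous-time
exponents).  Limit cycles are fixed points of the Poincare first-return map
``G`` on the section ``X = X*`` through the (unstable) coexistence
equilibrium, found by minimizing ``f(U) = 0.5*||U - G(U)||^2`` with a
Levenberg-Marquardt iteration; the crossing state is obtained by linear
interpolation between the two bracketing steps.

Population integrals are evaluated synchronously from the current density
throughout this module (the lagged and synchronous variants of the scheme
share their fixed points, and a map on ``(X, U)`` alone keeps the state
dimension at ``n_nodes + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

from .grid import AgeGrid
from .params import ModelParameters
from .reduced import AveragedParameters, ode_rhs
from .solver import RateTables, Trajectory, population_weights

__all__ = [
    "EquilibriumResult",
    "LimitCycleResult",
    "StabilityInfo",
    "one_step_map",
    "scheme_residual",
    "finite_difference_jacobian",
    "newton_equilibrium",
    "assess_stability",
    "poincare_map",
    "find_limit_cycle",
    "cycle_extrema_order",
    "ode_equilibrium",
    "dde_equilibrium",
]


def one_step_map(
    X: float, U: np.ndarray, tables: RateTables
) -> tuple[float, np.ndarray]:
    """One scheme step on ``(X, U)`` with synchronous population integrals."""
    p, h = tables.params, tables.grid.h
    y1 = float(tables.w1 @ U)
    y2 = float(tables.w2 @ U)
    if p.variant == "saturated":
        gain = p.s * p.y1_hat * np.tanh(y1 / p.y1_hat)
    else:
        gain = p.s * y1
    X_new = X * (1.0 + h * (p.r - p.a * X + gain - p.b * y2))
    U_new = np.empty_like(U)
    U_new[1:] = U[:-1] * (1.0 - h * tables.mu(X)[:-1])
    U_new[0] = float(tables.w_full @ (tables.B(X) * U))
    return X_new, U_new


def scheme_residual(
    X_star: float,
    U_star: np.ndarray,
    grid: AgeGrid,
    params: ModelParameters,
    *,
    tables: RateTables | None = None,
) -> np.ndarray:
    """Fixed-point residual ``F(z) = z - Phi(z)``, length ``n_nodes + 1``."""
    if tables is None:
        tables = RateTables(params, grid)
    X_new, U_new = one_step_map(X_star, np.asarray(U_star, float), tables)
    out = np.empty(U_star.size + 1)
    out[0] = X_star - X_new
    out[1:] = U_star - U_new
    return out


def finite_difference_jacobian(
    F: Callable[[float, np.ndarray], np.ndarray],
    X_star: float,
    U_star: np.ndarray,
    *,
    eps: float = 1e-6,
) -> np.ndarray:
    """Forward-difference Jacobian of ``F`` at ``(X, U)``.

    The prey column uses an absolute perturbation ``eps``; density columns
    use the relative perturbation ``eps * U[k]``, falling back to an
    absolute ``eps`` at (near-)zero nodes so every column stays informative
    at the predator-free state.
    """
    F0 = F(X_star, U_star)
    n = F0.size
    J = np.empty((n, n))
    J[:, 0] = (F(X_star + eps, U_star) - F0) / eps
    U_pert = U_star.astype(float).copy()
    for k in range(U_star.size):
        step = eps * U_star[k]
        if abs(step) < 1e-300:
            step = eps
        U_pert[k] = U_star[k] + step
        J[:, k + 1] = (F(X_star, U_pert) - F0) / step
        U_pert[k] = U_star[k]
    return J


@dataclass
class StabilityInfo:
    """Stability of a fixed point of the one-step map."""

    stable: bool
    spectral_radius: float
    leading_exponents: np.ndarray  # (lambda - 1)/h for the dominant eigenvalues


def assess_stability(
    jacobian_of_map: np.ndarray, h: float, *, n_leading: int = 5
) -> StabilityInfo:
    """Classify a discrete-map fixed point from its Jacobian spectrum."""
    eig = np.linalg.eigvals(jacobian_of_map)
    order = np.argsort(-np.abs(eig))
    leading = eig[order[:n_leading]]
    rho = float(np.abs(leading[0])) if leading.size else 0.0
    return StabilityInfo(
        stable=rho < 1.0,
        spectral_radius=rho,
        leading_exponents=(leading - 1.0) / h,
    )


@dataclass
class EquilibriumResult:
    """A fixed point of the scheme with residual and stability information."""

    X_star: float
    U_star: np.ndarray
    residual_norm: float
    converged: bool
    iterations: int
    y1: float = 0.0
    y2: float = 0.0
    stability: StabilityInfo | None = None

    @property
    def stable(self) -> bool | None:
        return None if self.stability is None else self.stability.stable


def newton_equilibrium(
    X_guess: float,
    U_guess: np.ndarray,
    grid: AgeGrid,
    params: ModelParameters,
    *,
    tol: float = 1e-10,
    max_iter: int = 50,
    eps: float = 1e-6,
    compute_stability: bool = True,
) -> EquilibriumResult:
    """Newton iteration on ``F(z) = z - Phi(z)`` from a warm start.

    Warm starts (a long integration, or a neighboring equilibrium during
    continuation) make damping unnecessary; a singular Jacobian or the
    iteration cap yields ``converged=False`` rather than an exception.
    """
    tables = RateTables(params, grid)

    def F(X, U):
        return scheme_residual(X, U, grid, params, tables=tables)

    X = float(X_guess)
    U = np.asarray(U_guess, dtype=float).copy()
    res = F(X, U)
    it = 0
    converged = float(np.abs(res).max()) < tol
    J = None
    while not converged and it < max_iter:
        J = finite_difference_jacobian(F, X, U, eps=eps)
        try:
            delta = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError:
            break
        X += float(delta[0])
        U += delta[1:]
        res = F(X, U)
        it += 1
        converged = float(np.abs(res).max()) < tol

    stability = None
    if converged and compute_stability:
        if J is None or it == 0:
            J = finite_difference_jacobian(F, X, U, eps=eps)
        dphi = np.eye(J.shape[0]) - J
        stability = assess_stability(dphi, grid.h)
    y1 = float(tables.w1 @ U)
    y2 = float(tables.w2 @ U)
    return EquilibriumResult(
        X_star=X, U_star=U, residual_norm=float(np.abs(res).max()),
        converged=converged, iterations=it, y1=y1, y2=y2, stability=stability,
    )


def coexistence_guesses(
    params: ModelParameters, grid: AgeGrid
) -> list[tuple[float, np.ndarray]]:
    """Warm starts for Newton from the renewal-equation equilibrium structure.

    At a steady state the age density is a survival curve,
    ``u(tau) = u(0) * exp(-integral of mu(x*, .))``, and the prey level
    ``x*`` must make the net reproduction number
    ``R0(x) = integral B(x, tau) exp(-M(x, tau)) dtau`` equal one (each
    predator replaces itself).  ``R0`` is hump-shaped in ``x`` (births grow
    with prey, but so does juvenile predation), so up to two roots exist;
    the newborn density then follows from the prey nullcline.  Roots with a
    negative density scale are discarded.
    """
    from scipy.integrate import cumulative_trapezoid
    from scipy.optimize import brentq

    from .rates import birth_rate, death_rate

    ages = grid.ages
    x_cap = params.r / params.a

    def R0(x: float) -> float:
        M = cumulative_trapezoid(death_rate(x, ages, params), ages, initial=0.0)
        return float(np.trapezoid(birth_rate(x, ages, params) * np.exp(-M), ages))

    # the scan reaches well above the prey-only carrying capacity: with the
    # prey feeding on juvenile predators, coexistence equilibria with
    # x* > r/a exist (the s*y1 gain offsets the competition loss)
    xs = np.geomspace(1e-3 * x_cap, 10.0 * x_cap, 120)
    vals = np.array([R0(x) - 1.0 for x in xs])
    w1, w2 = population_weights(grid)
    out = []
    for i in range(xs.size - 1):
        if vals[i] * vals[i + 1] < 0:
            xr = brentq(lambda x: R0(x) - 1.0, xs[i], xs[i + 1])
            M = cumulative_trapezoid(death_rate(xr, ages, params), ages, initial=0.0)
            S = np.exp(-M)
            denom = params.s * float(w1 @ S) - params.b * float(w2 @ S)
            if denom == 0.0:
                continue
            u0 = (params.a * xr - params.r) / denom
            if u0 > 0.0:
                out.append((xr, u0 * S))
    return out


class NoReturnError(RuntimeError):
    """The trajectory never re-crossed the Poincare section."""


def poincare_map(
    U_on_section: np.ndarray,
    X_star: float,
    grid: AgeGrid,
    params: ModelParameters,
    *,
    tables: RateTables | None = None,
    t_max: float = 400.0,
    record: bool = False,
) -> tuple[np.ndarray, float, Trajectory | None]:
    """First-return map on the section ``X = X_star`` (upward crossings).

    Integrates from ``(X_star, U)`` until the prey next crosses ``X_star``
    from below; the crossing density and time come from linear
    interpolation between the bracketing steps.  Returns ``(density at
    crossing, return time, optional recorded trajectory)``.
    """
    if tables is None:
        tables = RateTables(params, grid)
    h = grid.h
    n_steps = int(round(t_max / h))
    X = float(X_star)
    U = np.asarray(U_on_section, dtype=float).copy()
    s_prev = 0.0
    ts, xs, y1s, y2s = [], [], [], []
    U_prev = U.copy()
    for n in range(1, n_steps + 1):
        U_prev, X_prev = U, X
        X, U = one_step_map(X, U, tables)
        if record:
            ts.append(n * h)
            xs.append(X)
            y1s.append(float(tables.w1 @ U))
            y2s.append(float(tables.w2 @ U))
        s = X - X_star
        if n > 1 and s_prev < 0.0 <= s:
            theta = -s_prev / (s - s_prev)
            U_cross = U_prev + theta * (U - U_prev)
            t_cross = (n - 1 + theta) * h
            traj = None
            if record:
                traj = Trajectory(
                    t=np.array(ts), x=np.array(xs),
                    y1=np.array(y1s), y2=np.array(y2s),
                    status="completed", t_end=t_cross,
                )
            return U_cross, t_cross, traj
        s_prev = s
    raise NoReturnError(
        f"no upward return to the section X={X_star:.6g} within t_max={t_max}"
    )


@dataclass
class LimitCycleResult:
    """A fixed point of the Poincare map: a limit cycle of the scheme."""

    X_section: float
    U_fixed: np.ndarray
    period: float
    f_value: float            # 0.5*||U - G(U)||^2 at the solution
    converged: bool
    iterations: int
    extrema: dict = field(default_factory=dict)        # var -> (min, max)
    extrema_times: dict = field(default_factory=dict)  # 'max x', 'min y1', ... -> time


def cycle_extrema_order(traj: Trajectory) -> list[str]:
    """Events 'max x', 'min x', 'max y1', ... sorted by time over one period."""
    events = {}
    for name, series in (("x", traj.x), ("y1", traj.y1), ("y2", traj.y2)):
        events[f"max {name}"] = float(traj.t[int(np.argmax(series))])
        events[f"min {name}"] = float(traj.t[int(np.argmin(series))])
    return sorted(events, key=events.get)


def find_limit_cycle(
    U_initial: np.ndarray,
    X_star: float,
    grid: AgeGrid,
    params: ModelParameters,
    *,
    tol: float = 1e-14,
    grad_tol: float = 1e-10,
    max_iter: int = 20,
    picard_warmup: int = 30,
    eps: float = 1e-6,
    t_max: float = 400.0,
    return_map: Callable[[np.ndarray], tuple[np.ndarray, float]] | None = None,
) -> LimitCycleResult:
    """Locate a limit cycle as a fixed point of the Poincare map.

    A short run of plain map iterations (an attracting cycle makes
    ``U <- G(U)`` contract) warms up the Levenberg-Marquardt iteration on
    the residual ``U - G(U)``, whose Jacobian is formed by forward
    differences with relative perturbations.  Success means
    ``f(U) = 0.5*||U - G(U)||^2 < tol``.  ``return_map`` overrides the
    first-return map (used for reduced models or testing); it must return
    ``(image, return time)``.
    """
    tables = RateTables(params, grid)

    if return_map is not None:
        G = return_map
    else:

        def G(U):
            img, t_ret, _ = poincare_map(
                U, X_star, grid, params, tables=tables, t_max=t_max
            )
            return img, t_ret

    U = np.asarray(U_initial, dtype=float).copy()
    GU, period = G(U)
    f = 0.5 * float(((U - GU) ** 2).sum())
    n_eval = 1
    for _ in range(picard_warmup):
        if f < tol:
            break
        U = GU
        GU, period = G(U)
        n_eval += 1
        f_new = 0.5 * float(((U - GU) ** 2).sum())
        if f_new >= f:   # contraction stalled; hand over to LM
            f = f_new
            break
        f = f_new

    lam = 1e-3
    it = 0
    converged = f < tol
    while not converged and it < max_iter:
        R = U - GU
        # forward-difference Jacobian of the residual, relative perturbations
        m = U.size
        J = np.empty((m, m))
        U_pert = U.copy()
        for k in range(m):
            step = eps * U[k]
            if abs(step) < 1e-300:
                step = eps
            U_pert[k] = U[k] + step
            Gk, _ = G(U_pert)
            J[:, k] = ((U_pert - Gk) - R) / step
            U_pert[k] = U[k]
        n_eval += m
        grad = J.T @ R
        if float(np.linalg.norm(grad)) < grad_tol:
            break
        JTJ = J.T @ J
        improved = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(JTJ + lam * np.eye(m), -grad)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            U_try = U + delta
            GU_try, period_try = G(U_try)
            n_eval += 1
            f_try = 0.5 * float(((U_try - GU_try) ** 2).sum())
            if f_try < f:
                U, GU, f, period = U_try, GU_try, f_try, period_try
                lam = max(lam / 10.0, 1e-12)
                improved = True
                break
            lam *= 10.0
        it += 1
        if not improved:
            break
        converged = f < tol

    # per-variable extrema over one period, from the recorded return orbit
    extrema: dict = {}
    extrema_times: dict = {}
    try:
        if return_map is not None:
            raise NoReturnError("custom return map records no orbit")
        _, period, orbit = poincare_map(
            U, X_star, grid, params, tables=tables, t_max=t_max, record=True
        )
        if orbit is not None:
            for name, series in (("x", orbit.x), ("y1", orbit.y1), ("y2", orbit.y2)):
                extrema[name] = (float(series.min()), float(series.max()))
                extrema_times[f"max {name}"] = float(orbit.t[int(np.argmax(series))])
                extrema_times[f"min {name}"] = float(orbit.t[int(np.argmin(series))])
    except NoReturnError:
        pass
    return LimitCycleResult(
        X_section=X_star, U_fixed=U, period=float(period), f_value=f,
        converged=bool(f < tol), iterations=it,
        extrema=extrema, extrema_times=extrema_times,
    )


def dde_equilibrium(
    guess: tuple[float, float, float],
    params: ModelParameters,
    avg: AveragedParameters,
) -> np.ndarray:
    """Steady state of the delayed reduction.

    At a fixed point the delayed and current prey sizes coincide, so the
    maturation flux collapses to a closed-form function of the state; the
    root of the stationary right-hand side is found by least squares.
    Because the survival factor over the maturation delay replaces the
    transition rate ``D``, this equilibrium is close to, but not identical
    with, the ODE reduction's.
    """
    from .reduced import dde_delayed_transition

    p = params

    def rhs(z):
        x, y1, y2 = z
        x = max(x, 0.0)
        y2 = max(y2, 0.0)
        hunger = p.mu_M * np.exp(-p.rho * x)
        u_ts = dde_delayed_transition(x, x, y2, p, avg)
        born = (p.k * x - np.expm1(-p.zeta * x) * avg.b2) * y2
        return np.array(
            [
                x * (p.r - p.a * x + p.s * y1 - p.b * y2),
                born - u_ts - (p.g * x + avg.m1 + hunger) * y1,
                u_ts - (avg.m2 + hunger) * y2,
            ]
        )

    sol = least_squares(rhs, np.asarray(guess, float), xtol=1e-14, ftol=1e-14)
    return sol.x


def ode_equilibrium(
    guess: tuple[float, float, float],
    params: ModelParameters,
    avg: AveragedParameters,
    *,
    eps: float = 1e-7,
) -> tuple[np.ndarray, bool, np.ndarray]:
    """Coexistence equilibrium of the reduced ODE by nonlinear least squares.

    Returns ``(state, stable, eigenvalues)`` where stability is read off
    the forward-difference Jacobian of the right-hand side.
    """

    def rhs(z):
        return np.array(ode_rhs(z[0], z[1], z[2], params, avg))

    sol = least_squares(rhs, np.asarray(guess, float), xtol=1e-14, ftol=1e-14)
    z = sol.x
    J = np.empty((3, 3))
    f0 = rhs(z)
    for i in range(3):
        zp = z.copy()
        step = eps * max(abs(z[i]), 1.0)
        zp[i] += step
        J[:, i] = (rhs(zp) - f0) / step
    eig = np.linalg.eigvals(J)
    return z, bool(np.max(eig.real) < 0.0), eig
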