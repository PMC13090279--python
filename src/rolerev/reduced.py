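"""Age-averaged ODE and DDE reductions of the age-structured model.

Collapsing the predator age structure turns the renewal equation into a
three-variable ODE system for ``(x, y1, y2)``: the age-dependent base birth
and death rates are replaced by density-weighted averages over the
juvenile and adult age segments (``b2``, ``m1``, ``m2``), taken at a
coexistence equilibrium of the full model, and the maturation flux
``u(t, tau*)`` is replaced by a transition rate ``D = u_eq(tau*) / y1_eq``.

The DDE reduction keeps the maturation delay explicit instead: the flux of
juveniles maturing at time ``t`` is the newborn flux at ``t - tau*``
attenuated by the survival over ``[t - tau*, t]``, with the prey-dependent
part of the death rate integrated by the trapezoid rule in time.  For
``t < tau*`` the maturing generation comes from the initial age density.

With the adult base birth rate and the hunger deaths removed
(``b2 = 0``, ``mu_M = 0``), the ODE reduction coincides with the classical
three-compartment role-reversal ODE that motivated the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .grid import AgeGrid
from .params import InitialCondition, ModelParameters
from .solver import Trajectory, population_weights
from . import rates

__all__ = [
    "AveragedParameters",
    "age_averaged_parameters",
    "mb_integral",
    "ode_rhs",
    "dde_delayed_transition",
    "integrate_reduced",
]


@dataclass(frozen=True)
class AveragedParameters:
    """Age-averaged rates derived from an equilibrium density.

    ``D``: juvenile-to-adult transition rate; ``b2``: density-weighted mean
    of the base birth rate over the adult segment; ``m1``/``m2``: weighted
    means of the base death rate over the juvenile/adult segments; ``M_B``:
    integral of the base death rate over ``[0, tau_star]`` (the age-related
    death burden a maturing juvenile accumulates); ``u_bar_tau_star``: the
    equilibrium density at the maturation age.
    """

    D: float
    b2: float
    m1: float
    m2: float
    M_B: float
    u_bar_tau_star: float

    def to_dict(self) -> dict[str, float]:
        return dict(vars(self))

    @classmethod
    def from_dict(cls, d) -> "AveragedParameters":
        return cls(**d)


def mb_integral(tau_lo: float, tau_hi: float, params: ModelParameters) -> float:
    """Closed-form integral of the base death rate over ``[tau_lo, tau_hi]``."""
    c = params.d_p / params.d_ep
    return c * (
        math.exp(params.d_ep * (tau_hi - params.L))
        - math.exp(params.d_ep * (tau_lo - params.L))
    )


def age_averaged_parameters(
    equilibrium_density: np.ndarray,
    x_eq: float,
    grid: AgeGrid,
    params: ModelParameters,
) -> AveragedParameters:
    """Average the base rates against an equilibrium age density.

    Numerator and denominator integrals use the same trapezoid weights
    (half weight at the maturation node) as the population integrals, so a
    constant rate averages to itself exactly.
    """
    U = np.asarray(equilibrium_density, dtype=float)
    w1, w2 = population_weights(grid)
    y1 = float(w1 @ U)
    y2 = float(w2 @ U)
    if y1 <= 0.0 or y2 <= 0.0:
        raise ValueError(
            "degenerate equilibrium density: zero weight on an age segment "
            f"(y1={y1:.3g}, y2={y2:.3g})"
        )
    mu_b = rates.base_death_rate(grid.ages, params)
    btilde = rates.base_birth_rate(grid.ages, params)
    return AveragedParameters(
        D=float(U[grid.n_mature]) / y1,
        b2=float(w2 @ (btilde * U)) / y2,
        m1=float(w1 @ (mu_b * U)) / y1,
        m2=float(w2 @ (mu_b * U)) / y2,
        M_B=mb_integral(0.0, params.tau_star, params),
        u_bar_tau_star=float(U[grid.n_mature]),
    )


def ode_rhs(
    x: float, y1: float, y2: float, params: ModelParameters, avg: AveragedParameters
) -> tuple[float, float, float]:
    """Right-hand side of the age-averaged ODE reduction."""
    p = params
    hunger = p.mu_M * math.exp(-p.rho * x)
    dx = x * (p.r - p.a * x + p.s * y1 - p.b * y2)
    births = p.k * x * y2 - math.expm1(-p.zeta * x) * avg.b2 * y2
    dy1 = births - avg.D * y1 - p.g * x * y1 - avg.m1 * y1 - hunger * y1
    dy2 = avg.D * y1 - avg.m2 * y2 - hunger * y2
    return dx, dy1, dy2


def dde_delayed_transition(
    x_now: float,
    x_delayed: float,
    y2_delayed: float,
    params: ModelParameters,
    avg: AveragedParameters,
) -> float:
    """Maturation flux ``u(t, tau*)`` for ``t >= tau*``.

    The newborn flux a maturation age ago, ``u(t - tau*, 0) =
    k*x(t-tau*)*y2(t-tau*) + (1 - e^{-zeta x(t-tau*)}) b2 y2(t-tau*)``,
    attenuated by predation by prey, age-related death, and hunger along the
    characteristic, with the prey-dependent exponents integrated by the
    trapezoid rule between the two endpoint times.
    """
    if min(x_now, x_delayed, y2_delayed) < 0:
        raise ValueError("prey sizes and adult population must be nonnegative")
    p = params
    born = (p.k * x_delayed - math.expm1(-p.zeta * x_delayed) * avg.b2) * y2_delayed
    expo = (
        -0.5 * p.g * p.tau_star * (x_delayed + x_now)
        - avg.M_B
        - 0.5 * p.mu_M * p.tau_star
        * (math.exp(-p.rho * x_delayed) + math.exp(-p.rho * x_now))
    )
    return born * math.exp(expo)


def _initial_transition(
    t: float,
    x_now: float,
    x0: float,
    ic: InitialCondition,
    params: ModelParameters,
    avg: AveragedParameters,
) -> float:
    """Maturation flux for ``t < tau*``: the generation now maturing was at
    age ``tau* - t`` initially, and decays the same way over ``[0, t]``."""
    p = params
    u_init = float(ic.density(p.tau_star - t))
    expo = (
        -0.5 * p.g * t * (x0 + x_now)
        - mb_integral(p.tau_star - t, p.tau_star, params)
        - 0.5 * p.mu_M * t * (math.exp(-p.rho * x0) + math.exp(-p.rho * x_now))
    )
    return u_init * math.exp(expo)


def integrate_reduced(
    model: str,
    initial: tuple[float, float, float],
    params: ModelParameters,
    avg: AveragedParameters,
    T: float,
    *,
    blowup_threshold: float = 1000.0,
    dt: float = 0.01,
    ic: InitialCondition | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the reduced ODE (``model='ode'``) or DDE (``'dde'``).

    The ODE uses an adaptive Runge-Kutta integrator with a terminal
    blow-up event.  The DDE uses a fixed-step Heun scheme whose step
    divides the delay exactly, with the stored history providing the
    delayed values; ``ic`` (default: the reference profile) supplies the
    initial-generation branch for ``t < tau*``.
    """
    if model == "ode":
        return _integrate_ode(initial, params, avg, T, blowup_threshold, rtol, atol)
    if model == "dde":
        if ic is None:
            ic = InitialCondition.default(params)
        return _integrate_dde(initial, params, avg, T, blowup_threshold, dt, ic)
    raise ValueError(f"model must be 'ode' or 'dde', got {model!r}")


def _integrate_ode(initial, params, avg, T, blowup_threshold, rtol, atol) -> Trajectory:
    def rhs(t, z):
        return ode_rhs(z[0], z[1], z[2], params, avg)

    def blowup(t, z):
        return blowup_threshold - np.max(z)

    blowup.terminal = True
    blowup.direction = -1
    t_eval = np.linspace(0.0, T, max(int(T / 0.1), 2) + 1)
    sol = solve_ivp(
        rhs, (0.0, T), np.asarray(initial, float),
        t_eval=t_eval, events=blowup, rtol=rtol, atol=atol, method="RK45",
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    status = "blowup" if sol.status == 1 else "completed"
    t_end = float(sol.t_events[0][0]) if status == "blowup" else T
    return Trajectory(
        t=sol.t, x=sol.y[0], y1=sol.y[1], y2=sol.y[2], status=status, t_end=t_end
    )


def _integrate_dde(initial, params, avg, T, blowup_threshold, dt, ic) -> Trajectory:
    p = params
    d = max(int(round(p.tau_star / dt)), 1)
    dt = p.tau_star / d
    n_steps = int(math.ceil(T / dt))
    xs = np.empty(n_steps + 1)
    y1s = np.empty(n_steps + 1)
    y2s = np.empty(n_steps + 1)
    xs[0], y1s[0], y2s[0] = initial
    x0 = xs[0]

    def transition(i: int, t: float, x_now: float) -> float:
        if i >= d:
            return dde_delayed_transition(x_now, xs[i - d], y2s[i - d], p, avg)
        return _initial_transition(t, x_now, x0, ic, p, avg)

    def rhs(i, t, x, y1, y2):
        hunger = p.mu_M * math.exp(-p.rho * min(x, 700.0 / p.rho))
        u_ts = transition(i, t, x)
        dx = x * (p.r - p.a * x + p.s * y1 - p.b * y2)
        dy1 = (
            (p.k * x - math.expm1(-p.zeta * x) * avg.b2) * y2
            - u_ts - p.g * x * y1 - avg.m1 * y1 - hunger * y1
        )
        dy2 = u_ts - avg.m2 * y2 - hunger * y2
        return dx, dy1, dy2

    status, t_end = "completed", n_steps * dt
    i_last = n_steps
    for i in range(n_steps):
        t = i * dt
        x, y1, y2 = xs[i], y1s[i], y2s[i]
        f1 = rhs(i, t, x, y1, y2)
        # Heun: predictor at t+dt (delayed values at t+dt-tau* are past)
        xp = max(x + dt * f1[0], 0.0)
        y1p, y2p = y1 + dt * f1[1], max(y2 + dt * f1[2], 0.0)
        f2 = rhs(i + 1, t + dt, xp, max(y1p, 0.0), y2p)
        xs[i + 1] = max(x + 0.5 * dt * (f1[0] + f2[0]), 0.0)
        y1s[i + 1] = max(y1 + 0.5 * dt * (f1[1] + f2[1]), 0.0)
        y2s[i + 1] = max(y2 + 0.5 * dt * (f1[2] + f2[2]), 0.0)
        if max(xs[i + 1], y1s[i + 1], y2s[i + 1]) > blowup_threshold:
            status, t_end, i_last = "blowup", (i + 1) * dt, i + 1
            break

    n = i_last + 1
    return Trajectory(
        t=dt * np.arange(n), x=xs[:n], y1=y1s[:n], y2=y2s[:n],
        status=status, t_end=t_end,
    )
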