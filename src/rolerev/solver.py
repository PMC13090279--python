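"""Characteristics-aligned finite-difference solver for the age-structured model.

One step of the scheme, with time/age step ``h`` shared by both variables:

* prey: forward Euler on ``x' = x(r - a x + s y1 - b y2)``;
* density: shift one age node right with Euler decay,
  ``U[n+1, k] = U[n, k-1] * (1 - h*mu(X[n], (k-1)h))``;
* newborns: ``U[n+1, 0] = trapz(B(X[n], .) * U[n, .])`` (the renewal
  boundary condition evaluated by the trapezoid rule);
* populations: ``Y1, Y2`` are trapezoid integrals of the density over
  ``[0, tau_star]`` and ``[tau_star, tau_max]``, with half weight at the
  shared maturation node.  In the *lagged* (default) variant ``Y[n+1]`` is
  computed from the pre-update density ``U[n, .]``, faithfully to the
  printed scheme; the *synchronous* variant computes ``Y[n]`` from
  ``U[n, .]`` and is used by the fixed-point machinery (both variants share
  the same fixed points and converge to the same limit as ``h -> 0``).

The scheme is first-order accurate; ``h`` must satisfy ``h*mu < 1`` on the
grid for positivity.  ``clamp=True`` floors the per-step survival factor at
zero (and the prey at zero), a positivity-preserving fallback for coarse
steps used in bulk parameter sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .grid import AgeGrid
from .params import InitialCondition, ModelParameters
from . import rates

__all__ = [
    "RateTables",
    "SimState",
    "Trajectory",
    "NegativeDensityError",
    "initialize_state",
    "advance_step",
    "integrate",
    "population_sizes",
    "population_weights",
    "integrate_kmre",
]


class NegativeDensityError(RuntimeError):
    """The scheme produced a negative density or prey size.

    This signals a too-large time step for the current death rates; reduce
    ``h`` (or enable ``clamp`` for bulk runs).
    """


def population_weights(grid: AgeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoid weight vectors (including the factor ``h``) for the
    juvenile and adult population integrals.

    The maturation node carries half weight in each integral, so the two
    weight vectors sum exactly to the full-range trapezoid weights.
    """
    K, n1, h = grid.n_max, grid.n_mature, grid.h
    w1 = np.zeros(K + 1)
    w2 = np.zeros(K + 1)
    if n1 >= 1:
        w1[: n1 + 1] = h
        w1[0] = w1[n1] = 0.5 * h
    w2[n1:] = h
    w2[n1] = w2[K] = 0.5 * h
    return w1, w2


def _full_weights(grid: AgeGrid) -> np.ndarray:
    w = np.full(grid.n_max + 1, grid.h)
    w[0] = w[-1] = 0.5 * grid.h
    return w


class RateTables:
    """Per-(params, grid) precomputed rate arrays over the age nodes.

    Splits every rate into its prey-independent part (precomputed) and the
    prey-dependent factors evaluated per step, so a scheme step costs a few
    vector operations.
    """

    def __init__(self, params: ModelParameters, grid: AgeGrid):
        self.params = params
        self.grid = grid
        ages = grid.ages
        self.phi_above = rates.smooth_indicator(ages, params.tau_star, params.nu, "above")
        self.phi_below = rates.smooth_indicator(ages, params.tau_star, params.nu, "below")
        self.mu_b = rates.base_death_rate(ages, params)
        self.btilde = rates.base_birth_rate(ages, params)
        self.w_full = _full_weights(grid)
        self.w1, self.w2 = population_weights(grid)

    def mu(self, x: float) -> np.ndarray:
        p = self.params
        return p.g * x * self.phi_below + self.mu_b + p.mu_M * np.exp(-p.rho * min(x, 700 / p.rho))

    def B(self, x: float) -> np.ndarray:
        p = self.params
        if p.variant == "saturated":
            prey_term = p.k * p.x_hat * np.tanh(x / p.x_hat)
        else:
            prey_term = p.k * x
        return prey_term * self.phi_above - self.btilde * np.expm1(-p.zeta * x)


@dataclass
class SimState:
    """State of the discrete scheme at step ``n`` (time ``n*h``)."""

    n: int
    X: float
    U: np.ndarray
    Y1: float
    Y2: float
    h: float

    @property
    def t(self) -> float:
        return self.n * self.h


@dataclass
class Trajectory:
    """Time series of a run, with optional age-density snapshots.

    ``status`` is ``'completed'``, ``'blowup'`` (a solution component
    crossed the blow-up threshold; ``t_end`` records when), or
    ``'negative_density'``.
    """

    t: np.ndarray
    x: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    status: str = "completed"
    t_end: float = 0.0
    snapshots: dict = field(default_factory=dict)
    final_state: SimState | None = None

    def tail(self, t_from: float) -> "Trajectory":
        """The restriction to ``t >= t_from`` (series only)."""
        m = self.t >= t_from
        return Trajectory(
            t=self.t[m], x=self.x[m], y1=self.y1[m], y2=self.y2[m],
            status=self.status, t_end=self.t_end,
        )


def initialize_state(
    ic: InitialCondition, grid: AgeGrid, params: ModelParameters
) -> SimState:
    """Sample the initial profile on the grid and form the initial integrals."""
    u0 = np.asarray(ic.density(grid.ages), dtype=float)
    if np.any(u0 < 0):
        raise ValueError("initial age density must be nonnegative")
    w1, w2 = population_weights(grid)
    return SimState(
        n=0, X=float(ic.x0), U=u0, Y1=float(w1 @ u0), Y2=float(w2 @ u0), h=grid.h
    )


def _step_core(
    X: float,
    U: np.ndarray,
    Y1: float,
    Y2: float,
    tables: RateTables,
    clamp: bool,
) -> tuple[float, np.ndarray, float, float]:
    """One scheme step; returns (X', U', Y1', Y2') with Y' = trapz(U)."""
    p, h = tables.params, tables.grid.h
    if p.variant == "saturated":
        gain = p.s * p.y1_hat * np.tanh(Y1 / p.y1_hat)
    else:
        gain = p.s * Y1
    X_new = X * (1.0 + h * (p.r - p.a * X + gain - p.b * Y2))
    if clamp and X_new < 0.0:
        X_new = 0.0
    decay = 1.0 - h * tables.mu(X)
    if clamp:
        np.maximum(decay, 0.0, out=decay)
    newborn = float(tables.w_full @ (tables.B(X) * U))
    U_new = np.empty_like(U)
    U_new[1:] = U[:-1] * decay[:-1]
    U_new[0] = newborn
    # population integrals of the pre-update density (the scheme's lag)
    Y1_new = float(tables.w1 @ U)
    Y2_new = float(tables.w2 @ U)
    return X_new, U_new, Y1_new, Y2_new


def advance_step(
    state: SimState,
    grid: AgeGrid,
    params: ModelParameters,
    *,
    tables: RateTables | None = None,
    clamp: bool = False,
    lagged: bool = True,
) -> SimState:
    """Advance the scheme by one step ``h``.

    With ``lagged=True`` (default) the returned ``Y1, Y2`` are the trapezoid
    integrals of the *pre-update* density, exactly as the scheme prescribes;
    ``lagged=False`` recomputes them from the new density.
    """
    if tables is None:
        tables = RateTables(params, grid)
    X_new, U_new, Y1_new, Y2_new = _step_core(
        state.X, state.U, state.Y1, state.Y2, tables, clamp
    )
    if not lagged:
        Y1_new = float(tables.w1 @ U_new)
        Y2_new = float(tables.w2 @ U_new)
    if not clamp and (X_new < 0.0 or U_new[1:].min(initial=0.0) < 0.0):
        raise NegativeDensityError(
            f"negative prey size or density at t={(state.n + 1) * grid.h:.6g}; "
            "reduce the time step h"
        )
    return SimState(n=state.n + 1, X=X_new, U=U_new, Y1=Y1_new, Y2=Y2_new, h=grid.h)


def integrate(
    state: SimState,
    grid: AgeGrid,
    params: ModelParameters,
    T_max: float,
    *,
    blowup_threshold: float = 1000.0,
    snapshot_times: Iterable[float] = (),
    clamp: bool = False,
    lagged: bool = True,
    check_density_nodes: bool = False,
    record_every: int = 1,
) -> Trajectory:
    """Integrate to time ``T_max``, or stop early at blow-up.

    A blow-up is declared the first step any of ``X, Y1, Y2`` (and every
    density node too when ``check_density_nodes``) exceeds
    ``blowup_threshold``.  ``record_every`` thins the stored series.
    """
    tables = RateTables(params, grid)
    n_steps = grid.steps_for(T_max)
    snap_idx = {int(round(ts / grid.h)): float(ts) for ts in snapshot_times}
    ts, xs, y1s, y2s = [state.t], [state.X], [state.Y1], [state.Y2]
    snapshots: dict[float, np.ndarray] = {}
    if state.n in snap_idx:
        snapshots[snap_idx[state.n]] = state.U.copy()

    X, U, Y1, Y2 = state.X, state.U.copy(), state.Y1, state.Y2
    status, t_end = "completed", state.t + n_steps * grid.h
    n = state.n
    for i in range(n_steps):
        X, U, Y1, Y2 = _step_core(X, U, Y1, Y2, tables, clamp)
        n += 1
        t = n * grid.h
        if not clamp and (X < 0.0 or U.min() < 0.0):
            status, t_end = "negative_density", t
            break
        over = X > blowup_threshold or Y1 > blowup_threshold or Y2 > blowup_threshold
        if check_density_nodes and not over:
            over = U.max() > blowup_threshold
        if (i + 1) % record_every == 0 or over or i == n_steps - 1:
            ts.append(t)
            xs.append(X)
            y1s.append(Y1)
            y2s.append(Y2)
        if n in snap_idx:
            snapshots[snap_idx[n]] = U.copy()
        if over:
            status, t_end = "blowup", t
            break

    final = SimState(n=n, X=X, U=U, Y1=Y1, Y2=Y2, h=grid.h)
    return Trajectory(
        t=np.array(ts), x=np.array(xs), y1=np.array(y1s), y2=np.array(y2s),
        status=status, t_end=t_end, snapshots=snapshots, final_state=final,
    )


def population_sizes(U: np.ndarray, grid: AgeGrid) -> tuple[float, float]:
    """Juvenile and adult population integrals of a density on the grid."""
    w1, w2 = population_weights(grid)
    return float(w1 @ U), float(w2 @ U)


def integrate_kmre(
    u0_vals: np.ndarray,
    mu_vals: np.ndarray,
    B_vals: np.ndarray,
    h: float,
    n_steps: int,
) -> np.ndarray:
    """Integrate the plain renewal equation with prey-independent rates.

    ``mu_vals`` and ``B_vals`` are the death and birth rates sampled at the
    age nodes of ``u0_vals``.  The same shift/decay/newborn update as the
    full model, with the birth integral by the trapezoid rule.  Returns the
    density after ``n_steps`` steps.  Used as the analytically tractable
    special case of the solver.
    """
    u0_vals = np.asarray(u0_vals, dtype=float)
    K = u0_vals.size - 1
    w = np.full(K + 1, h)
    w[0] = w[-1] = 0.5 * h
    decay = 1.0 - h * np.asarray(mu_vals, dtype=float)
    U = u0_vals.copy()
    for _ in range(n_steps):
        newborn = float(w @ (np.asarray(B_vals) * U))
        U[1:] = U[:-1] * decay[:-1]
        U[0] = newborn
    return U
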