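"""Discretization bookkeeping for the age-structured solver.

Time and age share a common step ``h`` so that predator generations
propagate exactly along the characteristics ``t - tau = const`` of the
transport equation: one time step shifts the whole age density by one node.
The maturation age must sit on the grid (it splits the juvenile/adult
integrals); production grids are capped at the lifespan ``L``, while
*theory-mode* grids extend to ``tau0_max + T`` so that no density is ever
discarded (used by the convergence tests against the renewal-equation
oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgeGrid", "build_grid", "build_theory_grid", "CommensurabilityError"]


class CommensurabilityError(ValueError):
    """A requested age/time (tau_star, L, T) does not sit on the h-grid."""


def _snap(value: float, h: float, name: str, strict: bool) -> int:
    n = int(round(value / h))
    err = abs(n * h - value)
    if strict and err > 1e-6 * h:
        raise CommensurabilityError(
            f"{name}={value} is not h-commensurable with h={h} "
            f"(nearest node {n * h}, error {err:.3g})"
        )
    return n


@dataclass(frozen=True)
class AgeGrid:
    """Uniform age grid with nodes ``0, h, ..., n_max*h``.

    ``n_mature`` is the node index of the maturation age; ``capped`` marks a
    lifespan-capped grid (density advected past the last node is discarded)
    as opposed to a theory-mode grid that keeps every generation.
    """

    h: float
    n_mature: int   # index of tau_star
    n_max: int      # index of the last age node
    capped: bool = True
    snap_error: float = 0.0  # max |snapped - requested| over the snapped ages

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"step h={self.h} must be positive")
        if not 0 <= self.n_mature < self.n_max:
            raise ValueError(
                f"need 0 <= n_mature={self.n_mature} < n_max={self.n_max}"
            )

    @property
    def n_nodes(self) -> int:
        return self.n_max + 1

    @property
    def tau_star(self) -> float:
        """Maturation age as snapped to the grid."""
        return self.n_mature * self.h

    @property
    def tau_max(self) -> float:
        """Age of the last node (the lifespan cap for capped grids)."""
        return self.n_max * self.h

    @property
    def ages(self) -> np.ndarray:
        return self.h * np.arange(self.n_nodes)

    def steps_for(self, T: float) -> int:
        """Number of time steps covering the horizon ``T`` (snapped)."""
        return max(int(round(T / self.h)), 0)


def build_grid(
    h: float, tau_star: float, L: float, *, strict: bool = False
) -> AgeGrid:
    """Lifespan-capped grid: nodes ``0..N_L`` with ``N_L = round(L/h)``.

    ``strict=True`` raises :class:`CommensurabilityError` when ``tau_star``
    or ``L`` is further than ``1e-6*h`` from a node; otherwise they are
    silently snapped and the error recorded.
    """
    if not 0 < tau_star < L:
        raise ValueError(f"need 0 < tau_star={tau_star} < L={L}")
    n1 = _snap(tau_star, h, "tau_star", strict)
    nL = _snap(L, h, "L", strict)
    n1 = min(max(n1, 0), nL - 1)
    err = max(abs(n1 * h - tau_star), abs(nL * h - L))
    return AgeGrid(h=h, n_mature=n1, n_max=nL, capped=True, snap_error=err)


def build_theory_grid(
    h: float, tau_star: float, tau0_max: float, T: float, *, strict: bool = True
) -> AgeGrid:
    """Uncapped grid reaching ``tau0_max + T`` (no density discarded)."""
    n1 = _snap(tau_star, h, "tau_star", strict)
    n0 = _snap(tau0_max, h, "tau0_max", strict)
    n = _snap(T, h, "T", strict)
    err = max(
        abs(n1 * h - tau_star), abs(n0 * h - tau0_max), abs(n * h - T)
    )
    return AgeGrid(h=h, n_mature=n1, n_max=n0 + n, capped=False, snap_error=err)
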