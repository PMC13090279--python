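"""Model parameters and initial conditions for the role-reversal predator-prey model.

The model couples a logistic-type prey ODE to an age-structured predator
population governed by a renewal (transport) equation.  Fifteen biological
parameters control the prey dynamics and the predator birth/death rates; two
extra scales (``x_hat``, ``y1_hat``) appear only in the *saturated* model
variant, where the unbounded birth-rate terms are replaced by ``tanh``
saturations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "InitialCondition",
    "PARAMETER_RANGES",
    "SAMPLED_PARAMETERS",
]

#: Sampling box for the 15 biological parameters (the parameter-study ranges).
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "tau_star": (0.0, 2.0),
    "g": (0.0, 1.0),
    "nu": (1.0, 100.0),
    "r": (0.1, 0.6),
    "a": (0.005, 0.05),
    "k": (0.1, 1.0),
    "b": (0.1, 1.0),
    "s": (0.1, 1.0),
    "zeta": (5.0, 20.0),
    "mu_M": (0.5, 5.0),
    "rho": (3.0, 7.0),
    "d_p": (0.1, 1.0),
    "b_p": (0.03, 0.1),
    "b_ep": (0.05, 0.15),
    "d_ep": (0.05, 0.15),
}

#: Ordered names of the sampled parameters (the 15-D box above).
SAMPLED_PARAMETERS: tuple[str, ...] = tuple(PARAMETER_RANGES)

_POSITIVE = (
    "r", "a", "s", "b", "mu_M", "nu", "zeta", "rho",
    "d_p", "b_p", "b_ep", "d_ep", "L", "tau_star",
)
_NONNEGATIVE = ("k", "g")


@dataclass(frozen=True)
class ModelParameters:
    """The biological parameters of the age-structured role-reversal model.

    Defaults are the reference parameter set used throughout the package;
    the predator lifespan is capped at ``L`` (density advected past age L is
    discarded), ``variant`` selects the baseline or the saturated birth
    rates, and ``nu`` controls how sharply the smooth maturity indicator
    switches at the maturation age ``tau_star`` (``nu = 100`` is nearly a
    step function, ``nu = 1`` a gradual transition).
    """

    tau_star: float = 1.0    #: maturation age of the predator
    g: float = 0.2           #: consumption rate of juvenile predators by prey
    nu: float = 100.0        #: smoothness of the maturity indicator
    r: float = 0.4           #: intrinsic growth rate of prey
    a: float = 0.01          #: intraspecific competition rate of prey
    k: float = 0.3           #: reproduction rate of predator
    b: float = 0.8           #: consumption rate of prey by adult predator
    s: float = 0.2           #: prey growth from eating juvenile predators
    zeta: float = 10.0       #: birth-rate exponential factor
    mu_M: float = 1.0        #: hunger-death prefactor
    rho: float = 5.0         #: hunger-death exponential factor
    d_p: float = 0.4         #: base-death prefactor
    b_p: float = 0.05        #: base-birth prefactor
    b_ep: float = 0.1        #: base-birth exponential factor
    d_ep: float = 0.1        #: base-death exponential factor
    L: float = 30.0          #: maximal predator lifespan
    variant: str = "baseline"  #: 'baseline' or 'saturated'
    x_hat: float = 20.0      #: prey saturation scale (saturated variant)
    y1_hat: float = 10.0     #: juvenile saturation scale (saturated variant)

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name!r} must be positive, got {v}")
        for name in _NONNEGATIVE:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name!r} must be nonnegative, got {v}")
        if self.tau_star >= self.L:
            raise ValueError(
                f"maturation age tau_star={self.tau_star} must lie below "
                f"the lifespan cap L={self.L}"
            )
        if self.variant not in ("baseline", "saturated"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "saturated" and (self.x_hat <= 0 or self.y1_hat <= 0):
            raise ValueError("saturation scales x_hat, y1_hat must be positive")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float | str]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, float | str]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def sampled_values(self) -> np.ndarray:
        """The 15 sampled parameters as a vector, in ``SAMPLED_PARAMETERS`` order."""
        return np.array([getattr(self, n) for n in SAMPLED_PARAMETERS])


@dataclass(frozen=True)
class InitialCondition:
    """Initial prey size and predator age-density profile.

    ``levels``/``breaks`` describe a piecewise-constant profile: ``levels[i]``
    on ``[breaks[i], breaks[i+1])`` (the last piece includes its right
    endpoint), zero outside ``[breaks[0], breaks[-1]]``.  The default mirrors
    the reference initial state: prey at 0.5, juveniles at density 0.1 on
    ``[0, tau_star)`` and adults at 0.05 on ``[tau_star, L]``.
    """

    x0: float = 0.5
    levels: tuple[float, ...] = (0.1, 0.05)
    breaks: tuple[float, ...] = (0.0, 1.0, 30.0)
    #: boundary convention at interior breakpoints: 'left' assigns a node
    #: sitting exactly on a breakpoint to the piece on its right (half-open
    #: intervals); 'closed_left' assigns it to the piece on its left.
    convention: str = "left"

    def __post_init__(self) -> None:
        if self.x0 <= 0:
            raise ValueError(f"initial prey size x0={self.x0} must be positive")
        if len(self.breaks) != len(self.levels) + 1:
            raise ValueError("need len(breaks) == len(levels) + 1")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(v < 0 for v in self.levels):
            raise ValueError("age-density levels must be nonnegative")
        if self.convention not in ("left", "closed_left"):
            raise ValueError(f"unknown convention {self.convention!r}")

    #: optional tabulated profile (ages, values); overrides levels/breaks
    table: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    @classmethod
    def default(cls, params: ModelParameters) -> "InitialCondition":
        """The reference initial condition for the given parameters."""
        return cls(x0=0.5, levels=(0.1, 0.05), breaks=(0.0, params.tau_star, params.L))

    @classmethod
    def from_table(
        cls, ages, values, x0: float = 0.5
    ) -> "InitialCondition":
        """Profile tabulated on an age grid (linear interpolation between
        nodes, zero outside the tabulated range)."""
        ages = tuple(float(a) for a in ages)
        values = tuple(float(v) for v in values)
        if len(ages) != len(values) or len(ages) < 2:
            raise ValueError("need matching ages/values with at least 2 nodes")
        if any(v < 0 for v in values):
            raise ValueError("age-density values must be nonnegative")
        return cls(
            x0=x0, levels=(0.0,), breaks=(ages[0], ages[-1]),
            table=(ages, values),
        )

    @property
    def tau0_max(self) -> float:
        """Upper end of the support of the initial age density."""
        return self.breaks[-1]

    def density(self, tau: np.ndarray) -> np.ndarray:
        """Evaluate the initial age-density profile at the given ages."""
        tau = np.asarray(tau, dtype=float)
        if self.table is not None:
            ages, values = self.table
            out = np.interp(tau, ages, values, left=0.0, right=0.0)
            return out if out.ndim else float(out)
        side = "right" if self.convention == "left" else "left"
        idx = np.searchsorted(self.breaks, tau, side=side) - 1
        idx = np.clip(idx, 0, len(self.levels) - 1)
        out = np.asarray(self.levels, dtype=float)[idx]
        return np.where((tau < self.breaks[0]) | (tau > self.breaks[-1]), 0.0, out)
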