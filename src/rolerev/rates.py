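"""Birth, death, and growth rate functions of the role-reversal model.

The predator birth rate is ``B(x, tau) = k*x*phi_above(tau) +
Btilde(tau)*(1 - exp(-zeta*x))`` and the death rate is ``mu(x, tau) =
g*x*phi_below(tau) + mu_B(tau) + mu_M*exp(-rho*x)``, where ``phi_above`` /
``phi_below`` are logistic smoothings of the indicator of maturity
(above/below the maturation age ``tau_star``), ``Btilde`` is the base birth
rate supported on ``[tau_star, inf)`` with a sharp cutoff, and ``mu_B`` is an
age-increasing base death rate.  The prey grows logistically, gains from
eating juvenile predators and loses to adult predators.

All functions are pure and vectorized over ``tau`` (and over ``x`` where it
makes sense); scalar inputs yield scalars.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters

__all__ = [
    "smooth_indicator",
    "base_birth_rate",
    "base_death_rate",
    "birth_rate",
    "death_rate",
    "prey_growth_rate",
]

# exp argument cap: e^{±700} is the edge of double range; beyond it the
# logistic is exactly 0 or 1 to machine precision anyway.
_EXP_CAP = 700.0


def _safe_exp(z):
    return np.exp(np.clip(z, -_EXP_CAP, _EXP_CAP))


def smooth_indicator(tau, tau_star: float, nu: float, direction: str = "above"):
    """Logistic smoothing of the maturity indicator.

    ``direction='above'`` gives ``1/(1 + exp(-nu*(tau - tau_star)))``, an
    increasing sigmoid that approximates the indicator of ``tau >= tau_star``;
    ``'below'`` gives its complement.  The two versions sum to 1 exactly.
    """
    if nu <= 0:
        raise ValueError(f"indicator smoothness nu={nu} must be positive")
    tau = np.asarray(tau, dtype=float)
    if direction == "above":
        z = -nu * (tau - tau_star)
    elif direction == "below":
        z = nu * (tau - tau_star)
    else:
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    out = 1.0 / (1.0 + _safe_exp(z))
    return out if out.ndim else float(out)


def base_birth_rate(tau, params: ModelParameters):
    """Base (prey-independent) predator birth rate ``Btilde(tau)``.

    Zero below the maturation age (juveniles cannot reproduce), then
    ``b_p*(exp(-b_ep*(tau - tau_star)) + 1)``, which decays from ``2*b_p`` at
    maturation toward ``b_p`` in old age.  The cutoff at ``tau_star`` is
    sharp by construction, independently of the smoothness ``nu``.
    """
    tau = np.asarray(tau, dtype=float)
    val = params.b_p * (_safe_exp(-params.b_ep * (tau - params.tau_star)) + 1.0)
    out = np.where(tau < params.tau_star, 0.0, val)
    return out if out.ndim else float(out)


def base_death_rate(tau, params: ModelParameters):
    """Base predator death rate ``mu_B(tau) = d_p*exp(d_ep*(tau - L))``.

    Strictly positive and increasing with age; equals ``d_p`` at the
    lifespan cap ``L``.
    """
    tau = np.asarray(tau, dtype=float)
    out = params.d_p * _safe_exp(params.d_ep * (tau - params.L))
    return out if out.ndim else float(out)


def birth_rate(x, tau, params: ModelParameters):
    """Predator birth rate ``B(x, tau)``; vanishes at ``x = 0``.

    The ``k*x`` term is gated by the smooth maturity indicator; in the
    saturated variant it is replaced by ``k*x_hat*tanh(x/x_hat)``, bounded by
    ``k*x_hat``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("prey size x must be nonnegative")
    phi = smooth_indicator(tau, params.tau_star, params.nu, "above")
    if params.variant == "saturated":
        prey_term = params.k * params.x_hat * np.tanh(x / params.x_hat)
    else:
        prey_term = params.k * x
    out = prey_term * phi + base_birth_rate(tau, params) * (-np.expm1(-params.zeta * x))
    return out if np.ndim(out) else float(out)


def death_rate(x, tau, params: ModelParameters):
    """Predator death rate ``mu(x, tau)``: predation on juveniles by prey,
    age-related death, and hunger (which relaxes as prey become abundant)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("prey size x must be nonnegative")
    phi = smooth_indicator(tau, params.tau_star, params.nu, "below")
    out = (
        params.g * x * phi
        + base_death_rate(tau, params)
        + params.mu_M * _safe_exp(-params.rho * x)
    )
    return out if np.ndim(out) else float(out)


def prey_growth_rate(x, y1, y2, params: ModelParameters):
    """Right-hand side of the prey ODE.

    Baseline: ``x*(r - a*x + s*y1 - b*y2)``.  Saturated variant: the
    juvenile-feeding gain saturates as ``s*y1_hat*tanh(y1/y1_hat)``.
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if np.any(x < 0) or np.any(y1 < 0) or np.any(y2 < 0):
        raise ValueError("state components must be nonnegative")
    if params.variant == "saturated":
        gain = params.s * params.y1_hat * np.tanh(y1 / params.y1_hat)
    else:
        gain = params.s * y1
    out = x * (params.r - params.a * x + gain - params.b * y2)
    return out if np.ndim(out) else float(out)
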