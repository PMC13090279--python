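"""Minimal diagram renderers (matplotlib is an optional dependency)."""

from __future__ import annotations

import numpy as np

from .solver import Trajectory
from .studies import ATTRACTOR_LABELS, PhaseDiagram

__all__ = ["plot_trajectory", "plot_phase_diagram"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trajectory(traj: Trajectory, ax=None):
    """Prey and predator population sizes against time."""
    ax = _axes(ax)
    ax.plot(traj.t, traj.x, label="x (prey)")
    ax.plot(traj.t, traj.y1, label="y1 (juveniles)")
    ax.plot(traj.t, traj.y2, label="y2 (adults)")
    ax.set_xlabel("time")
    ax.set_ylabel("population size")
    ax.legend(frameon=False)
    return ax


def plot_phase_diagram(diagram: PhaseDiagram, ax=None):
    """Attractor label per (tau_star, g) cell as a colored grid."""
    ax = _axes(ax)
    codes = {lab: i for i, lab in enumerate(ATTRACTOR_LABELS)}
    img = np.vectorize(lambda s: codes.get(s, -1))(diagram.labels)
    extent = (
        diagram.g_grid[0], diagram.g_grid[-1],
        diagram.tau_grid[0], diagram.tau_grid[-1],
    )
    im = ax.imshow(
        img, origin="lower", aspect="auto", extent=extent,
        vmin=-1, vmax=len(ATTRACTOR_LABELS) - 1, cmap="viridis",
    )
    ax.set_xlabel("g (juvenile consumption by prey)")
    ax.set_ylabel("tau* (maturation age)")
    ax.set_title(f"attractor type ({diagram.model})")
    return ax, im
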