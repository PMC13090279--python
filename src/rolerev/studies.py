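"""Parameter studies: Latin-hypercube ensembles, attractor classification,
linear discriminant analysis, and phase/bifurcation diagrams.

The long-term behavior of the model falls into four classes: blow-up (a
solution component crosses a threshold in finite time), the predator-free
attractor (predators die out, prey at carrying capacity), equilibrial
coexistence (a stable steady state with both species present), and
periodic coexistence (a stable limit cycle).  A Latin-hypercube sample of
the 15-dimensional parameter box maps out how often each class occurs;
Fisher linear discriminant analysis of the labelled samples ranks which
parameters drive the outcome; and dense sweeps in the two dominant
parameters (maturation age ``tau_star`` and juvenile-consumption rate
``g``) give phase diagrams, computed either by the full
equilibrium/stability pipeline or by a cheap tail-amplitude test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import attractors
from .ensemble import EnsembleDiagnostics, simulate_ensemble
from .grid import AgeGrid, build_grid
from .params import InitialCondition, ModelParameters, PARAMETER_RANGES, SAMPLED_PARAMETERS
from .reduced import age_averaged_parameters, integrate_reduced, AveragedParameters
from .solver import Trajectory, initialize_state, integrate

__all__ = [
    "ATTRACTOR_LABELS",
    "LHSDesign",
    "LDAResult",
    "PhaseDiagram",
    "latin_hypercube",
    "classify_attractor",
    "classify_diagnostics",
    "ensemble_summary",
    "run_lhs_study",
    "fisher_lda",
    "phase_diagram",
    "compare_phase_diagrams",
    "bifurcation_branches",
]

ATTRACTOR_LABELS = (
    "blowup",
    "predator_free",
    "equilibrial_coexistence",
    "periodic_coexistence",
)

#: terminal predator population below which the predator counts as extinct
EXTINCTION_THRESHOLD = 1e-6
#: relative prey oscillation amplitude over the tail window separating
#: periodic from equilibrial coexistence
AMPLITUDE_THRESHOLD = 1e-3


@dataclass
class LHSDesign:
    """A stratified (Latin-hypercube) sample of a parameter box."""

    names: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    samples: pd.DataFrame
    seed: int

    @property
    def n(self) -> int:
        return len(self.samples)


def latin_hypercube(
    ranges: dict[str, tuple[float, float]] | None = None,
    n: int = 100,
    seed: int = 0,
) -> LHSDesign:
    """Latin-hypercube design: per column, exactly one sample per bin
    ``[lo + j*(hi-lo)/n, lo + (j+1)*(hi-lo)/n)``, columns independently
    permuted; reproducible under a fixed seed."""
    if ranges is None:
        ranges = dict(PARAMETER_RANGES)
    if n < 1:
        raise ValueError("need n >= 1")
    names = tuple(ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    lo = np.array([ranges[k][0] for k in names])
    hi = np.array([ranges[k][1] for k in names])
    table = pd.DataFrame(qmc.scale(unit, lo, hi), columns=list(names))
    return LHSDesign(names=names, ranges=dict(ranges), samples=table, seed=seed)


def classify_attractor(
    trajectory: Trajectory,
    *,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    tail_from: float = 400.0,
) -> str:
    """Label a single trajectory.

    Early termination by the blow-up threshold wins; otherwise a terminal
    predator population below ``extinction_threshold`` means predator-free;
    the remaining coexistence runs are split by the relative oscillation
    amplitude of the prey over the tail window.
    """
    if trajectory.status == "blowup":
        return "blowup"
    y_end = float(trajectory.y1[-1] + trajectory.y2[-1])
    if y_end < extinction_threshold:
        return "predator_free"
    tail = trajectory.tail(tail_from)
    if tail.t.size < 2:
        raise ValueError("trajectory too short for the tail window")
    amp = float(tail.x.max() - tail.x.min())
    mean = float(tail.x.mean())
    if amp > amplitude_threshold * max(mean, 1e-12):
        return "periodic_coexistence"
    return "equilibrial_coexistence"


def classify_diagnostics(
    diag: EnsembleDiagnostics,
    *,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
) -> np.ndarray:
    """Vectorized classification of ensemble diagnostics (same rules)."""
    n = diag.blew_up.size
    labels = np.full(n, "equilibrial_coexistence", dtype=object)
    amp = diag.tail_x_max - diag.tail_x_min
    periodic = amp > amplitude_threshold * np.maximum(diag.tail_x_mean, 1e-12)
    labels[periodic] = "periodic_coexistence"
    labels[diag.final_y < extinction_threshold] = "predator_free"
    labels[diag.blew_up] = "blowup"
    return labels


def ensemble_summary(labels: np.ndarray) -> pd.DataFrame:
    """Counts and fractions per attractor class (fractions sum to one)."""
    labels = np.asarray(labels, dtype=object)
    counts = {lab: int((labels == lab).sum()) for lab in ATTRACTOR_LABELS}
    total = labels.size
    return pd.DataFrame(
        {
            "count": pd.Series(counts),
            "fraction": pd.Series({k: v / total for k, v in counts.items()}),
        }
    )


def run_lhs_study(
    n: int = 10_000,
    seed: int | tuple[int, ...] = 0,
    *,
    h: float = 0.005,
    T_max: float = 500.0,
    variant: str = "baseline",
    blowup_threshold: float = 1000.0,
    batch_size: int = 1000,
) -> tuple[LHSDesign, pd.DataFrame]:
    """Full ensemble pipeline: design, integrate, classify.

    Returns the design and a result table (the 15 parameters, the label,
    the diagnostics, and the replicate seed, one row per sample).  Passing
    a tuple of seeds runs independent replicate designs of ``n`` samples
    each and pools the rows (class fractions are then computed over the
    pooled table).
    """
    seeds = (seed,) if isinstance(seed, int) else tuple(seed)
    designs, frames = [], []
    for s in seeds:
        design = latin_hypercube(PARAMETER_RANGES, n=n, seed=s)
        diag = simulate_ensemble(
            design.samples, h=h, T_max=T_max, variant=variant,
            blowup_threshold=blowup_threshold, batch_size=batch_size,
        )
        results = design.samples.copy()
        results["label"] = classify_diagnostics(diag)
        for col, val in vars(diag).items():
            results[col] = val
        results["seed"] = s
        designs.append(design)
        frames.append(results)
    return designs[0], pd.concat(frames, ignore_index=True)


@dataclass
class LDAResult:
    """Fisher LDA of labelled parameter sets.

    ``W`` holds the orthonormalized discriminant directions (columns);
    ``loadings`` are the range-adjusted directions ``R @ W`` (``R`` diagonal
    with the per-parameter range widths), which make coordinates with wide
    sampling ranges and coordinates with narrow ones comparable;
    ``projections`` are the samples projected onto the discriminant plane.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    projections: np.ndarray
    class_means: pd.DataFrame
    names: tuple[str, ...]

    def ranking(self, component: int = 0) -> pd.Series:
        """Parameters ordered by |range-adjusted loading| on a component."""
        s = pd.Series(np.abs(self.loadings[:, component]), index=list(self.names))
        return s.sort_values(ascending=False)


def fisher_lda(
    sample_table: pd.DataFrame,
    labels: np.ndarray,
    n_components: int = 2,
    *,
    ranges: dict[str, tuple[float, float]] | None = None,
    ridge: float = 1e-10,
) -> LDAResult:
    """Multiclass Fisher LDA via the generalized eigenproblem
    ``Sb w = lambda Sw w``.

    ``Sb`` is the between-class scatter ``sum_i n_i (mu_i - mu)(mu_i -
    mu)^T`` and ``Sw`` the pooled within-class scatter.  The dominant
    eigenvectors are orthonormalized by one Gram-Schmidt pass.  A singular
    ``Sw`` is ridge-regularized.  With ``c`` classes at most ``c - 1``
    eigenvalues are nonzero.
    """
    X = np.asarray(sample_table, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes for LDA")
    n, d = X.shape
    mu = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    means = {}
    for c in classes:
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        means[c] = mc
        Xc0 = Xc - mc
        Sw += Xc0.T @ Xc0
        dm = (mc - mu)[:, None]
        Sb += len(Xc) * (dm @ dm.T)

    from scipy.linalg import eigh

    reg = ridge * np.trace(Sw) / d
    for _ in range(2):
        try:
            vals, vecs = eigh(Sb, Sw + reg * np.eye(d))
            break
        except np.linalg.LinAlgError:
            reg = max(reg * 1e6, 1e-8 * np.trace(Sw) / d)
    order = np.argsort(vals)[::-1]
    W = vecs[:, order[:n_components]].copy()
    eigenvalues = vals[order[:n_components]]

    # one Gram-Schmidt pass (generalized eigenvectors are not orthogonal)
    for j in range(W.shape[1]):
        for i in range(j):
            W[:, j] -= (W[:, i] @ W[:, j]) * W[:, i]
        W[:, j] /= np.linalg.norm(W[:, j])

    names = tuple(sample_table.columns)
    if ranges is None:
        widths = X.max(axis=0) - X.min(axis=0)
    else:
        widths = np.array([ranges[k][1] - ranges[k][0] for k in names])
    loadings = widths[:, None] * W
    class_means = pd.DataFrame(means, index=list(names)).T
    return LDAResult(
        W=W, eigenvalues=eigenvalues, loadings=loadings,
        projections=X @ W, class_means=class_means, names=names,
    )


@dataclass
class PhaseDiagram:
    """Attractor label per cell of a (tau_star, g) sweep."""

    tau_grid: np.ndarray
    g_grid: np.ndarray
    labels: np.ndarray          # (len(tau_grid), len(g_grid)) of label strings
    model: str
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def area_fraction(self, label: str) -> float:
        return float((self.labels == label).mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ts in enumerate(self.tau_grid):
            for j, g in enumerate(self.g_grid):
                rows.append({"tau_star": ts, "g": g, "label": self.labels[i, j]})
        return pd.DataFrame(rows)


def _phase_initial_condition(p: ModelParameters) -> InitialCondition:
    # sweep convention: density 0.1 up to and including the maturation age
    return InitialCondition(
        x0=0.5, levels=(0.1, 0.05), breaks=(0.0, p.tau_star, p.L),
        convention="closed_left",
    )


def _pde_cell(
    p: ModelParameters,
    h: float,
    T: float,
    warm: attractors.EquilibriumResult | None,
    *,
    newton_tol: float = 1e-10,
) -> tuple[str, attractors.EquilibriumResult | None, Trajectory, "AgeGrid"]:
    """Classify one (tau_star, g) cell of the age-structured model.

    Integrate from the sweep initial condition; extinction means
    predator-free, otherwise Newton (warm-started by the final state or the
    neighbouring cell's equilibrium) plus the map spectrum decides
    equilibrial vs periodic.  If Newton fails the tail-amplitude rule is
    the fallback and the cell is flagged in the records.
    """
    grid = build_grid(h, p.tau_star, p.L)
    state = initialize_state(_phase_initial_condition(p), grid, p)
    traj = integrate(state, grid, p, T, record_every=5)
    if traj.status == "negative_density":
        # the step is too large for this cell's death rates: halve and redo
        if h > 0.004:
            return _pde_cell(p, h / 2.0, T, None, newton_tol=newton_tol)
        return "blowup:flagged", None, traj, grid
    if traj.status == "blowup":
        return "blowup", None, traj, grid
    # extinction test over the tail window: large-amplitude cycles park the
    # predator at astronomically low densities for long stretches, so the
    # terminal value alone would declare false extinctions
    tail = traj.t >= T - 100.0
    if float((traj.y1[tail] + traj.y2[tail]).max()) < EXTINCTION_THRESHOLD:
        return "predator_free", None, traj, grid

    starts = []
    if warm is not None and warm.U_star.size == grid.n_nodes:
        starts.append((warm.X_star, warm.U_star))
    starts.append((traj.final_state.X, traj.final_state.U))
    starts.extend(attractors.coexistence_guesses(p, grid))
    eq = None
    for X0, U0 in starts:
        cand = attractors.newton_equilibrium(
            X0, U0, grid, p, tol=newton_tol, compute_stability=True
        )
        if cand.converged and cand.y1 + cand.y2 > EXTINCTION_THRESHOLD:
            eq = cand
            break
    if eq is None:
        label = classify_attractor(traj, tail_from=max(0.0, T - 100.0))
        return label + ":flagged", None, traj, grid
    label = "equilibrial_coexistence" if eq.stable else "periodic_coexistence"
    return label, eq, traj, grid


def phase_diagram(
    tau_grid,
    g_grid,
    params: ModelParameters | None = None,
    *,
    h: float = 0.0125,
    T: float = 500.0,
    model: str = "pde",
) -> PhaseDiagram:
    """Phase diagram of the age-structured model over a (tau_star, g) grid.

    Rows sweep ``tau_star``; within a row ``g`` is traversed in decreasing
    order with the previous cell's equilibrium as the Newton warm start
    (continuation).
    """
    if params is None:
        params = ModelParameters()
    tau_grid = np.asarray(tau_grid, float)
    g_grid = np.asarray(g_grid, float)
    labels = np.empty((tau_grid.size, g_grid.size), dtype=object)
    rows = []
    order = np.argsort(g_grid)[::-1]  # continuation in decreasing g
    for i, ts in enumerate(tau_grid):
        warm = None
        for j in order:
            p = params.replace(tau_star=float(ts), g=float(g_grid[j]))
            label, eq, _, _ = _pde_cell(p, h, T, warm)
            flagged = label.endswith(":flagged")
            label = label.removesuffix(":flagged")
            labels[i, j] = label
            if eq is not None:
                warm = eq
            rows.append(
                {
                    "tau_star": float(ts), "g": float(g_grid[j]), "label": label,
                    "flagged": flagged,
                    "X_star": eq.X_star if eq else np.nan,
                    "y1": eq.y1 if eq else np.nan,
                    "y2": eq.y2 if eq else np.nan,
                    "spectral_radius": (
                        eq.stability.spectral_radius if eq and eq.stability else np.nan
                    ),
                }
            )
    return PhaseDiagram(
        tau_grid=tau_grid, g_grid=g_grid, labels=labels, model=model,
        records=pd.DataFrame(rows),
    )


def _reduced_cell(
    model: str,
    p: ModelParameters,
    avg: AveragedParameters,
    T: float,
) -> str:
    """Classify one cell for a reduced model with given averaged parameters."""
    y1_0 = 0.1 * p.tau_star
    y2_0 = 0.05 * (p.L - p.tau_star)
    traj = integrate_reduced(model, (0.5, y1_0, y2_0), p, avg, T)
    if traj.status == "blowup":
        return "blowup"
    tail = traj.t >= traj.t[-1] - 100.0
    if float((traj.y1[tail] + traj.y2[tail]).max()) < EXTINCTION_THRESHOLD:
        return "predator_free"
    if model == "ode":
        z = (traj.x[-1], traj.y1[-1], traj.y2[-1])
        _, stable, _ = attractors.ode_equilibrium(z, p, avg)
        return "equilibrial_coexistence" if stable else "periodic_coexistence"
    return classify_attractor(traj, tail_from=max(0.0, T - 100.0))


def compare_phase_diagrams(
    tau_grid,
    g_grid,
    params: ModelParameters | None = None,
    *,
    h_pde: float = 0.025,
    T: float = 500.0,
) -> dict[str, PhaseDiagram]:
    """Phase diagrams of the age-structured, ODE, and DDE models on a
    common grid.

    Per coexistence cell the age-structured equilibrium (sharp indicator,
    ``nu = 100``) supplies the age-averaged parameters that the two reduced
    models then use, so all three describe the same biology.  Cells that
    are predator-free in the age-structured model are not run for the
    reduced models (no averaged parameters exist there) and keep the
    predator-free label.
    """
    if params is None:
        params = ModelParameters()
    params = params.replace(nu=100.0)
    tau_grid = np.asarray(tau_grid, float)
    g_grid = np.asarray(g_grid, float)
    shape = (tau_grid.size, g_grid.size)
    labels = {m: np.empty(shape, dtype=object) for m in ("pde", "ode", "dde")}
    rows = []
    order = np.argsort(g_grid)[::-1]
    for i, ts in enumerate(tau_grid):
        warm = None
        for j in order:
            p = params.replace(tau_star=float(ts), g=float(g_grid[j]))
            label, eq, _, cell_grid = _pde_cell(p, h_pde, T, warm)
            label = label.removesuffix(":flagged")
            labels["pde"][i, j] = label
            row = {"tau_star": float(ts), "g": float(g_grid[j]), "pde": label}
            if eq is not None:
                warm = eq
                avg = age_averaged_parameters(eq.U_star, eq.X_star, cell_grid, p)
                for m in ("ode", "dde"):
                    labels[m][i, j] = _reduced_cell(m, p, avg, T)
                    row[m] = labels[m][i, j]
                for k, v in avg.to_dict().items():
                    row[k] = v
            else:
                for m in ("ode", "dde"):
                    labels[m][i, j] = label
                    row[m] = label
            rows.append(row)
    records = pd.DataFrame(rows)
    return {
        m: PhaseDiagram(
            tau_grid=tau_grid, g_grid=g_grid, labels=labels[m], model=m,
            records=records,
        )
        for m in ("pde", "ode", "dde")
    }


def bifurcation_branches(
    sweep_values,
    params: ModelParameters | None = None,
    *,
    sweep_parameter: str = "g",
    h: float = 0.0125,
    T: float = 500.0,
    compute_cycles: bool = True,
) -> pd.DataFrame:
    """Equilibrium branch (with stability) along a one-parameter sweep;
    where the equilibrium is unstable, the limit-cycle min/max per variable.

    The sweep proceeds in decreasing parameter order with warm-start
    continuation, matching the phase-diagram pipeline.
    """
    if params is None:
        params = ModelParameters()
    sweep_values = np.asarray(sweep_values, float)
    order = np.argsort(sweep_values)[::-1]
    rows = [None] * sweep_values.size
    warm = None
    for j in order:
        p = params.replace(**{sweep_parameter: float(sweep_values[j])})
        label, eq, traj, cell_grid = _pde_cell(p, h, T, warm)
        label = label.removesuffix(":flagged")
        row = {
            sweep_parameter: float(sweep_values[j]), "label": label,
            "x_eq": np.nan, "y1_eq": np.nan, "y2_eq": np.nan, "stable": np.nan,
        }
        for var in ("x", "y1", "y2"):
            row[f"{var}_cycle_min"] = np.nan
            row[f"{var}_cycle_max"] = np.nan
        if eq is not None:
            warm = eq
            row.update(
                x_eq=eq.X_star, y1_eq=eq.y1, y2_eq=eq.y2, stable=eq.stable
            )
            if not eq.stable and compute_cycles:
                cyc = attractors.find_limit_cycle(
                    traj.final_state.U, eq.X_star, cell_grid, p, tol=1e-12
                )
                for var, (lo, hi) in cyc.extrema.items():
                    row[f"{var}_cycle_min"] = lo
                    row[f"{var}_cycle_max"] = hi
                row["period"] = cyc.period
        rows[j] = row
    return pd.DataFrame(rows)
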