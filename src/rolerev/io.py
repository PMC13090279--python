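"""Columnar-text result serialization.

Every file starts with ``#``-prefixed header lines recording the package
version, the full parameter set, and any extra run metadata (seed, step,
...), so a run is reproducible from its output header alone.  Data follow
as tab-separated columns readable with ``pandas.read_csv(...,
sep="\\t", comment="#")``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParameters
from .solver import Trajectory
from .studies import PhaseDiagram

__all__ = [
    "write_trajectory",
    "write_density",
    "read_density",
    "write_phase_diagram",
    "read_phase_diagram",
    "write_table",
    "read_table",
]


def _header(params: ModelParameters | None, extra: dict | None) -> str:
    from . import __version__

    lines = [f"# rolerev {__version__}"]
    if params is not None:
        items = " ".join(f"{k}={v}" for k, v in params.to_dict().items())
        lines.append(f"# params: {items}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _write(path: str | Path, frame: pd.DataFrame, params, extra) -> None:
    path = Path(path)
    try:
        with path.open("w") as fh:
            fh.write(_header(params, extra))
            frame.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    except OSError as err:
        raise OSError(f"cannot write results to {path}: {err}") from err


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    *,
    params: ModelParameters | None = None,
    extra: dict | None = None,
) -> None:
    """Write any result table with the standard reproducibility header."""
    _write(path, frame, params, extra)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    *,
    params: ModelParameters | None = None,
    extra: dict | None = None,
) -> None:
    """Time series as (time, x, y1, y2); snapshots go to a sibling file
    ``<stem>_density<suffix>`` in (time, age, density) long format."""
    frame = pd.DataFrame({"time": traj.t, "x": traj.x, "y1": traj.y1, "y2": traj.y2})
    meta = {"status": traj.status, "t_end": traj.t_end}
    meta.update(extra or {})
    _write(path, frame, params, meta)
    if traj.snapshots:
        path = Path(path)
        rows = []
        for t, U in sorted(traj.snapshots.items()):
            # age spacing equals the time step of the scheme
            h = traj.final_state.h if traj.final_state else 1.0
            ages = np.arange(U.size) * h
            rows.append(pd.DataFrame({"time": t, "age": ages, "density": U}))
        dens = pd.concat(rows, ignore_index=True)
        _write(path.with_name(path.stem + "_density" + path.suffix), dens, params, meta)


def write_density(
    U: np.ndarray,
    h: float,
    path: str | Path,
    *,
    params: ModelParameters | None = None,
    extra: dict | None = None,
) -> None:
    """An age-density profile as (age, density) columns."""
    frame = pd.DataFrame({"age": h * np.arange(np.size(U)), "density": np.asarray(U)})
    _write(path, frame, params, extra)


def read_density(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an (age, density) file; returns (density, step)."""
    frame = read_table(path)
    ages = frame["age"].to_numpy()
    h = float(ages[1] - ages[0]) if ages.size > 1 else 1.0
    return frame["density"].to_numpy(), h


def write_phase_diagram(
    diagram: PhaseDiagram,
    path: str | Path,
    *,
    params: ModelParameters | None = None,
    extra: dict | None = None,
) -> None:
    frame = diagram.records if len(diagram.records) else diagram.to_frame()
    meta = {"model": diagram.model}
    meta.update(extra or {})
    _write(path, frame, params, meta)


def read_phase_diagram(path: str | Path, model: str = "pde") -> PhaseDiagram:
    """Rebuild the label grid from a written phase-diagram file."""
    frame = read_table(path)
    tau_grid = np.unique(frame["tau_star"].to_numpy())
    g_grid = np.unique(frame["g"].to_numpy())
    col = "label" if "label" in frame.columns else model
    labels = np.empty((tau_grid.size, g_grid.size), dtype=object)
    for _, row in frame.iterrows():
        i = int(np.argmin(np.abs(tau_grid - row["tau_star"])))
        j = int(np.argmin(np.abs(g_grid - row["g"])))
        labels[i, j] = row[col]
    return PhaseDiagram(
        tau_grid=tau_grid, g_grid=g_grid, labels=labels, model=model, records=frame
    )
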