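"""Recording and rendering of simulation output.

Rate traces are written as plain-text files, one ``time activity`` line
per reporting interval.  Density snapshots are written one file per
recorded time, with the per-cell probability masses in linear-index order
(row-major, ``j * n_v + i``) so a snapshot reloads to the exact in-memory
state.  Marginal distributions over each state variable are exact column
and row sums of the mass grid.
"""

from __future__ import annotations

import hashlib
import logging
import os
from pathlib import Path

import numpy as np

from .grid import ConfigurationError, FileFormatError, StateGrid
from .network import RunResult

logger = logging.getLogger("popgrid")


def _grid_hash(grid: StateGrid) -> str:
    key = (f"{grid.v_min!r} {grid.v_max!r} {grid.h_min!r} {grid.h_max!r} "
           f"{grid.n_v} {grid.n_h}")
    return hashlib.sha1(key.encode()).hexdigest()[:12]


def record_rate(times, values, path: str | os.PathLike) -> None:
    """Write a rate (or AvgV) trace: one ``time<TAB>activity`` line each."""
    with open(path, "w") as fh:
        for t, v in zip(times, values):
            fh.write(f"{t:.9g}\t{v:.9g}\n")


def load_rate(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.empty(0), np.empty(0)
    return data[:, 0], data[:, 1]


def density_filename(node: str, t: float) -> str:
    return f"{node}_{t:.9g}.density"


def record_density(mass: np.ndarray, grid: StateGrid, t: float,
                   path: str | os.PathLike) -> None:
    """Write one density snapshot (cell masses in linear-index order)."""
    with open(path, "w") as fh:
        fh.write(f"# time {t:.9g}\n")
        fh.write(f"# grid {grid.n_v} {grid.n_h} {_grid_hash(grid)}\n")
        for m in mass:
            fh.write(f"{m:.17g}\n")


def load_density(path: str | os.PathLike,
                 grid: StateGrid | None = None) -> tuple[float, np.ndarray]:
    """Read a snapshot back; optionally verify it belongs to ``grid``."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2 or not lines[0].startswith("# time"):
        raise FileFormatError(f"{path}: not a density snapshot")
    t = float(lines[0].split()[2])
    header = lines[1].split()
    if grid is not None and header[4] != _grid_hash(grid):
        raise FileFormatError(f"{path}: snapshot belongs to a different grid")
    mass = np.array([float(x) for x in lines[2:] if x.strip()])
    return t, mass


def write_run_output(result: RunResult, out_dir: str | os.PathLike) -> None:
    """Write all recorded rates and densities of a run to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for node, trace in result.rates.items():
        record_rate(trace.times, trace.values, out / f"{node}.rate")
    for node, snapshots in result.densities.items():
        pop = result.network.nodes[node]
        for t, mass in snapshots:
            record_density(mass, pop.grid, t,
                           out / density_filename(node, t))
    (out / "simulation.log").write_text("\n".join(result.log) + "\n")


def marginals(mass: np.ndarray, grid: StateGrid,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Exact marginal distributions over v (columns) and h (rows).

    Each marginal sums to the total in-grid mass (refractory mass is held
    outside the grid and does not appear).
    """
    m = np.asarray(mass).reshape(grid.n_h, grid.n_v)
    return m.sum(axis=0), m.sum(axis=1)


def render_density_heatmap(mass: np.ndarray, grid: StateGrid,
                           path: str | os.PathLike,
                           title: str = "") -> None:
    """Render the density as a heat map normalised to the maximum value."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    m = np.asarray(mass, dtype=float).reshape(grid.n_h, grid.n_v)
    peak = m.max()
    if peak <= 0:
        logger.warning("all-zero density: rendering a uniform image")
        img = np.zeros_like(m)
    else:
        img = m / peak
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        img, origin="lower", aspect="auto", cmap="inferno", vmin=0, vmax=1,
        extent=(grid.v_min, grid.v_max, grid.h_min, grid.h_max))
    ax.set_xlabel("v")
    ax.set_ylabel("h")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="density / max density")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_marginals(mass: np.ndarray, grid: StateGrid,
                     path: str | os.PathLike, title: str = "") -> None:
    """Plot both marginal densities side by side."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    marg_v, marg_h = marginals(mass, grid)
    centers_v = grid.v_min + (np.arange(grid.n_v) + 0.5) * grid.cell_width
    centers_h = grid.h_min + (np.arange(grid.n_h) + 0.5) * grid.cell_height
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(centers_v, marg_v / grid.cell_width)
    ax1.set_xlabel("v")
    ax1.set_ylabel("density")
    ax2.plot(centers_h, marg_h / grid.cell_height)
    ax2.set_xlabel("h")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_rate_plot(times, values, path: str | os.PathLike,
                     ylabel: str = "firing rate (Hz)") -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(times, values)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
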