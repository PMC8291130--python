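"""Regular state-space grids and geometric transition matrices.

State space is discretised into ``n_h`` rows by ``n_v`` columns of identical
axis-aligned rectangular cells.  The deterministic (noise-free) dynamics of
a neuron model are pre-solved into a sparse stochastic *transition matrix*:
every cell's four vertices are advanced by one Euler time step, and the
resulting quadrilateral is recursively triangulated against the grid lines
of the untransformed grid until each triangle lies inside a single cell.
The per-cell triangle areas, divided by the quadrilateral area, give the
proportion of probability mass the source cell sends to each target cell.

Cells use half-open intervals ``[low, high)`` in both dimensions; a point
exactly on the upper grid bound belongs to the last cell.  Mass mapped
below the lower grid bounds is pinned at the boundary cell; mass mapped
above the upper bounds wraps around to the lower bound.  Both situations
indicate an undersized grid and are logged as warnings, since the resulting
dynamics at the boundary are not meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from .models import NeuronModel, euler_step

logger = logging.getLogger("popgrid")

#: points closer than this to a grid line are snapped onto it
SNAP = 1e-12
#: transition fractions below this are dropped and the row renormalised
FRACTION_FLOOR = 1e-12
#: tolerance on per-source-row mass conservation
ROW_SUM_TOL = 1e-9


class ConfigurationError(ValueError):
    """A structurally invalid grid, model, network or simulation setting."""


class DegenerateCellError(ValueError):
    """A transformed cell collapsed to (near) zero area."""


class FileFormatError(ValueError):
    """A .model or .tmat file that cannot be parsed or fails validation."""


# ---------------------------------------------------------------------------
# StateGrid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateGrid:
    """A rectangular discretisation of 2D state space.

    Cell ``(i, j)`` (column i along v, row j along h, both 0-based from the
    lower bounds) spans
    ``[v_min + i*cell_width, v_min + (i+1)*cell_width) x
    [h_min + j*cell_height, h_min + (j+1)*cell_height)``
    and has linear index ``j * n_v + i``.
    """

    v_min: float
    v_max: float
    h_min: float
    h_max: float
    n_v: int
    n_h: int

    def __post_init__(self) -> None:
        if not (self.v_min < self.v_max and self.h_min < self.h_max):
            raise ConfigurationError(
                f"grid bounds must be ordered: v=({self.v_min}, {self.v_max}),"
                f" h=({self.h_min}, {self.h_max})"
            )
        if self.n_v < 1 or self.n_h < 1:
            raise ConfigurationError(
                f"grid resolution must be positive, got {self.n_v}x{self.n_h}"
            )

    @property
    def cell_width(self) -> float:
        return (self.v_max - self.v_min) / self.n_v

    @property
    def cell_height(self) -> float:
        return (self.h_max - self.h_min) / self.n_h

    @property
    def n_cells(self) -> int:
        return self.n_v * self.n_h

    # -- indexing ----------------------------------------------------------

    def linear_index(self, i: int, j: int) -> int:
        return j * self.n_v + i

    def cell_coords(self, linear: int) -> tuple[int, int]:
        return linear % self.n_v, linear // self.n_v

    def column_of(self, v: float) -> int:
        """Raw (unclamped) column index of coordinate v; may be out of range.

        A coordinate exactly on ``v_max`` belongs to the last column.
        """
        if v == self.v_max:
            return self.n_v - 1
        return math.floor((v - self.v_min) / self.cell_width)

    def row_of(self, h: float) -> int:
        if h == self.h_max:
            return self.n_h - 1
        return math.floor((h - self.h_min) / self.cell_height)

    def resolve(self, i: int, j: int) -> tuple[int, int, bool]:
        """Apply the boundary policy to a raw index pair.

        Below the lower bound the index is pinned to 0; above the upper
        bound it wraps around.  Returns (i, j, clipped_or_wrapped).
        """
        touched = False
        if i < 0:
            i, touched = 0, True
        elif i >= self.n_v:
            i, touched = i % self.n_v, True
        if j < 0:
            j, touched = 0, True
        elif j >= self.n_h:
            j, touched = j % self.n_h, True
        return i, j, touched

    def cell_of_point(self, v: float, h: float) -> int:
        """Linear index of the cell containing (v, h), boundary policy applied."""
        i, j, _ = self.resolve(self.column_of(v), self.row_of(h))
        return self.linear_index(i, j)

    # -- geometry ----------------------------------------------------------

    def cell_vertices(self, i: int, j: int) -> np.ndarray:
        """The four corners of cell (i, j), counter-clockwise from lower-left."""
        x0 = self.v_min + i * self.cell_width
        x1 = self.v_min + (i + 1) * self.cell_width
        y0 = self.h_min + j * self.cell_height
        y1 = self.h_min + (j + 1) * self.cell_height
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])

    def cell_center(self, linear: int) -> tuple[float, float]:
        i, j = self.cell_coords(linear)
        return (self.v_min + (i + 0.5) * self.cell_width,
                self.h_min + (j + 0.5) * self.cell_height)

    def cell_centers_v(self) -> np.ndarray:
        """Centre v-coordinate of every cell, in linear-index order."""
        centers = self.v_min + (np.arange(self.n_v) + 0.5) * self.cell_width
        return np.tile(centers, self.n_h)


def build_grid(bounds: Sequence[float], resolution: Sequence[int]) -> StateGrid:
    """Construct a grid from (v_min, v_max, h_min, h_max) and (n_v, n_h)."""
    v_min, v_max, h_min, h_max = (float(b) for b in bounds)
    n_v, n_h = int(resolution[0]), int(resolution[1])
    return StateGrid(v_min, v_max, h_min, h_max, n_v, n_h)


# ---------------------------------------------------------------------------
# TransitionMatrix
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """A sparse stochastic map of mass proportions between grid cells.

    ``matrix`` is stored target-by-source (CSR), so that advancing a density
    column vector ``rho`` is ``matrix @ rho``.  Every source column sums
    to 1 within ``ROW_SUM_TOL``.
    """

    matrix: sp.csr_matrix
    dt: float
    kind: str  # "deterministic" | "jump"

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def apply(self, mass: np.ndarray) -> np.ndarray:
        return self.matrix @ mass

    def row_fractions(self, source: int) -> list[tuple[int, float]]:
        """The (target, proportion) outflow list of one source cell."""
        col = self.matrix.getcol(source).tocoo()
        return sorted(zip(col.row.tolist(), col.data.tolist()))

    def entries(self) -> Iterator[tuple[int, int, float]]:
        """Iterate (source, target, proportion) over all nonzero entries."""
        coo = self.matrix.tocoo()
        order = np.lexsort((coo.row, coo.col))
        for k in order:
            yield int(coo.col[k]), int(coo.row[k]), float(coo.data[k])

    def validate(self) -> None:
        sums = np.asarray(self.matrix.sum(axis=0)).ravel()
        bad = np.where(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            raise FileFormatError(
                f"transition matrix row {bad[0]} sums to {sums[bad[0]]!r}, "
                "expected 1"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise FileFormatError("transition matrix has a negative entry")


def _assemble(entries_src: np.ndarray, entries_tgt: np.ndarray,
              entries_p: np.ndarray, n_cells: int, dt: float,
              kind: str) -> TransitionMatrix:
    """Build a validated CSR matrix, dropping sliver fractions and
    renormalising each source row."""
    m = sp.coo_matrix(
        (entries_p, (entries_tgt, entries_src)), shape=(n_cells, n_cells)
    ).tocsr()
    m.sum_duplicates()
    m.data[m.data < FRACTION_FLOOR] = 0.0
    m.eliminate_zeros()
    col_sums = np.asarray(m.sum(axis=0)).ravel()
    if np.any(col_sums <= 0):
        missing = int(np.where(col_sums <= 0)[0][0])
        raise DegenerateCellError(
            f"source cell {missing} has no outgoing mass after assembly"
        )
    scale = sp.diags(1.0 / col_sums)
    m = (m @ scale).tocsr()
    tm = TransitionMatrix(matrix=m, dt=dt, kind=kind)
    tm.validate()
    return tm


# ---------------------------------------------------------------------------
# Cell transformation
# ---------------------------------------------------------------------------

def transform_cell(model: NeuronModel, grid: StateGrid,
                   cell: int | tuple[int, int],
                   substeps: int = 1) -> np.ndarray:
    """Translate the four vertices of a cell by one model time step.

    Returns the transformed quadrilateral (4x2 array, same vertex order as
    :meth:`StateGrid.cell_vertices`).  The quadrilateral need not be
    rectangular or convex.
    """
    if isinstance(cell, tuple):
        i, j = cell
    else:
        i, j = grid.cell_coords(cell)
    if not (0 <= i < grid.n_v and 0 <= j < grid.n_h):
        raise ConfigurationError(f"cell ({i}, {j}) outside grid")
    verts = grid.cell_vertices(i, j)
    out = np.empty_like(verts)
    for k, (v, h) in enumerate(verts):
        try:
            out[k] = euler_step(model, (v, h), model.timestep, substeps)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"model {model.name!r} blew up at cell ({i}, {j}), "
                f"vertex ({v!r}, {h!r})"
            ) from exc
    return out


def _transform_all_vertices(model: NeuronModel, grid: StateGrid,
                            substeps: int) -> tuple[np.ndarray, np.ndarray]:
    """Euler-step every grid vertex, vectorised when the field allows it.

    Returns (V, H) arrays of shape (n_h + 1, n_v + 1).
    """
    xs = grid.v_min + np.arange(grid.n_v + 1) * grid.cell_width
    ys = grid.h_min + np.arange(grid.n_h + 1) * grid.cell_height
    V, H = np.meshgrid(xs, ys)
    dt = model.timestep / substeps
    Vc, Hc = V.copy(), H.copy()
    try:
        with np.errstate(all="ignore"):
            for _ in range(substeps):
                dv, dw = model.vector_field((Vc, Hc), 0.0)
                dv = np.broadcast_to(np.asarray(dv, dtype=float), Vc.shape)
                dw = np.broadcast_to(np.asarray(dw, dtype=float), Hc.shape)
                Vc = Vc + dt * model.timescale * dv
                Hc = Hc + dt * model.timescale * dw
        return Vc, Hc
    except Exception:
        # vector field not array-capable: fall back to per-vertex stepping
        out_v = np.empty_like(V)
        out_h = np.empty_like(H)
        for j in range(V.shape[0]):
            for i in range(V.shape[1]):
                out_v[j, i], out_h[j, i] = euler_step(
                    model, (V[j, i], H[j, i]), model.timestep, substeps)
        return out_v, out_h


# ---------------------------------------------------------------------------
# Recursive triangulation of a transformed cell against the grid
# ---------------------------------------------------------------------------

def _tri_area(ax, ay, bx, by, cx, cy) -> float:
    return abs((bx - ax) * (cy - ay) - (cx - ax) * (by - ay)) * 0.5


def _clip_poly(poly: list[tuple[float, float]], axis: int, c: float,
               keep_le: bool) -> list[tuple[float, float]]:
    """Sutherland-Hodgman clip of a convex polygon against an axis line.

    ``axis`` 0 clips on x, 1 on y; keeps the side <= c (or >= c).
    Points within SNAP of the line count as on it (kept by both sides).
    """
    out: list[tuple[float, float]] = []
    n = len(poly)
    for k in range(n):
        p, q = poly[k], poly[(k + 1) % n]
        dp = p[axis] - c
        dq = q[axis] - c
        if not keep_le:
            dp, dq = -dp, -dq
        p_in = dp <= SNAP
        q_in = dq <= SNAP
        if p_in:
            out.append(p)
        if p_in != q_in:
            t = dp / (dp - dq)
            if axis == 0:
                out.append((c, p[1] + t * (q[1] - p[1])))
            else:
                out.append((p[0] + t * (q[0] - p[0]), c))
    return out


def _fan_triangles(poly: list[tuple[float, float]]):
    for k in range(1, len(poly) - 1):
        yield (poly[0], poly[k], poly[k + 1])


class _Overlap:
    """Accumulates per-cell triangle areas for one transformed cell."""

    __slots__ = ("grid", "areas", "eps")

    def __init__(self, grid: StateGrid, quad_area: float):
        self.grid = grid
        self.areas: dict[tuple[int, int], float] = {}
        # slivers smaller than this carry no meaningful mass
        self.eps = quad_area * 1e-14

    def add_triangle(self, tri, depth: int = 0) -> None:
        (ax, ay), (bx, by), (cx, cy) = tri
        if _tri_area(ax, ay, bx, by, cx, cy) <= self.eps:
            return
        if depth > 200:
            raise RecursionError("triangulation failed to terminate")
        g = self.grid
        # look for a vertical grid line strictly inside the x-extent
        xmin, xmax = min(ax, bx, cx), max(ax, bx, cx)
        k_lo = math.floor((xmin - g.v_min) / g.cell_width) + 1
        line = g.v_min + k_lo * g.cell_width
        if line < xmax - SNAP and line > xmin + SNAP:
            poly = [tri[0], tri[1], tri[2]]
            for part in (_clip_poly(poly, 0, line, True),
                         _clip_poly(poly, 0, line, False)):
                if len(part) >= 3:
                    for sub in _fan_triangles(part):
                        self.add_triangle(sub, depth + 1)
            return
        # then a horizontal line inside the y-extent
        ymin, ymax = min(ay, by, cy), max(ay, by, cy)
        k_lo = math.floor((ymin - g.h_min) / g.cell_height) + 1
        line = g.h_min + k_lo * g.cell_height
        if line < ymax - SNAP and line > ymin + SNAP:
            poly = [tri[0], tri[1], tri[2]]
            for part in (_clip_poly(poly, 1, line, True),
                         _clip_poly(poly, 1, line, False)):
                if len(part) >= 3:
                    for sub in _fan_triangles(part):
                        self.add_triangle(sub, depth + 1)
            return
        # triangle lies inside a single cell: bin it by its centroid
        cx3 = (ax + bx + cx) / 3.0
        cy3 = (ay + by + cy) / 3.0
        key = (g.column_of(cx3), g.row_of(cy3))
        self.areas[key] = self.areas.get(key, 0.0) + _tri_area(
            ax, ay, bx, by, cx, cy)


def overlap_fractions(quad: np.ndarray, grid: StateGrid,
                      ) -> list[tuple[int, float]]:
    """Exact area fractions of a transformed cell over the original grid.

    The quadrilateral is split into two triangles along a diagonal (signed
    areas taken absolute, which also handles non-convex and twisted quads)
    and each triangle is recursively subdivided at its intersections with
    grid lines until every piece lies in a single cell.  Fractions are
    (overlap area) / (quad area); the boundary policy maps out-of-grid
    pieces back inside, so the returned fractions sum to 1.

    Returns (linear cell index, fraction) pairs sorted by index.
    """
    q = np.asarray(quad, dtype=float)
    tris = [(tuple(q[0]), tuple(q[1]), tuple(q[2])),
            (tuple(q[0]), tuple(q[2]), tuple(q[3]))]
    total = sum(_tri_area(a[0], a[1], b[0], b[1], c[0], c[1])
                for a, b, c in tris)
    cell_area = grid.cell_width * grid.cell_height
    if total < 1e-12 * cell_area:
        raise DegenerateCellError(
            f"transformed cell has near-zero area {total!r} "
            f"(vertices {q.tolist()})"
        )
    acc = _Overlap(grid, total)
    for tri in tris:
        acc.add_triangle(tri)
    out: dict[int, float] = {}
    touched = False
    for (i, j), area in acc.areas.items():
        i2, j2, t = grid.resolve(i, j)
        touched = touched or t
        lin = grid.linear_index(i2, j2)
        out[lin] = out.get(lin, 0.0) + area / total
    if touched:
        logger.warning(
            "transformed cell extends outside the grid; mass pinned/wrapped "
            "at the boundary (results there are not meaningful)"
        )
    return sorted(out.items())


# ---------------------------------------------------------------------------
# Deterministic transition matrix
# ---------------------------------------------------------------------------

def generate_deterministic_matrix(model: NeuronModel, grid: StateGrid,
                                  substeps: int = 1) -> TransitionMatrix:
    """Pre-solve one noise-free time step of ``model`` over ``grid``.

    Translates every cell by one Euler step of duration ``model.timestep``
    and measures its exact area overlap with the untransformed grid.  Each
    source cell is processed independently, so the result does not depend
    on traversal order.  Rows (source cells) sum to 1 after the boundary
    policy; fractions below ``FRACTION_FLOOR`` are dropped and the row
    renormalised.
    """
    Vt, Ht = _transform_all_vertices(model, grid, substeps)
    if not (np.all(np.isfinite(Vt)) and np.all(np.isfinite(Ht))):
        bad = np.argwhere(~(np.isfinite(Vt) & np.isfinite(Ht)))[0]
        j, i = int(bad[0]), int(bad[1])
        raise FloatingPointError(
            f"model {model.name!r} produced a non-finite state near cell "
            f"({min(i, grid.n_v - 1)}, {min(j, grid.n_h - 1)}) at vertex "
            f"({grid.v_min + i * grid.cell_width!r}, "
            f"{grid.h_min + j * grid.cell_height!r})"
        )
    if model.tolerance is not None:
        xs = grid.v_min + np.arange(grid.n_v + 1) * grid.cell_width
        ys = grid.h_min + np.arange(grid.n_h + 1) * grid.cell_height
        V0, H0 = np.meshgrid(xs, ys)
        disp = np.hypot(Vt - V0, Ht - H0)
        if disp.max() > model.tolerance:
            logger.warning(
                "model %s: max per-step displacement %.3g exceeds "
                "tolerance %.3g during matrix generation",
                model.name, disp.max(), model.tolerance,
            )
    src: list[int] = []
    tgt: list[int] = []
    val: list[float] = []
    n_warn = logging.getLogger("popgrid")
    with _suppress_boundary_spam():
        for j in range(grid.n_h):
            for i in range(grid.n_v):
                quad = np.array([
                    [Vt[j, i], Ht[j, i]],
                    [Vt[j, i + 1], Ht[j, i + 1]],
                    [Vt[j + 1, i + 1], Ht[j + 1, i + 1]],
                    [Vt[j + 1, i], Ht[j + 1, i]],
                ])
                try:
                    fracs = overlap_fractions(quad, grid)
                except DegenerateCellError as exc:
                    raise DegenerateCellError(
                        f"cell ({i}, {j}): {exc}") from exc
                s = grid.linear_index(i, j)
                for t, f in fracs:
                    src.append(s)
                    tgt.append(t)
                    val.append(f)
    return _assemble(np.array(src), np.array(tgt), np.array(val),
                     grid.n_cells, model.timestep, "deterministic")


class _suppress_boundary_spam:
    """Collapse repeated boundary warnings during matrix generation."""

    def __enter__(self):
        self._filter = _OnceFilter()
        logger.addFilter(self._filter)
        return self

    def __exit__(self, *exc):
        logger.removeFilter(self._filter)
        return False


class _OnceFilter(logging.Filter):
    def __init__(self):
        super().__init__()
        self.seen: set[str] = set()

    def filter(self, record: logging.LogRecord) -> bool:
        key = record.msg
        if key in self.seen:
            return False
        self.seen.add(key)
        return True


# ---------------------------------------------------------------------------
# File dialects (.model / .tmat)
# ---------------------------------------------------------------------------

_MODEL_MAGIC = "popgrid-model v1"
_TMAT_MAGIC = "popgrid-tmat v1"


def write_model_file(grid: StateGrid, model: NeuronModel, path,
                     reset_mapping: Sequence[tuple[int, int]] | None = None,
                     ) -> None:
    """Write the grid geometry and model parameters as a .model file.

    The dialect is a versioned plain-text header of ``key value`` lines,
    optionally followed by a serialized reset mapping (threshold cell ->
    reset cell pairs).  The vector field itself is code and is not stored.
    """
    lines = [
        _MODEL_MAGIC,
        f"name {model.name}",
        f"bounds {grid.v_min!r} {grid.v_max!r} {grid.h_min!r} {grid.h_max!r}",
        f"resolution {grid.n_v} {grid.n_h}",
        f"dt {model.timestep!r}",
        f"timescale {model.timescale!r}",
        f"threshold_v {model.threshold_v!r}",
        f"reset_v {model.reset_v!r}",
        f"reset_shift_h {model.reset_shift_h!r}",
        f"refractory_period {model.refractory_period!r}",
        f"efficacy_orientation {model.efficacy_orientation}",
    ]
    if reset_mapping is not None:
        lines.append(f"reset_mapping {len(reset_mapping)}")
        for thr, rst in reset_mapping:
            lines.append(f"{thr} {rst}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ModelFileInfo:
    """The parameter record read back from a .model file."""

    name: str
    grid: StateGrid
    dt: float
    timescale: float
    threshold_v: float
    reset_v: float
    reset_shift_h: float
    refractory_period: float
    efficacy_orientation: str
    reset_mapping: tuple[tuple[int, int], ...] | None = None


def read_model_file(path) -> ModelFileInfo:
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw or raw[0].strip() != _MODEL_MAGIC:
        raise FileFormatError(f"{path}: line 1: expected {_MODEL_MAGIC!r}")
    fields: dict[str, list[str]] = {}
    mapping: list[tuple[int, int]] | None = None
    it = enumerate(raw[1:], start=2)
    for lineno, line in it:
        parts = line.split()
        if not parts:
            continue
        key, vals = parts[0], parts[1:]
        if key == "reset_mapping":
            try:
                count = int(vals[0])
            except (IndexError, ValueError):
                raise FileFormatError(
                    f"{path}: line {lineno}: bad reset_mapping count")
            mapping = []
            for _ in range(count):
                lineno, line = next(it)
                a, b = line.split()
                mapping.append((int(a), int(b)))
            continue
        fields[key] = vals
    try:
        bounds = [float(x) for x in fields["bounds"]]
        n_v, n_h = (int(x) for x in fields["resolution"])
        info = ModelFileInfo(
            name=fields["name"][0],
            grid=StateGrid(bounds[0], bounds[1], bounds[2], bounds[3],
                           n_v, n_h),
            dt=float(fields["dt"][0]),
            timescale=float(fields["timescale"][0]),
            threshold_v=float(fields["threshold_v"][0]),
            reset_v=float(fields["reset_v"][0]),
            reset_shift_h=float(fields["reset_shift_h"][0]),
            refractory_period=float(fields["refractory_period"][0]),
            efficacy_orientation=fields["efficacy_orientation"][0],
            reset_mapping=tuple(mapping) if mapping is not None else None,
        )
    except (KeyError, IndexError, ValueError) as exc:
        raise FileFormatError(f"{path}: missing or malformed field: {exc}")
    return info


def write_tmat(matrix: TransitionMatrix, path) -> None:
    """Write a transition matrix as a plain-text .tmat file.

    One line per nonzero entry, ``source target proportion``, proportions
    at 17 significant digits so the round trip is bit-exact.
    """
    with open(path, "w") as fh:
        fh.write(_TMAT_MAGIC + "\n")
        fh.write(f"dt {matrix.dt!r}\n")
        fh.write(f"kind {matrix.kind}\n")
        fh.write(f"cells {matrix.n_cells}\n")
        for s, t, p in matrix.entries():
            fh.write(f"{s} {t} {p:.17g}\n")


def read_tmat(path) -> TransitionMatrix:
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw or raw[0].strip() != _TMAT_MAGIC:
        raise FileFormatError(f"{path}: line 1: expected {_TMAT_MAGIC!r}")
    header: dict[str, str] = {}
    entries_start = None
    for lineno, line in enumerate(raw[1:4], start=2):
        parts = line.split()
        if len(parts) != 2:
            raise FileFormatError(f"{path}: line {lineno}: malformed header")
        header[parts[0]] = parts[1]
    try:
        dt = float(header["dt"])
        kind = header["kind"]
        n_cells = int(header["cells"])
    except (KeyError, ValueError) as exc:
        raise FileFormatError(f"{path}: malformed header: {exc}")
    src, tgt, val = [], [], []
    for lineno, line in enumerate(raw[4:], start=5):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FileFormatError(
                f"{path}: line {lineno}: expected 'source target proportion'")
        try:
            s, t, p = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError:
            raise FileFormatError(f"{path}: line {lineno}: malformed entry")
        if p < 0:
            raise FileFormatError(
                f"{path}: line {lineno}: negative proportion {p!r}")
        src.append(s)
        tgt.append(t)
        val.append(p)
    m = sp.coo_matrix((val, (tgt, src)), shape=(n_cells, n_cells)).tocsr()
    tm = TransitionMatrix(matrix=m, dt=dt, kind=kind)
    tm.validate()
    return tm


def generate_grid_files(
    func,
    timestep: float,
    basename: str,
    threshold_v: float,
    reset_v: float,
    grid_v_min: float,
    grid_v_max: float,
    grid_h_min: float,
    grid_h_max: float,
    grid_v_res: int,
    grid_h_res: int,
    timescale: float = 1.0,
    tolerance: float | None = None,
    reset_shift_h: float = 0.0,
    efficacy_orientation: str = "v",
    refractory_period: float = 0.0,
    substeps: int = 1,
) -> tuple[StateGrid, TransitionMatrix]:
    """Generate the ``basename.model`` / ``basename.tmat`` artefact pair.

    ``func(y, t)`` is the neuron model function returning the derivatives
    of the two state variables.  The grid geometry, threshold/reset
    parameters and the pre-solved deterministic transition matrix are
    written next to each other so a simulation description can reference
    them.  Returns the grid and matrix for immediate use.
    """
    model = NeuronModel(
        name=basename,
        vector_field=func,
        timestep=timestep,
        timescale=timescale,
        threshold_v=threshold_v,
        reset_v=reset_v,
        reset_shift_h=reset_shift_h,
        refractory_period=refractory_period,
        efficacy_orientation=efficacy_orientation,
        tolerance=tolerance,
    )
    grid = build_grid((grid_v_min, grid_v_max, grid_h_min, grid_h_max),
                      (grid_v_res, grid_h_res))
    matrix = generate_deterministic_matrix(model, grid, substeps)
    write_model_file(grid, model, f"{basename}.model")
    write_tmat(matrix, f"{basename}.tmat")
    return grid, matrix


def check_compatible(info: ModelFileInfo, tmat: TransitionMatrix) -> None:
    """Raise if a .model record and a .tmat matrix cannot be used together."""
    if tmat.n_cells != info.grid.n_cells:
        raise FileFormatError(
            f"tmat has {tmat.n_cells} cells but model grid has "
            f"{info.grid.n_cells}"
        )
    if not math.isclose(tmat.dt, info.dt, rel_tol=1e-12):
        raise FileFormatError(
            f"tmat dt {tmat.dt!r} does not match model dt {info.dt!r}"
        )
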