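"""Threshold-reset dynamics with refractory mass queues.

Mass that the deterministic or stochastic step leaves in a *threshold cell*
(any cell whose column lies at or beyond the column containing the
threshold potential) represents neurons that fired.  Each threshold cell
owns a queue: fired mass is pushed onto the queue head, shifted one slot
per step, and finally re-injected into the mapped *reset cell* — the cell
in the column containing the reset potential, in the same row shifted by
``reset_shift_h``.

Because the refractory period need not be an integer multiple of the time
step, delivery is split by linear interpolation between the final two queue
places: a packet pushed at step ``t`` delivers ``(1 - alpha)`` of its mass
at step ``t + L`` and ``alpha`` at step ``t + L + 1``, where
``n = refractory_period / dt``, ``alpha = n - floor(n)`` and
``L = max(ceil(n), 1)``.  An integer-multiple refractory period therefore
arrives in a single step, and a zero refractory period re-injects mass on
the very next step.

The total fired mass per step, divided by the time step, is the population
firing rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .grid import ConfigurationError, StateGrid
from .master import DensityState
from .models import NeuronModel

#: snap tolerance when deciding whether a period is an exact multiple of dt
_PHASE_SNAP = 1e-9


@dataclass(frozen=True)
class ResetMapping:
    """Pre-calculated threshold-cell -> reset-cell pairs.

    ``threshold_cells`` are the linear indices of all cells on or above the
    threshold column; ``pairs[k]`` maps ``threshold_cells[k]`` to its reset
    cell.
    """

    threshold_cells: np.ndarray
    reset_cells: np.ndarray
    threshold_column: int
    reset_column: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.threshold_cells.tolist(),
                        self.reset_cells.tolist()))


def build_reset_mapping(grid: StateGrid, model: NeuronModel) -> ResetMapping:
    """Map every threshold cell to its reset cell.

    The threshold cells cover all columns whose lower v-edge is at or above
    the lower edge of the column containing ``threshold_v`` — mass jumped
    far past threshold by a large efficacy is captured too.  The reset cell
    lies in the column containing ``reset_v``, in the source row displaced
    by ``round(reset_shift_h / cell_height)`` rows; a displaced row outside
    the grid is pinned at the nearest edge row.
    """
    if not (grid.v_min <= model.reset_v <= grid.v_max):
        raise ConfigurationError(
            f"reset_v ({model.reset_v}) outside grid v-range "
            f"[{grid.v_min}, {grid.v_max}]"
        )
    if not (grid.v_min <= model.threshold_v <= grid.v_max):
        raise ConfigurationError(
            f"threshold_v ({model.threshold_v}) outside grid v-range "
            f"[{grid.v_min}, {grid.v_max}]"
        )
    thr_col = grid.column_of(model.threshold_v)
    reset_col = grid.column_of(model.reset_v)
    row_shift = round(model.reset_shift_h / grid.cell_height)
    thr_cells = []
    rst_cells = []
    for j in range(grid.n_h):
        j_target = min(max(j + row_shift, 0), grid.n_h - 1)
        for i in range(thr_col, grid.n_v):
            thr_cells.append(grid.linear_index(i, j))
            rst_cells.append(grid.linear_index(reset_col, j_target))
    return ResetMapping(
        threshold_cells=np.array(thr_cells, dtype=int),
        reset_cells=np.array(rst_cells, dtype=int),
        threshold_column=thr_col,
        reset_column=reset_col,
    )


def _queue_shape(refractory_period: float, dt: float) -> tuple[int, float]:
    """Active queue length L and interpolation weight alpha."""
    n = refractory_period / dt
    k = math.floor(n + _PHASE_SNAP)
    alpha = n - k
    if alpha < _PHASE_SNAP:
        alpha = 0.0
    length = max(k, 1) if alpha == 0.0 else k + 1
    return length, alpha


@dataclass
class RefractoryQueues:
    """Per-threshold-cell mass queues implementing the refractory hold.

    ``slots`` has one row per threshold cell and ``L + 1`` columns: L
    active places plus the final place holding the interpolation remainder
    that is delivered one step later.
    """

    slots: np.ndarray
    length: int
    alpha: float

    @classmethod
    def for_model(cls, mapping: ResetMapping, refractory_period: float,
                  dt: float) -> "RefractoryQueues":
        if dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {dt}")
        if refractory_period < 0:
            raise ConfigurationError("refractory_period must be >= 0")
        length, alpha = _queue_shape(refractory_period, dt)
        slots = np.zeros((len(mapping.threshold_cells), length + 1))
        return cls(slots=slots, length=length, alpha=alpha)

    def total(self) -> float:
        return float(self.slots.sum())

    def copy(self) -> "RefractoryQueues":
        return RefractoryQueues(self.slots.copy(), self.length, self.alpha)


def step_reset(
    state: DensityState,
    mapping: ResetMapping,
    queues: RefractoryQueues,
    dt: float,
) -> tuple[DensityState, float]:
    """Advance the refractory queues one step and harvest threshold mass.

    In order: (1) the queues shift one place, delivering the interpolated
    portion of the oldest mass to the mapped reset cells; (2) all mass
    currently in threshold cells is removed and pushed onto the queue
    heads.  The removed total is the fired mass of this step.  Queues are
    mutated in place; a new :class:`DensityState` is returned with the
    updated cell masses (same time stamp — the reset is part of the
    enclosing simulation step).
    """
    if queues.slots.shape[0] != len(mapping.threshold_cells):
        raise ConfigurationError("queues do not match the reset mapping")
    mass = state.mass.astype(float, copy=True)
    q = queues.slots
    L, alpha = queues.length, queues.alpha
    delivered = q[:, L] + (1.0 - alpha) * q[:, L - 1]
    residual = alpha * q[:, L - 1]
    # shift one place along the queue (the oldest active place was consumed)
    if L > 1:
        q[:, 1:L] = q[:, 0:L - 1].copy()
    q[:, L] = residual
    q[:, 0] = 0.0
    np.add.at(mass, mapping.reset_cells, delivered)
    # harvest threshold mass and push onto the queue heads
    fired_each = mass[mapping.threshold_cells]
    fired = float(fired_each.sum())
    q[:, 0] = fired_each
    mass[mapping.threshold_cells] = 0.0
    return replace(state, mass=mass, queues=queues), fired


def firing_rate(fired_mass: float, dt: float) -> float:
    """Population firing rate in Hz from the fired mass of one step."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not (-1e-12 <= fired_mass <= 1.0 + 1e-12):
        raise ValueError(f"fired_mass must be in [0, 1], got {fired_mass}")
    return max(fired_mass, 0.0) / dt
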