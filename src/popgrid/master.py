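"""Poisson shot-noise master equation over a state-space grid.

Incoming spikes are Poisson events that displace a neuron instantaneously
by a fixed *efficacy* ``h`` in one state variable.  On a regular grid the
resulting single-spike transition is identical for every cell: mass moves
to at most two target cells, offset ``k = floor(|h|/s) * sign(h)`` and
``k + sign(h)`` (``s`` the cell size along the jump direction), with
proportions ``1 - f`` and ``f`` where ``f = |h|/s - floor(|h|/s)``.

Given jump matrices ``M_k`` and Poisson rates ``lambda_k`` for each input,
the density obeys the master equation

    d rho / dt = sum_k lambda_k (M_k - I) rho

which is integrated with a fixed number of forward-Euler substeps per
simulation step.  All inputs are combined into a single generator, so the
result does not depend on the order in which connections are listed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import scipy.sparse as sp

from .grid import StateGrid, TransitionMatrix, _assemble

logger = logging.getLogger("popgrid")

#: mass tolerance: |negative| below this is clamped, above is a hard error
NEGATIVE_MASS_TOL = 1e-12

#: default number of Euler substeps per simulation step
DEFAULT_MASTER_STEPS = 10


class MasterBlowUpError(FloatingPointError):
    """The Euler integration of the master equation produced significant
    negative mass; raise ``master_steps`` (or reduce the time step)."""


@dataclass(frozen=True)
class JumpSpec:
    """A single-spike state-space jump: signed efficacy and its direction.

    ``orientation`` is ``"v"`` for a jump in the first state variable
    (membrane potential) or ``"h"`` for the second (e.g. conductance).
    """

    efficacy: float
    orientation: str = "v"

    def __post_init__(self) -> None:
        if not math.isfinite(self.efficacy):
            raise ValueError(f"efficacy must be finite, got {self.efficacy}")
        if self.orientation not in ("v", "h"):
            raise ValueError(
                f"orientation must be 'v' or 'h', got {self.orientation!r}")


@dataclass
class DensityState:
    """Probability mass per grid cell, plus held (refractory) mass.

    ``mass`` is indexed linearly (row-major, ``j * n_v + i``).  ``queues``
    is attached by the threshold-reset machinery; its contents count toward
    the global mass balance, so ``total()`` is 1 at all times.
    """

    mass: np.ndarray
    time: float = 0.0
    queues: Any = None  # RefractoryQueues, attached by threshold_reset

    def total(self) -> float:
        t = float(self.mass.sum())
        if self.queues is not None:
            t += self.queues.total()
        return t


def delta_density(grid: StateGrid, v: float, w: float) -> DensityState:
    """All mass (1.0) in the single cell containing state (v, w)."""
    mass = np.zeros(grid.n_cells)
    mass[grid.cell_of_point(v, w)] = 1.0
    return DensityState(mass=mass)


def build_jump_matrix(grid: StateGrid, jump: JumpSpec) -> TransitionMatrix:
    """The transition matrix of a single incoming spike.

    Every source cell shares the same two-target split; only boundary cells
    differ, where the out-of-grid target is pinned (below) or wrapped
    (above) per the grid's boundary policy.
    """
    h = jump.efficacy
    if h == 0.0:
        return TransitionMatrix(
            matrix=sp.identity(grid.n_cells, format="csr"),
            dt=0.0, kind="jump")
    s = grid.cell_width if jump.orientation == "v" else grid.cell_height
    steps = abs(h) / s
    sign = 1 if h > 0 else -1
    k = math.floor(steps) * sign
    f = steps - math.floor(steps)

    if jump.orientation == "v":
        n_along, n_across = grid.n_v, grid.n_h
    else:
        n_along, n_across = grid.n_h, grid.n_v

    idx = np.arange(n_along)
    src_list, tgt_list, val_list = [], [], []
    touched = False
    for offset, weight in ((k, 1.0 - f), (k + sign, f)):
        if weight <= 0.0:
            continue
        raw = idx + offset
        resolved = raw.copy()
        below = raw < 0
        above = raw >= n_along
        resolved[below] = 0
        resolved[above] = raw[above] % n_along
        touched = touched or bool(below.any() or above.any())
        src_list.append(idx)
        tgt_list.append(resolved)
        val_list.append(np.full(n_along, weight))
    if touched:
        logger.warning(
            "jump of %g exceeds the grid along %s near a boundary; mass "
            "pinned/wrapped there", h, jump.orientation)

    src1 = np.concatenate(src_list)
    tgt1 = np.concatenate(tgt_list)
    val1 = np.concatenate(val_list)
    # replicate the 1D transition across the other dimension
    other = np.arange(n_across)
    if jump.orientation == "v":
        src = (other[:, None] * grid.n_v + src1[None, :]).ravel()
        tgt = (other[:, None] * grid.n_v + tgt1[None, :]).ravel()
    else:
        src = (src1[:, None] * grid.n_v + other[None, :]).ravel()
        tgt = (tgt1[:, None] * grid.n_v + other[None, :]).ravel()
    val = np.repeat(val1, n_across) if jump.orientation == "h" else \
        np.tile(val1, n_across)
    return _assemble(src, tgt, val, grid.n_cells, 0.0, "jump")


def apply_master_process(
    state: DensityState,
    inputs: Sequence[tuple[float, TransitionMatrix]],
    dt: float,
    master_steps: int = DEFAULT_MASTER_STEPS,
) -> DensityState:
    """Integrate the Poisson master equation over one simulation step.

    ``inputs`` is a list of (Poisson rate in Hz, jump matrix) pairs; all are
    combined into one generator and advanced with ``master_steps`` Euler
    substeps of ``dt / master_steps``.  Total mass is conserved; tiny
    negative excursions (< 1e-12) are clamped and the mass renormalised,
    larger ones raise :class:`MasterBlowUpError`.
    """
    if master_steps < 1:
        raise ValueError("master_steps must be >= 1")
    if any(rate < 0 for rate, _ in inputs):
        raise ValueError("Poisson input rates must be >= 0")
    active = [(rate, tm) for rate, tm in inputs if rate > 0]
    rho = state.mass.astype(float, copy=True)
    if active:
        total0 = rho.sum()
        sub = dt / master_steps
        for _ in range(master_steps):
            delta = np.zeros_like(rho)
            for rate, tm in active:
                delta += rate * (tm.matrix @ rho - rho)
            rho += sub * delta
            mn = rho.min()
            if mn < 0.0:
                if mn < -NEGATIVE_MASS_TOL:
                    raise MasterBlowUpError(
                        f"negative probability mass ({mn:.3e}) during master "
                        f"integration; increase master_steps (currently "
                        f"{master_steps}) or reduce the time step"
                    )
                np.clip(rho, 0.0, None, out=rho)
        tot = rho.sum()
        if tot > 0 and total0 > 0:
            rho *= total0 / tot
    return replace(state, mass=rho, time=state.time + dt)
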