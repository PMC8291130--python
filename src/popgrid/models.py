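"""Point-neuron models as 2D vector fields.

A population is simulated over the state space of a single neuron.  The
neuron's noise-free dynamics are a two-dimensional autonomous dynamical
system ``d(v, w)/dt = F(v, w)``; one-dimensional models (LIF, QIF) are
embedded in 2D with an inert second coordinate.  The vector field is
declared as a plain Python function ``f(y, t)`` of a state pair ``y`` and a
placeholder time argument, the convention familiar from ``scipy.integrate``.

The archive ships the standard models used throughout the package:

``lif``
    Leaky integrate-and-fire, ``F(v) = -v`` (dimensionless, tau = 1 s).
``qif``
    Quadratic integrate-and-fire, ``F(v) = v**2 + I``.
``cond2d``
    Conductance-based LIF with membrane potential ``V`` (mV) and an
    excitatory conductance variable ``g_e``:
    ``tau dV/dt = -g_l (V - E_l) - g_e V``,  ``tau_e dg_e/dt = -g_e``,
    with ``E_l = -65 mV``, ``tau = 20 ms``, ``tau_e = 5 ms``, threshold
    ``-55 mV`` and reset ``-65 mV``.  Incoming spikes kick ``g_e``
    (``efficacy_orientation = "h"``).
``fitzhugh_nagumo``
    ``dV/dt = V - V^3/3 - W``, ``dW/dt = 0.08 (V + 0.7 - 0.8 W)``;
    no effective threshold-reset (threshold parked at the grid edge).
``izhikevich``
    The Izhikevich simple model (mV/ms time base),
    ``dv/dt = 0.04 v^2 + 5 v + 140 - u``, ``du/dt = a (b v - u)``.
``adex``
    Adaptive exponential integrate-and-fire (Brette-Gerstner parameters,
    pF/nS/mV/pA unit system).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("popgrid")

VectorField = Callable[[Sequence[float], float], Sequence[float]]


@dataclass(frozen=True)
class NeuronModel:
    """A 2D point-neuron model plus its threshold-reset parameters.

    ``vector_field(y, t)`` returns the time derivatives of the two state
    variables in model time units; multiplying by ``timescale`` converts
    them to per-second rates (``timescale = 1000`` for models written on a
    millisecond time base).  ``t`` is a placeholder: fields are autonomous.

    ``threshold_v``/``reset_v`` describe the threshold-reset mechanic in the
    first state variable; ``reset_shift_h`` is added to the second variable
    on reset (e.g. the Izhikevich ``d`` parameter).  Models without a
    threshold park ``threshold_v`` at (or above) the top of the simulated
    grid so no mass is ever captured.

    ``efficacy_orientation`` says in which variable an incoming spike causes
    an instantaneous jump: ``"v"`` (first variable, delta synapse) or
    ``"h"`` (second variable, e.g. a conductance kick).

    ``tolerance``, when set, is the largest per-step state displacement
    considered trustworthy; a larger step logs a warning but is not an
    error.
    """

    name: str
    vector_field: VectorField
    timestep: float
    timescale: float = 1.0
    threshold_v: float = math.inf
    reset_v: float = -math.inf
    reset_shift_h: float = 0.0
    refractory_period: float = 0.0
    efficacy_orientation: str = "v"
    tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError(f"timestep must be > 0, got {self.timestep}")
        if self.timescale <= 0:
            raise ValueError(f"timescale must be > 0, got {self.timescale}")
        if self.refractory_period < 0:
            raise ValueError("refractory_period must be >= 0")
        if not self.reset_v < self.threshold_v:
            raise ValueError(
                f"reset_v ({self.reset_v}) must lie below threshold_v "
                f"({self.threshold_v})"
            )
        if self.efficacy_orientation not in ("v", "h"):
            raise ValueError(
                "efficacy_orientation must be 'v' or 'h', got "
                f"{self.efficacy_orientation!r}"
            )

    def derivatives(self, v: float, w: float) -> tuple[float, float]:
        """Per-second derivatives at (v, w), timescale applied."""
        dv, dw = self.vector_field((v, w), 0.0)
        return self.timescale * dv, self.timescale * dw

    def with_(self, **changes) -> "NeuronModel":
        """A copy with selected parameters replaced."""
        return replace(self, **changes)


def euler_step(
    model: NeuronModel,
    point: Sequence[float],
    dt: float,
    substeps: int = 1,
) -> tuple[float, float]:
    """Advance a state point by one Euler step of the noise-free flow.

    No threshold is applied: this is the pure deterministic flow used when
    translating grid-cell vertices.  ``substeps`` > 1 subdivides ``dt`` for
    stiff fields; the default single step is normally sufficient at the
    small time steps used for grid generation.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    v, w = float(point[0]), float(point[1])
    h = dt / substeps
    for _ in range(substeps):
        dv, dw = model.derivatives(v, w)
        if not (math.isfinite(dv) and math.isfinite(dw)):
            raise FloatingPointError(
                f"vector field of model {model.name!r} is non-finite at "
                f"({v}, {w})"
            )
        v += h * dv
        w += h * dw
    if model.tolerance is not None:
        disp = math.hypot(v - float(point[0]), w - float(point[1]))
        if disp > model.tolerance:
            logger.warning(
                "model %s: per-step displacement %.3g exceeds tolerance %.3g "
                "at state (%.4g, %.4g)",
                model.name, disp, model.tolerance, point[0], point[1],
            )
    return v, w


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------

def _lif_field(y, t):
    return (-y[0], 0.0)


def _qif_field_factory(current: float) -> VectorField:
    def qif(y, t):
        return (y[0] * y[0] + current, 0.0)
    return qif


def _cond2d_field_factory(tau: float, tau_e: float, e_l: float,
                          g_l: float) -> VectorField:
    def cond(y, t):
        v, g = y
        return ((-g_l * (v - e_l) - g * v) / tau, -g / tau_e)
    return cond


def _fn_field(y, t):
    v, w = y
    return (v - v ** 3 / 3.0 - w, 0.08 * (v + 0.7 - 0.8 * w))


def _izh_field_factory(a: float, b: float, current: float) -> VectorField:
    def izh(y, t):
        v, u = y
        return (0.04 * v * v + 5.0 * v + 140.0 - u + current,
                a * (b * v - u))
    return izh


def _adex_field_factory(c_m, g_l, e_l, v_t, delta_t, tau_w, a, current):
    def adex(y, t):
        v, w = y
        dv = (-g_l * (v - e_l) + g_l * delta_t * np.exp((v - v_t) / delta_t)
              - w + current) / c_m
        dw = (a * (v - e_l) - w) / tau_w
        return (dv, dw)
    return adex


def _build_archive() -> dict[str, NeuronModel]:
    return {
        "lif": NeuronModel(
            name="lif",
            vector_field=_lif_field,
            timestep=1e-3,
            timescale=1.0,
            threshold_v=1.0,
            reset_v=0.0,
            efficacy_orientation="v",
        ),
        "qif": NeuronModel(
            name="qif",
            vector_field=_qif_field_factory(1.0),
            timestep=1e-3,
            timescale=1.0,
            threshold_v=10.0,
            reset_v=-10.0,
            efficacy_orientation="v",
        ),
        "cond2d": NeuronModel(
            name="cond2d",
            vector_field=_cond2d_field_factory(
                tau=0.020, tau_e=0.005, e_l=-65.0, g_l=1.0),
            timestep=1e-3,
            timescale=1.0,
            threshold_v=-55.0,
            reset_v=-65.0,
            efficacy_orientation="h",
        ),
        "fitzhugh_nagumo": NeuronModel(
            name="fitzhugh_nagumo",
            vector_field=_fn_field,
            timestep=1e-3,
            timescale=1.0,
            # no threshold-reset: threshold sits at the top of the
            # recommended grid, reset at the bottom, so no mass is captured
            threshold_v=3.0,
            reset_v=-3.0,
            efficacy_orientation="v",
        ),
        "izhikevich": NeuronModel(
            name="izhikevich",
            vector_field=_izh_field_factory(a=0.02, b=0.2, current=0.0),
            timestep=1e-4,
            timescale=1000.0,  # model is written per millisecond
            threshold_v=30.0,
            reset_v=-65.0,
            reset_shift_h=8.0,
            efficacy_orientation="v",
        ),
        "adex": NeuronModel(
            name="adex",
            vector_field=_adex_field_factory(
                c_m=281.0, g_l=30.0, e_l=-70.6, v_t=-50.4, delta_t=2.0,
                tau_w=144.0, a=4.0, current=0.0),
            timestep=1e-4,
            timescale=1000.0,
            threshold_v=-40.0,
            reset_v=-70.6,
            reset_shift_h=80.5,
            efficacy_orientation="v",
        ),
    }


_ARCHIVE = _build_archive()

#: Recommended state-space extents (v_min, v_max, h_min, h_max) that cover
#: the region each archive model visits under moderate drive.
RECOMMENDED_GRIDS: dict[str, tuple[float, float, float, float]] = {
    "lif": (-1.0, 1.1, -1.0, 1.0),
    "qif": (-10.0, 10.0, -1.0, 1.0),
    "cond2d": (-72.0, -54.0, -0.2, 1.0),
    "fitzhugh_nagumo": (-3.0, 3.0, -1.5, 2.0),
    "izhikevich": (-80.0, 35.0, -20.0, 10.0),
    "adex": (-80.0, -38.0, -100.0, 400.0),
}


def archive_model(name: str) -> NeuronModel:
    """Return an archive model by name with its standard parameters.

    Use :meth:`NeuronModel.with_` to override individual parameters
    (e.g. a refractory period or a different time step).
    """
    try:
        return _ARCHIVE[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available models: "
            + ", ".join(sorted(_ARCHIVE))
        ) from None
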