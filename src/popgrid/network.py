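"""Networks of interacting populations and the synchronous run loop.

Each node is a population: either a density over a state-space grid
(evolved with the population density technique) or a plain rate source.
Connections carry the presynaptic activity, scaled by the number of
incoming connections per neuron, through a transmission-delay queue; the
delivered value is the Poisson input rate used to drive the target's
master equation with a jump matrix built once from the connection's
efficacy.

The update is synchronous: every node reads last-step (delay-queued)
activities, then every node advances.  A delay of 0 therefore still
implies a one-step transport lag between nodes.  Within one node step the
operator order is fixed: deterministic transition, reset/refractory
redistribution, master process, then activity computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import (ConfigurationError, StateGrid, TransitionMatrix,
                   generate_deterministic_matrix)
from .master import (DEFAULT_MASTER_STEPS, DensityState, JumpSpec,
                     apply_master_process, build_jump_matrix, delta_density)
from .models import NeuronModel
from .reset import (RefractoryQueues, ResetMapping, build_reset_mapping,
                    firing_rate, step_reset)

logger = logging.getLogger("popgrid")

NODE_TYPES = ("EXCITATORY", "INHIBITORY", "NEUTRAL")

#: per-node, per-step tolerance on total probability mass
MASS_TOL = 1e-9


@dataclass(frozen=True)
class NodeSpec:
    """Declaration of one population node."""

    name: str
    algorithm: str
    node_type: str = "NEUTRAL"
    activity_kind: str = "rate"  # "rate" | "avgv"

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise ConfigurationError(
                f"node {self.name!r}: type must be one of {NODE_TYPES}, "
                f"got {self.node_type!r}")
        if self.activity_kind not in ("rate", "avgv"):
            raise ConfigurationError(
                f"node {self.name!r}: activity_kind must be 'rate' or "
                f"'avgv', got {self.activity_kind!r}")


@dataclass(frozen=True)
class ConnectionSpec:
    """A typed delayed connection between two named nodes.

    ``num_connections`` is the average number of synapses each neuron of
    the target population receives from the source population; it
    multiplies the source activity to give the effective Poisson rate.
    """

    in_node: str
    out_node: str
    num_connections: float
    efficacy: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.num_connections < 0:
            raise ConfigurationError(
                f"connection {self.in_node}->{self.out_node}: "
                "num_connections must be >= 0")
        if self.delay < 0:
            raise ConfigurationError(
                f"connection {self.in_node}->{self.out_node}: "
                "delay must be >= 0")


def effective_input_rate(conn: ConnectionSpec, in_activity: float) -> float:
    """Effective Poisson rate delivered by a connection: n_conn x activity."""
    return conn.num_connections * in_activity


class DelayQueue:
    """Scalar transmission-delay queue with linear interpolation.

    With ``n = delay / dt`` the queue keeps ``ceil(n) + 1`` past values and
    reads ``(1 - f) * oldest + f * second-oldest`` where ``f = ceil(n) - n``,
    i.e. an effective transport of ``n + 1`` steps: the extra step is the
    synchronous-update lag, so a zero-delay connection delivers the
    previous step's activity.
    """

    def __init__(self, delay: float, dt: float):
        if delay < 0:
            raise ConfigurationError("delay must be >= 0")
        n = delay / dt
        k = math.floor(n + 1e-9)
        frac = n - k
        ceil_n = k if frac < 1e-9 else k + 1
        self.f = float(ceil_n - n)
        if self.f < 1e-9:
            self.f = 0.0
        self.slots = [0.0] * (ceil_n + 1)

    def read(self) -> float:
        if len(self.slots) == 1:
            return self.slots[-1]
        return (1.0 - self.f) * self.slots[-1] + self.f * self.slots[-2]

    def push(self, value: float) -> None:
        self.slots.pop()
        self.slots.insert(0, value)


# ---------------------------------------------------------------------------
# Population implementations
# ---------------------------------------------------------------------------

class RatePopulation:
    """A node emitting a constant activity (external Poisson source)."""

    is_grid = False

    def __init__(self, name: str, rate: float):
        self.name = name
        self.rate = float(rate)
        self.activity = float(rate)

    def step(self, inputs, dt: float) -> float:
        self.activity = self.rate
        return self.activity


class GridPopulation:
    """A population evolved with the grid population density technique.

    Holds the grid, the pre-computed deterministic transition matrix, the
    reset mapping with its refractory queues, and the current density.
    The initial density is a delta: all mass in the cell containing
    ``start`` (default: the reset potential at second coordinate 0,
    clipped into the grid).
    """

    is_grid = True

    def __init__(
        self,
        name: str,
        model: NeuronModel,
        grid: StateGrid,
        det_matrix: TransitionMatrix | None = None,
        master_steps: int = DEFAULT_MASTER_STEPS,
        activity_kind: str = "rate",
        start: tuple[float, float] | None = None,
        timestep: float | None = None,
    ):
        self.name = name
        self.model = model
        self.grid = grid
        self.dt = timestep if timestep is not None else model.timestep
        if det_matrix is None:
            det_matrix = generate_deterministic_matrix(model, grid)
        if det_matrix.n_cells != grid.n_cells:
            raise ConfigurationError(
                f"node {name!r}: transition matrix size "
                f"{det_matrix.n_cells} does not match grid "
                f"{grid.n_cells}")
        self.det_matrix = det_matrix
        self.master_steps = int(master_steps)
        self.activity_kind = activity_kind
        self.mapping = build_reset_mapping(grid, model)
        self.queues = RefractoryQueues.for_model(
            self.mapping, model.refractory_period, self.dt)
        if start is None:
            w0 = min(max(0.0, grid.h_min), grid.h_max)
            start = (model.reset_v, w0)
        self.state = delta_density(grid, start[0], start[1])
        self.state.queues = self.queues
        self._centers_v = grid.cell_centers_v()
        self.activity = 0.0
        self.fired = 0.0

    def step(self, inputs: Sequence[tuple[float, TransitionMatrix]],
             dt: float) -> float:
        """Advance one simulation step of length ``dt``.

        ``dt`` must equal or be an integer multiple of the node's own time
        step; in the latter case the node substeps with the same inputs.
        """
        ratio = dt / self.dt
        k = round(ratio)
        if k < 1 or abs(ratio - k) > 1e-9:
            raise ConfigurationError(
                f"node {self.name!r}: simulation t_step {dt} is not an "
                f"integer multiple of the node time step {self.dt}")
        fired_total = 0.0
        for _ in range(k):
            state = self.state
            state = DensityState(
                mass=self.det_matrix.apply(state.mass),
                time=state.time, queues=state.queues)
            state, fired = step_reset(state, self.mapping, self.queues,
                                      self.dt)
            fired_total += fired
            state = apply_master_process(state, inputs, self.dt,
                                         self.master_steps)
            self.state = state
        self.fired = fired_total
        total = self.state.total()
        if abs(total - 1.0) > MASS_TOL:
            raise FloatingPointError(
                f"node {self.name!r}: total mass {total!r} drifted from 1 "
                f"at t={self.state.time!r}")
        if self.activity_kind == "avgv":
            in_grid = self.state.mass.sum()
            self.activity = (
                float(self.state.mass @ self._centers_v) / in_grid
                if in_grid > 0 else 0.0)
        else:
            self.activity = firing_rate(fired_total, dt)
        return self.activity


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExternalInputSpec:
    """An input slot fed per step by the caller of ``evolve``."""

    node: str
    num_connections: float = 1.0
    efficacy: float = 0.0
    delay: float = 0.0


class _RuntimeConnection:
    __slots__ = ("spec", "queue", "jump")

    def __init__(self, spec: ConnectionSpec, queue: DelayQueue,
                 jump: TransitionMatrix | None):
        self.spec = spec
        self.queue = queue
        self.jump = jump


def _check_sign_rule(node_type: str, efficacy: float, label: str) -> None:
    if node_type == "EXCITATORY" and efficacy < 0:
        raise ConfigurationError(
            f"{label}: negative efficacy {efficacy} from an EXCITATORY node")
    if node_type == "INHIBITORY" and efficacy > 0:
        raise ConfigurationError(
            f"{label}: positive efficacy {efficacy} from an INHIBITORY node")


class Network:
    """A population network with a synchronous simulation loop.

    Populations are added with :meth:`add_node`; connections with
    :meth:`connect`.  External per-step inputs are declared with
    :meth:`add_external_input` and supplied, in declaration order, to each
    :meth:`evolve` call, which returns the activities of the nodes declared
    with :meth:`add_output` (also in declaration order).
    """

    def __init__(self, t_step: float):
        if t_step <= 0:
            raise ConfigurationError(f"t_step must be > 0, got {t_step}")
        self.t_step = float(t_step)
        self.nodes: dict[str, RatePopulation | GridPopulation] = {}
        self.node_specs: dict[str, NodeSpec] = {}
        self.connections: list[_RuntimeConnection] = []
        self.external_inputs: list[ExternalInputSpec] = []
        self._external_runtime: list[_RuntimeConnection | None] = []
        self._external_jumps: list[TransitionMatrix | None] = []
        self.outputs: list[str] = []
        self.time = 0.0
        self.steps_taken = 0

    # -- construction ------------------------------------------------------

    def add_node(self, population, node_type: str = "NEUTRAL",
                 ) -> None:
        name = population.name
        if name in self.nodes:
            raise ConfigurationError(f"duplicate node name {name!r}")
        spec = NodeSpec(
            name=name,
            algorithm=type(population).__name__,
            node_type=node_type,
            activity_kind=getattr(population, "activity_kind", "rate"),
        )
        self.nodes[name] = population
        self.node_specs[name] = spec

    def _require_node(self, name: str):
        if name not in self.nodes:
            raise ConfigurationError(
                f"unknown node {name!r}; known nodes: "
                + ", ".join(self.nodes) if self.nodes else "(none)")
        return self.nodes[name]

    def _jump_for(self, target, efficacy: float) -> TransitionMatrix | None:
        if not target.is_grid:
            return None
        jump = JumpSpec(efficacy=efficacy,
                        orientation=target.model.efficacy_orientation)
        return build_jump_matrix(target.grid, jump)

    def connect(self, spec: ConnectionSpec) -> None:
        src = self._require_node(spec.in_node)
        target = self._require_node(spec.out_node)
        _check_sign_rule(self.node_specs[spec.in_node].node_type,
                         spec.efficacy,
                         f"connection {spec.in_node}->{spec.out_node}")
        queue = DelayQueue(spec.delay, self.t_step)
        self.connections.append(
            _RuntimeConnection(spec, queue, self._jump_for(target,
                                                           spec.efficacy)))

    def add_external_input(self, spec: ExternalInputSpec) -> None:
        target = self._require_node(spec.node)
        jump = self._jump_for(target, spec.efficacy)
        if spec.delay > 0:
            conn = _RuntimeConnection(
                ConnectionSpec(in_node="<external>", out_node=spec.node,
                               num_connections=spec.num_connections,
                               efficacy=spec.efficacy, delay=spec.delay),
                DelayQueue(spec.delay, self.t_step), jump)
        else:
            conn = None
        self.external_inputs.append(spec)
        self._external_runtime.append(conn)
        self._external_jumps.append(jump)

    def add_output(self, node: str) -> None:
        self._require_node(node)
        self.outputs.append(node)

    def validate(self) -> "Network":
        """Re-check endpoints and efficacy sign rules; returns self."""
        for conn in self.connections:
            self._require_node(conn.spec.in_node)
            self._require_node(conn.spec.out_node)
            _check_sign_rule(
                self.node_specs[conn.spec.in_node].node_type,
                conn.spec.efficacy,
                f"connection {conn.spec.in_node}->{conn.spec.out_node}")
        return self

    # -- simulation --------------------------------------------------------

    def evolve(self, external_values: Sequence[float] = ()) -> list[float]:
        """Advance the whole network one synchronous step.

        ``external_values`` must contain one rate per declared external
        input, in declaration order.  Returns the activities of the
        declared output nodes.
        """
        if len(external_values) != len(self.external_inputs):
            raise ConfigurationError(
                f"expected {len(self.external_inputs)} external input "
                f"value(s), got {len(external_values)}")
        # gather per-node master inputs from delayed activities
        per_node: dict[str, list[tuple[float, TransitionMatrix]]] = {
            name: [] for name in self.nodes}
        for conn in self.connections:
            if conn.jump is None:
                continue
            delayed = conn.queue.read()
            rate = effective_input_rate(conn.spec, delayed)
            per_node[conn.spec.out_node].append((max(rate, 0.0), conn.jump))
        for spec, runtime, jump, value in zip(
                self.external_inputs, self._external_runtime,
                self._external_jumps, external_values):
            if jump is None:
                continue
            if runtime is not None:
                rate = effective_input_rate(runtime.spec,
                                            runtime.queue.read())
            else:
                rate = spec.num_connections * float(value)
            per_node[spec.node].append((max(rate, 0.0), jump))
        # advance every node
        for name, node in self.nodes.items():
            node.step(per_node[name], self.t_step)
        # push fresh activities into the delay queues
        for conn in self.connections:
            conn.queue.push(self.nodes[conn.spec.in_node].activity)
        for runtime, value in zip(self._external_runtime, external_values):
            if runtime is not None:
                runtime.queue.push(float(value))
        self.time += self.t_step
        self.steps_taken += 1
        return [self.nodes[name].activity for name in self.outputs]

    def mass_error(self) -> float:
        """Largest |total mass - 1| over the grid nodes."""
        errs = [abs(node.state.total() - 1.0)
                for node in self.nodes.values() if node.is_grid]
        return max(errs, default=0.0)


def validate_network(nodes: Sequence[tuple], connections:
                     Sequence[ConnectionSpec], t_step: float) -> Network:
    """Build and validate a network from (population, node_type) pairs."""
    net = Network(t_step)
    for population, node_type in nodes:
        net.add_node(population, node_type)
    for spec in connections:
        net.connect(spec)
    return net.validate()


# ---------------------------------------------------------------------------
# Whole-simulation driver
# ---------------------------------------------------------------------------

@dataclass
class RateTrace:
    times: list[float] = field(default_factory=list)
    values: list[float] = field(default_factory=list)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.values)


@dataclass
class RunResult:
    """Recorded output of :func:`run_network`."""

    rates: dict[str, RateTrace]
    densities: dict[str, list[tuple[float, np.ndarray]]]
    activities: dict[str, np.ndarray]
    times: np.ndarray
    log: list[str]
    network: Network


def run_network(
    network: Network,
    t_end: float,
    rate_records: dict[str, float] | None = None,
    density_records: dict[str, tuple[float, float, float]] | None = None,
    external: Sequence[Sequence[float]] | None = None,
) -> RunResult:
    """Run ``round(t_end / t_step)`` synchronous steps and record output.

    ``rate_records`` maps node name -> recording interval; a node's
    activity (firing rate, or average membrane potential for AvgV nodes)
    is stored every interval, starting at t = 0 (the initial activity).
    ``density_records`` maps node name -> (t_start, t_end, t_interval) for
    grid-node density snapshots.  ``external`` optionally supplies the
    per-step external input rows; a missing argument means all zeros.
    """
    if t_end < 0:
        raise ConfigurationError(f"t_end must be >= 0, got {t_end}")
    dt = network.t_step
    n_steps = round(t_end / dt)
    rate_records = rate_records or {}
    density_records = density_records or {}
    for name, interval in rate_records.items():
        network._require_node(name)
        if interval < dt - 1e-12:
            raise ConfigurationError(
                f"rate record for {name!r}: t_interval ({interval}) must be "
                f">= t_step ({dt})")
    for name, (ts, te, ti) in density_records.items():
        if not network._require_node(name).is_grid:
            raise ConfigurationError(
                f"density record requested for non-grid node {name!r}")
        if ti < dt - 1e-12:
            raise ConfigurationError(
                f"density record for {name!r}: t_interval ({ti}) must be "
                f">= t_step ({dt})")

    rates = {name: RateTrace() for name in rate_records}
    densities: dict[str, list[tuple[float, np.ndarray]]] = {
        name: [] for name in density_records}
    all_traces: dict[str, list[float]] = {name: [] for name in network.nodes}
    log: list[str] = [f"t_step={dt} steps={n_steps}"]

    def _due(t: float, interval: float) -> bool:
        k = round(t / interval)
        return abs(t - k * interval) < dt * 1e-6

    def _record(t: float) -> None:
        for name, interval in rate_records.items():
            if _due(t, interval):
                tr = rates[name]
                tr.times.append(t)
                tr.values.append(network.nodes[name].activity)
        for name, (ts, te, ti) in density_records.items():
            if ts - 1e-12 <= t <= te + 1e-12 and _due(t - ts, ti):
                densities[name].append(
                    (t, network.nodes[name].state.mass.copy()))

    _record(0.0)
    times = []
    for step in range(n_steps):
        row = external[step] if external is not None else \
            [0.0] * len(network.external_inputs)
        network.evolve(row)
        t = network.time
        times.append(t)
        for name in network.nodes:
            all_traces[name].append(network.nodes[name].activity)
        _record(t)
    log.append(f"final mass error {network.mass_error():.3e}")
    return RunResult(
        rates=rates,
        densities=densities,
        activities={k: np.asarray(v) for k, v in all_traces.items()},
        times=np.asarray(times),
        log=log,
        network=network,
    )
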