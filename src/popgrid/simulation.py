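"""Building and running simulations from XML descriptions.

:func:`build_network` instantiates a :class:`~popgrid.network.Network`
from a parsed :class:`~popgrid.config.SimulationConfig`, reading the
referenced ``.model``/``.tmat`` artefacts.  :func:`run_simulation` executes
the whole run loop with the configured reporting plan.

:class:`Simulation` is the step-wise control interface for driving a
simulation from user code: ``init`` (with variable overrides), time-step
and length getters, ``start``, ``evolve_single_step(inputs) -> outputs``
and ``end``.  Inputs and outputs are ordered exactly as the
``IncomingConnection``/``OutgoingConnection`` declarations in the XML.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import SimulationConfig, parse_simulation_xml
from .grid import (ConfigurationError, check_compatible, read_model_file,
                   read_tmat)
from .models import NeuronModel
from .network import (ConnectionSpec, ExternalInputSpec, GridPopulation,
                      Network, RatePopulation, RunResult, run_network)


def _zero_field(y, t):
    return (0.0, 0.0)


def _model_from_file_info(info) -> NeuronModel:
    """Reconstruct the model parameter record from a .model file.

    The vector field itself is not stored in the file — it is already baked
    into the .tmat transition matrix — so a placeholder field is used; only
    the threshold/reset/refractory parameters and the time step matter at
    run time.
    """
    return NeuronModel(
        name=info.name,
        vector_field=_zero_field,
        timestep=info.dt,
        timescale=info.timescale,
        threshold_v=info.threshold_v,
        reset_v=info.reset_v,
        reset_shift_h=info.reset_shift_h,
        refractory_period=info.refractory_period,
        efficacy_orientation=info.efficacy_orientation,
    )


def build_network(config: SimulationConfig,
                  base_dir: str | os.PathLike = ".") -> Network:
    """Instantiate the population network described by a config."""
    base = Path(base_dir)
    net = Network(config.run.t_step)
    artefacts: dict[str, tuple] = {}
    for alg in config.algorithms:
        if alg.kind == "grid":
            info = read_model_file(base / alg.model_file)
            tmat = read_tmat(base / alg.tmat_file)
            check_compatible(info, tmat)
            artefacts[alg.name] = (info, tmat)
    for node in config.nodes:
        alg = config.algorithm(node.algorithm)
        if alg.kind == "rate":
            net.add_node(RatePopulation(node.name, alg.rate),
                         node.node_type)
            continue
        info, tmat = artefacts[alg.name]
        model = _model_from_file_info(info)
        if alg.tau_refractive:
            model = model.with_(refractory_period=alg.tau_refractive)
        start = None
        if alg.start_v is not None or alg.start_w is not None:
            start = (alg.start_v if alg.start_v is not None else model.reset_v,
                     alg.start_w if alg.start_w is not None else 0.0)
        net.add_node(
            GridPopulation(
                name=node.name, model=model, grid=info.grid,
                det_matrix=tmat, master_steps=config.run.master_steps,
                activity_kind=alg.rate_method, start=start),
            node.node_type)
    for conn in config.connections:
        net.connect(ConnectionSpec(
            in_node=conn.in_node, out_node=conn.out_node,
            num_connections=conn.num_connections,
            efficacy=conn.efficacy, delay=conn.delay))
    for inc in config.incoming:
        net.add_external_input(ExternalInputSpec(
            node=inc.node, num_connections=inc.num_connections,
            efficacy=inc.efficacy, delay=inc.delay))
    for out in config.outgoing:
        net.add_output(out)
    return net.validate()


def run_simulation(config: SimulationConfig,
                   base_dir: str | os.PathLike = ".",
                   external: Sequence[Sequence[float]] | None = None,
                   ) -> RunResult:
    """Build the network and run it to ``t_end`` with the reporting plan.

    Identical configs produce bit-identical results: the density path
    contains no randomness.
    """
    net = build_network(config, base_dir)
    return run_network(
        net,
        t_end=config.run.t_end,
        rate_records={r.node: r.t_interval for r in config.rate_records},
        density_records={r.node: (r.t_start, r.t_end, r.t_interval)
                         for r in config.density_records},
        external=external,
    )


class Simulation:
    """Step-wise driver for a simulation loaded from an XML file."""

    def __init__(self, xml_path: str | os.PathLike,
                 variables: Mapping[str, str] | None = None):
        """Load and parse the XML description, applying variable overrides.

        Overrides must be strings; a variable not overridden uses the
        default from its ``<Variable>`` element.
        """
        self.xml_path = Path(xml_path)
        self.config = parse_simulation_xml(
            self.xml_path.read_text(), variables)
        self.network: Network | None = None

    def get_time_step(self) -> float:
        return self.config.run.t_step

    def get_simulation_length(self) -> float:
        return self.config.run.t_end

    @property
    def n_steps(self) -> int:
        return round(self.config.run.t_end / self.config.run.t_step)

    def start(self) -> None:
        """Instantiate the network, ready for the first evolve call."""
        self.network = build_network(self.config, self.xml_path.parent)

    def evolve_single_step(self, inputs: Sequence[float] = ()) -> list[float]:
        """Advance one time step.

        ``inputs`` holds one rate per ``IncomingConnection`` declaration (in
        XML order); the returned list holds the activities of the
        ``OutgoingConnection`` nodes (in XML order).
        """
        if self.network is None:
            raise ConfigurationError(
                "start() must be called before evolve_single_step()")
        return self.network.evolve(inputs)

    def end(self) -> dict[str, float]:
        """Finish the run; returns simple summary statistics."""
        if self.network is None:
            return {}
        stats = {
            "time": self.network.time,
            "steps": float(self.network.steps_taken),
            "mass_error": self.network.mass_error(),
        }
        return stats
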