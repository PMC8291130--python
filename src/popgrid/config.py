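"""Parsing of the XML simulation dialect.

A simulation description is a ``<Simulation>`` document with the sections
``Algorithms``, ``Nodes``, ``Connections``, ``Reporting`` and
``SimulationRunParameter``, plus optional ``<Variable>`` definitions and a
``<WeightType>`` declaring how connections are parameterised.

``Variable`` elements give named default values that may stand in for any
attribute value or element text in the file.  They are substituted
textually (all variables are strings) before any type checking; overrides
passed by the caller take precedence over the XML defaults.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Mapping

from .grid import ConfigurationError
from .master import DEFAULT_MASTER_STEPS
from .network import NODE_TYPES

WEIGHT_TYPES = ("double", "DelayedConnection", "CustomConnectionParameters")

#: algorithm type -> weight types it may be combined with; None marks types
#: that are recognised from the original vocabulary but not implemented here
_ALGORITHM_COMPAT: dict[str, tuple[str, ...] | None] = {
    "RateAlgorithm": WEIGHT_TYPES,
    "RateFunctor": WEIGHT_TYPES,
    "GridAlgorithm": ("CustomConnectionParameters",),
    "GridAlgorithmGroup": ("CustomConnectionParameters",),
    "MeshAlgorithm": None,
    "MeshAlgorithmCustom": None,
    "MeshAlgorithmGroup": None,
    "GridJumpAlgorithm": None,
    "OUAlgorithm": None,
    "WilsonCowanAlgorithm": None,
}


@dataclass(frozen=True)
class AlgorithmDef:
    """A named algorithm declaration (normalised: grid or rate)."""

    name: str
    kind: str  # "grid" | "rate"
    model_file: str = ""
    tmat_file: str = ""
    tau_refractive: float = 0.0
    rate_method: str = "rate"  # "rate" | "avgv"
    start_v: float | None = None
    start_w: float | None = None
    rate: float = 0.0


@dataclass(frozen=True)
class NodeDef:
    name: str
    algorithm: str
    node_type: str


@dataclass(frozen=True)
class ConnectionDef:
    in_node: str
    out_node: str
    num_connections: float
    efficacy: float
    delay: float
    extra: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class IncomingDef:
    node: str
    num_connections: float = 1.0
    efficacy: float = 0.0
    delay: float = 0.0


@dataclass(frozen=True)
class RateRecord:
    node: str
    t_interval: float


@dataclass(frozen=True)
class DensityRecord:
    node: str
    t_start: float
    t_end: float
    t_interval: float


@dataclass(frozen=True)
class RunParams:
    simulation_name: str
    t_end: float
    t_step: float
    log_name: str = "simulation.log"
    master_steps: int = DEFAULT_MASTER_STEPS


@dataclass(frozen=True)
class SimulationConfig:
    """The fully parsed, variable-substituted simulation description."""

    weight_type: str
    algorithms: tuple[AlgorithmDef, ...]
    nodes: tuple[NodeDef, ...]
    connections: tuple[ConnectionDef, ...]
    incoming: tuple[IncomingDef, ...]
    outgoing: tuple[str, ...]
    rate_records: tuple[RateRecord, ...]
    density_records: tuple[DensityRecord, ...]
    display_nodes: tuple[str, ...]
    run: RunParams
    variables: tuple[tuple[str, str], ...] = ()

    def algorithm(self, name: str) -> AlgorithmDef:
        for alg in self.algorithms:
            if alg.name == name:
                return alg
        raise ConfigurationError(f"unknown algorithm {name!r}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _substitute(root: ET.Element, values: Mapping[str, str]) -> None:
    for elem in root.iter():
        if elem.tag == "Variable":
            continue
        for key, val in list(elem.attrib.items()):
            if val.strip() in values:
                elem.attrib[key] = values[val.strip()]
        if elem.text and elem.text.strip() in values:
            elem.text = values[elem.text.strip()]


def _num(text: str | None, what: str) -> float:
    if text is None:
        raise ConfigurationError(f"{what}: missing value")
    try:
        return float(text.strip())
    except ValueError:
        raise ConfigurationError(
            f"{what}: non-numerical value {text.strip()!r}") from None


def _attr(elem: ET.Element, *names: str, default: str | None = None,
          required_as: str | None = None) -> str | None:
    for n in names:
        if n in elem.attrib:
            return elem.attrib[n]
    if required_as is not None:
        raise ConfigurationError(
            f"<{elem.tag}>: missing attribute {required_as!r}")
    return default


def _parse_algorithm(elem: ET.Element, weight_type: str) -> AlgorithmDef:
    a_type = _attr(elem, "type", required_as="type")
    name = _attr(elem, "name", required_as="name")
    compat = _ALGORITHM_COMPAT.get(a_type, "unknown")
    if compat == "unknown":
        raise ConfigurationError(
            f"algorithm {name!r}: unknown type {a_type!r}; supported types: "
            "RateAlgorithm, RateFunctor, GridAlgorithm (GridAlgorithmGroup)")
    if compat is None:
        raise ConfigurationError(
            f"algorithm {name!r}: type {a_type!r} is unsupported in this "
            "implementation")
    if weight_type not in compat:
        raise ConfigurationError(
            f"algorithm {name!r}: type {a_type!r} is not compatible with "
            f"WeightType {weight_type!r} (allowed: {', '.join(compat)})")
    if a_type in ("GridAlgorithm", "GridAlgorithmGroup"):
        rate_method = (_attr(elem, "ratemethod", default="") or "")
        start_v = _attr(elem, "start_v")
        start_w = _attr(elem, "start_w")
        tau = _attr(elem, "tau_refractive")
        return AlgorithmDef(
            name=name, kind="grid",
            model_file=_attr(elem, "modelfile", required_as="modelfile"),
            tmat_file=_attr(elem, "tmatfile", required_as="tmatfile"),
            tau_refractive=_num(tau, f"algorithm {name!r} tau_refractive")
            if tau is not None else 0.0,
            rate_method="avgv" if rate_method == "AvgV" else "rate",
            start_v=_num(start_v, f"algorithm {name!r} start_v")
            if start_v is not None else None,
            start_w=_num(start_w, f"algorithm {name!r} start_w")
            if start_w is not None else None,
        )
    # rate-producing algorithms
    if a_type == "RateAlgorithm":
        rate_elem = elem.find("rate")
        rate = _num(rate_elem.text if rate_elem is not None else None,
                    f"algorithm {name!r} <rate>")
    else:  # RateFunctor: constant expressions only
        expr_elem = elem.find("expression")
        text = expr_elem.text if expr_elem is not None else None
        if text is None:
            raise ConfigurationError(
                f"algorithm {name!r}: RateFunctor requires an <expression>")
        try:
            rate = float(text.strip())
        except ValueError:
            raise ConfigurationError(
                f"algorithm {name!r}: RateFunctor supports constant "
                f"expressions only, got {text.strip()!r}") from None
    return AlgorithmDef(name=name, kind="rate", rate=rate)


def _parse_connection(elem: ET.Element, weight_type: str) -> ConnectionDef:
    in_node = _attr(elem, "In", required_as="In")
    out_node = _attr(elem, "Out", required_as="Out")
    label = f"connection {in_node}->{out_node}"
    if weight_type == "CustomConnectionParameters":
        core = {"In", "Out", "num_connections", "efficacy", "delay"}
        extra = tuple(sorted(
            (k, v) for k, v in elem.attrib.items() if k not in core))
        return ConnectionDef(
            in_node=in_node, out_node=out_node,
            num_connections=_num(
                _attr(elem, "num_connections", required_as="num_connections"),
                f"{label} num_connections"),
            efficacy=_num(_attr(elem, "efficacy", required_as="efficacy"),
                          f"{label} efficacy"),
            delay=_num(_attr(elem, "delay", default="0"), f"{label} delay"),
            extra=extra,
        )
    body = (elem.text or "").split()
    if weight_type == "DelayedConnection":
        if len(body) != 3:
            raise ConfigurationError(
                f"{label}: DelayedConnection needs 'num_connections efficacy "
                f"delay', got {elem.text!r}")
        return ConnectionDef(
            in_node=in_node, out_node=out_node,
            num_connections=_num(body[0], f"{label} num_connections"),
            efficacy=_num(body[1], f"{label} efficacy"),
            delay=_num(body[2], f"{label} delay"),
        )
    # weight type "double": a single multiplier
    if len(body) != 1:
        raise ConfigurationError(
            f"{label}: double connection needs a single weight, "
            f"got {elem.text!r}")
    return ConnectionDef(
        in_node=in_node, out_node=out_node,
        num_connections=_num(body[0], f"{label} weight"),
        efficacy=0.0, delay=0.0,
    )


def parse_simulation_xml(
    document: str,
    overrides: Mapping[str, str] | None = None,
) -> SimulationConfig:
    """Parse an XML simulation description into a :class:`SimulationConfig`.

    ``overrides`` maps variable names to replacement strings; a variable
    not overridden keeps the default from its ``<Variable>`` element.
    Unknown override names are rejected.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise ConfigurationError(f"malformed XML: {exc}") from None
    if root.tag != "Simulation":
        raise ConfigurationError(
            f"root element must be <Simulation>, got <{root.tag}>")

    variables: dict[str, str] = {}
    for var in root.iter("Variable"):
        name = _attr(var, "Name", "name", required_as="Name")
        if name in variables:
            raise ConfigurationError(f"duplicate Variable {name!r}")
        variables[name] = (var.text or "").strip()
    overrides = dict(overrides or {})
    for key in overrides:
        if key not in variables:
            raise ConfigurationError(
                f"override for unknown Variable {key!r}; defined: "
                + (", ".join(variables) or "(none)"))
        if not isinstance(overrides[key], str):
            raise ConfigurationError(
                f"Variable {key!r}: overrides must be passed as strings")
    values = {**variables, **overrides}
    _substitute(root, values)

    wt_elem = root.find("WeightType")
    weight_type = (wt_elem.text or "").strip() if wt_elem is not None \
        else "CustomConnectionParameters"
    if weight_type not in WEIGHT_TYPES:
        raise ConfigurationError(
            f"WeightType must be one of {WEIGHT_TYPES}, got {weight_type!r}")

    algorithms = []
    algs = root.find("Algorithms")
    for elem in (algs if algs is not None else []):
        if elem.tag != "Algorithm":
            continue
        algorithms.append(_parse_algorithm(elem, weight_type))
    names = [a.name for a in algorithms]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate algorithm names")

    nodes = []
    nodes_elem = root.find("Nodes")
    for elem in (nodes_elem if nodes_elem is not None else []):
        if elem.tag != "Node":
            continue
        node_type = _attr(elem, "type", default="NEUTRAL")
        # _DIRECT variants are synonyms in the original vocabulary
        node_type = node_type.replace("_DIRECT", "")
        if node_type not in NODE_TYPES:
            raise ConfigurationError(
                f"node {_attr(elem, 'name')!r}: invalid type {node_type!r}")
        nodes.append(NodeDef(
            name=_attr(elem, "name", required_as="name"),
            algorithm=_attr(elem, "algorithm", required_as="algorithm"),
            node_type=node_type,
        ))
    node_names = [n.name for n in nodes]
    if len(set(node_names)) != len(node_names):
        raise ConfigurationError("duplicate node names")
    for n in nodes:
        if n.algorithm not in names:
            raise ConfigurationError(
                f"node {n.name!r} references undeclared algorithm "
                f"{n.algorithm!r}")

    connections = []
    incoming = []
    outgoing = []
    conns = root.find("Connections")
    for elem in (conns if conns is not None else []):
        if elem.tag == "Connection":
            connections.append(_parse_connection(elem, weight_type))
        elif elem.tag == "IncomingConnection":
            node = _attr(elem, "Node", "node", required_as="Node")
            nc = _attr(elem, "num_connections", default="1")
            eff = _attr(elem, "efficacy", default="0")
            delay = _attr(elem, "delay", default="0")
            incoming.append(IncomingDef(
                node=node,
                num_connections=_num(nc, "IncomingConnection"),
                efficacy=_num(eff, "IncomingConnection"),
                delay=_num(delay, "IncomingConnection"),
            ))
        elif elem.tag == "OutgoingConnection":
            outgoing.append(_attr(elem, "Node", "node", required_as="Node"))
    for conn in connections:
        for endpoint in (conn.in_node, conn.out_node):
            if endpoint not in node_names:
                raise ConfigurationError(
                    f"connection references unknown node {endpoint!r}")
    for inc in incoming:
        if inc.node not in node_names:
            raise ConfigurationError(
                f"IncomingConnection references unknown node {inc.node!r}")
    for out in outgoing:
        if out not in node_names:
            raise ConfigurationError(
                f"OutgoingConnection references unknown node {out!r}")
    # efficacy sign rule vs the In node's type
    types = {n.name: n.node_type for n in nodes}
    for conn in connections:
        t = types[conn.in_node]
        if t == "EXCITATORY" and conn.efficacy < 0:
            raise ConfigurationError(
                f"connection {conn.in_node}->{conn.out_node}: negative "
                "efficacy from an EXCITATORY node")
        if t == "INHIBITORY" and conn.efficacy > 0:
            raise ConfigurationError(
                f"connection {conn.in_node}->{conn.out_node}: positive "
                "efficacy from an INHIBITORY node")

    run_elem = root.find("SimulationRunParameter")
    if run_elem is None:
        raise ConfigurationError("missing <SimulationRunParameter>")

    def _child(tag: str, default: str | None = None) -> str | None:
        e = run_elem.find(tag)
        if e is None or e.text is None:
            if default is not None:
                return default
            raise ConfigurationError(
                f"SimulationRunParameter: missing <{tag}>")
        return e.text.strip()

    master_raw = _child("master_steps", default=str(DEFAULT_MASTER_STEPS))
    master_steps = int(_num(master_raw, "master_steps"))
    if master_steps < 1:
        raise ConfigurationError("master_steps must be >= 1")
    run = RunParams(
        simulation_name=_child("SimulationName", default="simulation"),
        t_end=_num(_child("t_end"), "t_end"),
        t_step=_num(_child("t_step"), "t_step"),
        log_name=_child("name_log", default="simulation.log"),
        master_steps=master_steps,
    )
    if run.t_step <= 0:
        raise ConfigurationError(f"t_step must be > 0, got {run.t_step}")
    if run.t_end < 0:
        raise ConfigurationError(f"t_end must be >= 0, got {run.t_end}")

    rate_records = []
    density_records = []
    display_nodes = []
    rep = root.find("Reporting")
    for elem in (rep if rep is not None else []):
        node = _attr(elem, "node", "name", required_as="node") \
            if elem.tag in ("Rate", "Density", "Display") else None
        if elem.tag == "Rate":
            ti = _num(_attr(elem, "t_interval", required_as="t_interval"),
                      f"Rate record for {node!r}")
            if ti < run.t_step - 1e-12:
                raise ConfigurationError(
                    f"Rate record for {node!r}: t_interval must be >= t_step")
            rate_records.append(RateRecord(node=node, t_interval=ti))
        elif elem.tag == "Density":
            rec = DensityRecord(
                node=node,
                t_start=_num(_attr(elem, "t_start", required_as="t_start"),
                             "Density t_start"),
                t_end=_num(_attr(elem, "t_end", required_as="t_end"),
                           "Density t_end"),
                t_interval=_num(
                    _attr(elem, "t_interval", required_as="t_interval"),
                    "Density t_interval"),
            )
            if rec.t_interval < run.t_step - 1e-12:
                raise ConfigurationError(
                    f"Density record for {node!r}: t_interval must be >= "
                    "t_step")
            density_records.append(rec)
        elif elem.tag == "Display":
            display_nodes.append(node)
    for rec_node in ([r.node for r in rate_records]
                     + [r.node for r in density_records] + display_nodes):
        if rec_node not in node_names:
            raise ConfigurationError(
                f"Reporting references unknown node {rec_node!r}")
    alg_by_name = {a.name: a for a in algorithms}
    for rec in density_records:
        node_alg = alg_by_name[
            next(n.algorithm for n in nodes if n.name == rec.node)]
        if node_alg.kind != "grid":
            raise ConfigurationError(
                f"Density record for {rec.node!r}: densities can only be "
                "recorded from grid-algorithm nodes")

    return SimulationConfig(
        weight_type=weight_type,
        algorithms=tuple(algorithms),
        nodes=tuple(nodes),
        connections=tuple(connections),
        incoming=tuple(incoming),
        outgoing=tuple(outgoing),
        rate_records=tuple(rate_records),
        density_records=tuple(density_records),
        display_nodes=tuple(display_nodes),
        run=run,
        variables=tuple(sorted(variables.items())),
    )


# ---------------------------------------------------------------------------
# Serialisation (round-trip support)
# ---------------------------------------------------------------------------

def serialize_simulation_xml(config: SimulationConfig) -> str:
    """Render a config back to XML; re-parsing yields an equal config."""
    root = ET.Element("Simulation")
    for name, value in config.variables:
        var = ET.SubElement(root, "Variable", Name=name)
        var.text = value
    wt = ET.SubElement(root, "WeightType")
    wt.text = config.weight_type
    algs = ET.SubElement(root, "Algorithms")
    for alg in config.algorithms:
        if alg.kind == "grid":
            attrs = {
                "type": "GridAlgorithm", "name": alg.name,
                "modelfile": alg.model_file, "tmatfile": alg.tmat_file,
            }
            if alg.tau_refractive:
                attrs["tau_refractive"] = repr(alg.tau_refractive)
            if alg.rate_method == "avgv":
                attrs["ratemethod"] = "AvgV"
            if alg.start_v is not None:
                attrs["start_v"] = repr(alg.start_v)
            if alg.start_w is not None:
                attrs["start_w"] = repr(alg.start_w)
            ET.SubElement(algs, "Algorithm", attrs)
        else:
            e = ET.SubElement(algs, "Algorithm",
                              {"type": "RateAlgorithm", "name": alg.name})
            r = ET.SubElement(e, "rate")
            r.text = repr(alg.rate)
    nodes = ET.SubElement(root, "Nodes")
    for n in config.nodes:
        ET.SubElement(nodes, "Node", {
            "algorithm": n.algorithm, "name": n.name, "type": n.node_type})
    conns = ET.SubElement(root, "Connections")
    for c in config.connections:
        if config.weight_type == "CustomConnectionParameters":
            attrs = {"In": c.in_node, "Out": c.out_node,
                     "num_connections": repr(c.num_connections),
                     "efficacy": repr(c.efficacy), "delay": repr(c.delay)}
            attrs.update(dict(c.extra))
            ET.SubElement(conns, "Connection", attrs)
        else:
            e = ET.SubElement(conns, "Connection",
                              {"In": c.in_node, "Out": c.out_node})
            if config.weight_type == "DelayedConnection":
                e.text = f"{c.num_connections!r} {c.efficacy!r} {c.delay!r}"
            else:
                e.text = repr(c.num_connections)
    for inc in config.incoming:
        ET.SubElement(conns, "IncomingConnection", {
            "Node": inc.node, "num_connections": repr(inc.num_connections),
            "efficacy": repr(inc.efficacy), "delay": repr(inc.delay)})
    for out in config.outgoing:
        ET.SubElement(conns, "OutgoingConnection", {"Node": out})
    rep = ET.SubElement(root, "Reporting")
    for r in config.rate_records:
        ET.SubElement(rep, "Rate", {
            "node": r.node, "t_interval": repr(r.t_interval)})
    for d in config.density_records:
        ET.SubElement(rep, "Density", {
            "node": d.node, "t_start": repr(d.t_start),
            "t_end": repr(d.t_end), "t_interval": repr(d.t_interval)})
    for d in config.display_nodes:
        ET.SubElement(rep, "Display", {"node": d})
    run = ET.SubElement(root, "SimulationRunParameter")
    for tag, value in (
            ("SimulationName", config.run.simulation_name),
            ("t_end", repr(config.run.t_end)),
            ("t_step", repr(config.run.t_step)),
            ("name_log", config.run.log_name),
            ("master_steps", str(config.run.master_steps))):
        e = ET.SubElement(run, tag)
        e.text = value
    return ET.tostring(root, encoding="unicode")
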