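"""Declarative sequence definition, assembly and the lazy parameter graph.

A sequence is defined as a hierarchy of *blueprints*: reusable modules
carrying physics rules (pure functions over named parameters), optionally
flagged as loops (repeating their subtree) or atomics (leaves that translate
into hardware execution blocks).  ``assemble`` instantiates the hierarchy
into an :class:`ElementTree` and compiles every rule into a node of a
:class:`ParameterGraph` — a DAG with cached, lazily evaluated values.  Only
the dependency closure of a requested parameter is ever computed, and a
cached value is reused until one of its transitive inputs changes (loop
counters and protocol parameters are ordinary source nodes, so per-iteration
values flow through the same invalidation machinery).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterator, Mapping, Sequence

import networkx as nx

from ._units import DEFAULT_LIMITS, MS, HardwareLimits

__all__ = [
    "AssemblyError",
    "Blueprint",
    "BlueprintRegistry",
    "Element",
    "ElementTree",
    "EvaluationError",
    "ParameterGraph",
    "Protocol",
    "ProtocolReport",
    "Rule",
    "Violation",
    "assemble",
    "check_protocol",
    "const",
    "dump_bundle",
    "load_bundle",
    "rule_function",
    "solve_min_tr",
]


class AssemblyError(ValueError):
    """Raised when blueprint definitions cannot be assembled."""


class EvaluationError(RuntimeError):
    """Raised when a parameter rule fails; carries the parameter path."""

    def __init__(self, message: str, path: tuple[str, ...]):
        super().__init__(f"{message} [parameter path: {' -> '.join(path)}]")
        self.path = path


# --------------------------------------------------------------------------
# Rule registry: rules are host-language pure functions registered under a
# stable name so that sequence bundles can reference them by name.
# --------------------------------------------------------------------------

RULE_FUNCTIONS: dict[str, Callable[..., Any]] = {}


def rule_function(name: str) -> Callable[[Callable[..., Any]], Callable[..., Any]]:
    """Register a pure function as a named, serializable parameter rule."""

    def deco(func: Callable[..., Any]) -> Callable[..., Any]:
        if name in RULE_FUNCTIONS and RULE_FUNCTIONS[name] is not func:
            raise ValueError(f"rule function {name!r} already registered")
        RULE_FUNCTIONS[name] = func
        func.__rule_name__ = name
        return func

    return deco


@dataclass(frozen=True)
class Rule:
    """A parameter rule: a registered pure function plus its dependency names.

    ``deps`` are resolved at assembly time against the element hierarchy:
    plain names search the element itself, then its ancestors (nearest
    first; a loop exposes the implicit name ``index``), then the protocol
    and hardware-limit namespaces.  Qualified names ``inst.param`` search
    the ancestor chain for a direct child instance ``inst``.
    """

    func_name: str
    deps: tuple[str, ...] = ()
    value: Any = None  # payload for "const" rules

    @property
    def func(self) -> Callable[..., Any]:
        if self.func_name == "const":
            val = self.value
            return lambda: val
        return RULE_FUNCTIONS[self.func_name]


def const(value: Any) -> Rule:
    """A rule holding a constant value."""
    return Rule("const", (), value)


@dataclass(frozen=True)
class Blueprint:
    """A reusable sequence module definition.

    ``children`` is an ordered list of ``(instance_name, blueprint_name)``
    pairs; ``is_loop`` blueprints must define a rule ``count`` evaluating to
    a nonnegative integer, and expose the implicit counter ``index``;
    ``is_atomic`` blueprints are leaves that define a rule ``raw`` producing
    the hardware events of one execution block.
    """

    name: str
    rules: Mapping[str, Rule] = field(default_factory=dict)
    children: tuple[tuple[str, str], ...] = ()
    is_loop: bool = False
    is_atomic: bool = False

    def __post_init__(self) -> None:
        if self.is_loop and "count" not in self.rules:
            raise AssemblyError(f"loop blueprint {self.name!r} lacks a 'count' rule")
        if self.is_atomic and self.children:
            raise AssemblyError(f"atomic blueprint {self.name!r} must be a leaf")


class BlueprintRegistry:
    """Named collection of blueprints a sequence can be assembled from."""

    def __init__(self) -> None:
        self._bps: dict[str, Blueprint] = {}

    def add(self, bp: Blueprint) -> Blueprint:
        self._bps[bp.name] = bp
        return bp

    def get(self, name: str) -> Blueprint:
        try:
            return self._bps[name]
        except KeyError:
            raise AssemblyError(f"unknown blueprint reference {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._bps

    def names(self) -> list[str]:
        return sorted(self._bps)


# --------------------------------------------------------------------------
# Protocol
# --------------------------------------------------------------------------


@dataclass
class Protocol:
    """User-facing acquisition parameters.

    Times in milliseconds, geometry in millimetres, angles in degrees.
    ``extras`` is an open key-value set for sequence-specific parameters
    (b-values, subbolus duration, post-labeling delay, spoke counts,
    spectral points, bandwidth, mixing time, concatenations, ...).
    """

    tr: float = 10.0
    te: float = 5.0
    ti: float | None = None
    flip: float = 10.0
    refocus_flip: float = 180.0
    fov: tuple[float, float, float] = (256.0, 256.0, 256.0)
    matrix: tuple[int, int, int] = (64, 64, 1)
    partial_fourier: tuple[float, float] = (1.0, 1.0)  # phase, slice
    acceleration: tuple[int, int] = (1, 1)
    train_length: tuple[int, int] = (1, 1)
    averages: int = 1
    prescans: int = 0
    slice_thickness: float = 5.0
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.te <= 0:
            raise ValueError("TR and TE must be positive")
        if self.ti is not None and self.ti <= 0:
            raise ValueError("TI must be positive when present")
        if any(m < 1 for m in self.matrix):
            raise ValueError("matrix entries must be >= 1")
        for pf in self.partial_fourier:
            if not 0 < pf <= 1:
                raise ValueError("partial Fourier fraction must be in (0, 1]")
        if any(a < 1 for a in self.acceleration):
            raise ValueError("acceleration must be >= 1")
        if self.averages < 0 or self.prescans < 0:
            raise ValueError("averages/prescans must be nonnegative")

    def as_graph_sources(self) -> dict[str, Any]:
        src = {
            "protocol.tr": self.tr,
            "protocol.te": self.te,
            "protocol.ti": self.ti,
            "protocol.flip": self.flip,
            "protocol.refocus_flip": self.refocus_flip,
            "protocol.fov": tuple(self.fov),
            "protocol.matrix": tuple(self.matrix),
            "protocol.pf_phase": self.partial_fourier[0],
            "protocol.pf_slice": self.partial_fourier[1],
            "protocol.accel_phase": self.acceleration[0],
            "protocol.accel_slice": self.acceleration[1],
            "protocol.train_phase": self.train_length[0],
            "protocol.train_slice": self.train_length[1],
            "protocol.averages": self.averages,
            "protocol.prescans": self.prescans,
            "protocol.slice_thickness": self.slice_thickness,
        }
        for k, v in self.extras.items():
            src[f"protocol.{k}"] = v
        return src

    def to_dict(self) -> dict[str, Any]:
        return {
            "tr": self.tr,
            "te": self.te,
            "ti": self.ti,
            "flip": self.flip,
            "refocus_flip": self.refocus_flip,
            "fov": list(self.fov),
            "matrix": list(self.matrix),
            "partial_fourier": list(self.partial_fourier),
            "acceleration": list(self.acceleration),
            "train_length": list(self.train_length),
            "averages": self.averages,
            "prescans": self.prescans,
            "slice_thickness": self.slice_thickness,
            "extras": dict(self.extras),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Protocol":
        d = dict(d)
        for key in ("fov", "matrix", "partial_fourier", "acceleration", "train_length"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# --------------------------------------------------------------------------
# Parameter graph
# --------------------------------------------------------------------------


@dataclass
class _Node:
    id: str
    func: Callable[..., Any] | None  # None for source nodes
    dep_ids: tuple[str, ...]
    value: Any = None
    valid: bool = False
    dependents: set[str] = field(default_factory=set)


class ParameterGraph:
    """DAG of parameter rules with cached lazy evaluation.

    Source nodes (protocol values, loop counters, hardware limits) are set
    with :meth:`update`, which dirties exactly the transitive dependents.
    :meth:`evaluate` computes a node by recursively requesting only the
    values in its dependency closure; every rule evaluation is counted so
    laziness is instrumentable.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, _Node] = {}
        self.eval_counts: dict[str, int] = {}
        self._finalized = False

    # -- construction ------------------------------------------------------
    def add_source(self, node_id: str, value: Any) -> None:
        self._nodes[node_id] = _Node(node_id, None, (), value=value, valid=True)

    def add_rule(self, node_id: str, func: Callable[..., Any], dep_ids: Sequence[str]) -> None:
        if node_id in self._nodes:
            raise AssemblyError(f"duplicate parameter node {node_id!r}")
        self._nodes[node_id] = _Node(node_id, func, tuple(dep_ids))

    def finalize(self) -> None:
        """Check acyclicity, wire dependents, precompute strategies."""
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for node in self._nodes.values():
            for dep in node.dep_ids:
                if dep not in self._nodes:
                    raise AssemblyError(
                        f"parameter {node.id!r} depends on unknown node {dep!r}"
                    )
                g.add_edge(dep, node.id)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            members = sorted({a for a, _ in cycle})
            raise AssemblyError(f"cyclic parameter dependency: {members}")
        for node in self._nodes.values():
            for dep in node.dep_ids:
                self._nodes[dep].dependents.add(node.id)
        self._nx = g
        self._finalized = True

    # -- queries -----------------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node_ids(self) -> list[str]:
        return list(self._nodes)

    def strategy(self, node_id: str) -> list[str]:
        """Topological order of the node's dependency closure (inputs first)."""
        closure = nx.ancestors(self._nx, node_id) | {node_id}
        return list(nx.topological_sort(self._nx.subgraph(closure)))

    def is_source(self, node_id: str) -> bool:
        return self._nodes[node_id].func is None

    # -- evaluation --------------------------------------------------------
    def evaluate(self, node_id: str, _path: tuple[str, ...] = ()) -> Any:
        try:
            node = self._nodes[node_id]
        except KeyError:
            raise EvaluationError(f"unknown parameter {node_id!r}", _path + (node_id,))
        if node.valid:
            return node.value
        path = _path + (node_id,)
        args = [self.evaluate(dep, path) for dep in node.dep_ids]
        try:
            node.value = node.func(*args)
        except EvaluationError:
            raise
        except Exception as exc:  # noqa: BLE001 - rule failures become path errors
            raise EvaluationError(f"rule failed: {exc}", path) from exc
        node.valid = True
        self.eval_counts[node_id] = self.eval_counts.get(node_id, 0) + 1
        return node.value

    def update(self, node_id: str, value: Any) -> frozenset[str]:
        """Set a source node; returns the invalidated node ids (incl. itself)."""
        node = self._nodes.get(node_id)
        if node is None:
            raise KeyError(f"unknown parameter {node_id!r}")
        if node.func is not None:
            raise ValueError(f"{node_id!r} is a computed rule, not a source")
        node.value = value
        dirty = {node_id}
        stack = list(node.dependents)
        while stack:
            nid = stack.pop()
            if nid in dirty:
                continue
            dirty.add(nid)
            n = self._nodes[nid]
            if n.valid:
                n.valid = False
            stack.extend(n.dependents)
        return frozenset(dirty)

    def reset_counters(self) -> None:
        self.eval_counts = {}

    @property
    def total_evaluations(self) -> int:
        return sum(self.eval_counts.values())


# --------------------------------------------------------------------------
# Element tree
# --------------------------------------------------------------------------


@dataclass
class Element:
    """One instantiated node of the sequence hierarchy."""

    path: str
    instance: str
    blueprint: str
    kind: str  # module | loop | atomic
    parent: "Element | None"
    children: list["Element"] = field(default_factory=list)
    nodes: dict[str, str] = field(default_factory=dict)  # local rule name -> graph node id

    def node_id(self, local: str) -> str:
        return self.nodes[local]

    @property
    def index_node(self) -> str:
        return self.nodes["index"]

    @property
    def count_node(self) -> str:
        return self.nodes["count"]


def _as_loop_count(value: Any, node_id: str) -> int:
    """Coerce a loop count rule value to a nonnegative int or raise."""
    if isinstance(value, float) and value.is_integer():
        value = int(value)
    try:
        ok = int(value) == value and value >= 0
    except (TypeError, ValueError):
        ok = False
    if not ok:
        raise EvaluationError(
            f"loop count must be a nonnegative integer, got {value!r}", (node_id,)
        )
    return int(value)


class ElementTree:
    """Instantiated hierarchy with a deterministic traversal order."""

    def __init__(self, root: Element):
        self.root = root

    def iter_elements(self) -> Iterator[Element]:
        stack = [self.root]
        while stack:
            el = stack.pop()
            yield el
            stack.extend(reversed(el.children))

    def atomics(self) -> list[Element]:
        return [el for el in self.iter_elements() if el.kind == "atomic"]

    def traverse(self, graph: ParameterGraph, on_atomic: Callable[[Element], None]) -> int:
        """Depth-first execution traversal.

        Loops re-run their subtree for each ascending counter value, writing
        the counter into the graph so per-iteration rules recompute.  Returns
        the number of atomic visits.
        """
        visits = 0

        def walk(el: Element) -> None:
            nonlocal visits
            if el.kind == "loop":
                count = _as_loop_count(graph.evaluate(el.count_node), el.count_node)
                for i in range(count):
                    graph.update(el.index_node, i)
                    for child in el.children:
                        walk(child)
            else:
                if el.kind == "atomic":
                    visits += 1
                    on_atomic(el)
                for child in el.children:
                    walk(child)

        walk(self.root)
        return visits

    def count_atomic_visits(self, graph: ParameterGraph) -> int:
        """Number of atomic visits in a full traversal (no block building)."""
        return self.traverse(graph, lambda el: None)


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------


def _resolve_dep(el: Element, dep: str, graph_sources: Mapping[str, Any]) -> str:
    """Resolve a rule dependency name to a graph node id (see :class:`Rule`)."""
    if dep.startswith("protocol.") or dep.startswith("limits."):
        if dep in graph_sources:
            return dep
        raise AssemblyError(f"{el.path}: unknown protocol/limits reference {dep!r}")
    if "." in dep:
        parts = dep.split(".")
        inst, middle, local = parts[0], parts[1:-1], parts[-1]

        def descend(base: Element) -> str | None:
            cur = base
            for seg in middle:
                nxt = next((c for c in cur.children if c.instance == seg), None)
                if nxt is None:
                    return None
                cur = nxt
            return cur.nodes.get(local)

        anc: Element | None = el
        while anc is not None:
            for child in anc.children:
                if child.instance == inst:
                    hit = descend(child)
                    if hit is not None:
                        return hit
            if anc.instance == inst:
                hit = descend(anc)
                if hit is not None:
                    return hit
            anc = anc.parent
        raise AssemblyError(f"{el.path}: cannot resolve dependency {dep!r}")
    anc = el
    while anc is not None:
        if dep in anc.nodes:
            return anc.nodes[dep]
        anc = anc.parent
    for prefix in ("protocol.", "limits."):
        if prefix + dep in graph_sources:
            return prefix + dep
    raise AssemblyError(f"{el.path}: cannot resolve dependency {dep!r}")


def assemble(
    root: Blueprint | str,
    protocol: Protocol,
    registry: BlueprintRegistry,
    limits: HardwareLimits = DEFAULT_LIMITS,
) -> tuple[ElementTree, ParameterGraph]:
    """Instantiate a blueprint hierarchy into an element tree + parameter graph.

    Assembly computes a calculation strategy (dependency wiring and topological
    order) for every rule but evaluates nothing: hardware events are only
    computed when traversal requests an atomic's ``raw`` parameter.
    """
    root_bp = registry.get(root) if isinstance(root, str) else root

    graph = ParameterGraph()
    sources = protocol.as_graph_sources()
    sources.update(
        {
            "limits.gmax": limits.gmax,
            "limits.slew": limits.slew,
            "limits.b1_max": limits.b1_max,
            "limits.all": limits,
        }
    )
    for nid, value in sources.items():
        graph.add_source(nid, value)

    # pass 1: instantiate elements and declare their node ids
    pending: list[tuple[Element, Blueprint]] = []

    def instantiate(bp: Blueprint, instance: str, parent: Element | None) -> Element:
        path = instance if parent is None else f"{parent.path}/{instance}"
        kind = "loop" if bp.is_loop else ("atomic" if bp.is_atomic else "module")
        el = Element(path=path, instance=instance, blueprint=bp.name, kind=kind, parent=parent)
        for local in bp.rules:
            el.nodes[local] = f"{path}.{local}"
        if bp.is_loop:
            el.nodes["index"] = f"{path}.index"
            graph.add_source(el.nodes["index"], 0)
        pending.append((el, bp))
        for inst_name, child_bp_name in bp.children:
            el.children.append(instantiate(registry.get(child_bp_name), inst_name, el))
        return el

    root_el = instantiate(root_bp, root_bp.name, None)

    # pass 2: resolve dependencies and register rules
    for el, bp in pending:
        for local, r in bp.rules.items():
            dep_ids = tuple(_resolve_dep(el, d, sources) for d in r.deps)
            graph.add_rule(el.nodes[local], r.func, dep_ids)

    graph.finalize()

    tree = ElementTree(root_el)
    # validate loop counts are evaluable nonnegative integers
    for el in tree.iter_elements():
        if el.kind == "loop":
            try:
                _as_loop_count(graph.evaluate(el.count_node), el.count_node)
            except EvaluationError as exc:
                raise AssemblyError(f"loop {el.path!r}: {exc}") from exc
    return tree, graph


# --------------------------------------------------------------------------
# Protocol validity checking
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    kind: str
    message: str
    where: str = ""
    value: float | None = None


@dataclass
class ProtocolReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)


def check_protocol(
    tree: ElementTree,
    graph: ParameterGraph,
    limits: HardwareLimits = DEFAULT_LIMITS,
) -> ProtocolReport:
    """Validate an assembled sequence against timing and hardware limits.

    Violations (negative fill times, gradient amplitude/slew over limits,
    RF/ADC overlap) are report entries, never exceptions.  An empty report
    means the sequence is streamable as configured.
    """
    from .hardware_events import build_block, validate_block

    report = ProtocolReport()

    blocks = []

    def on_atomic(el: Element) -> None:
        blocks.append((el, build_block(el, graph)))

    try:
        tree.traverse(graph, on_atomic)
    except EvaluationError as exc:
        report.violations.append(Violation("evaluation", str(exc)))
        return report

    # timing feasibility: any computed *_fill parameter must be nonnegative
    for nid in graph.node_ids():
        if nid.endswith("_fill") and not graph.is_source(nid):
            fill = graph.evaluate(nid)
            if fill < 0:
                name = nid.rsplit(".", 1)[-1]
                # fills other than TR/TI fills derive from the echo timing
                which = "TR" if "tr" in name else ("TI" if "ti" in name else "TE")
                proto_id = {"TE": "protocol.te", "TR": "protocol.tr",
                            "TI": "protocol.ti"}[which]
                minimum = None
                if proto_id in graph:
                    requested = graph.evaluate(proto_id)
                    if requested is not None:
                        minimum = requested - fill / MS
                report.violations.append(
                    Violation(
                        "timing",
                        f"{which} below minimum"
                        + (f" (minimum {minimum:.3f} ms)" if minimum is not None else ""),
                        where=nid,
                        value=minimum,
                    )
                )

    for el, block in blocks:
        for v in validate_block(block, limits):
            report.violations.append(replace(v, where=f"{el.path}: {v.where}"))
    return report


def solve_min_tr(tree: ElementTree, graph: ParameterGraph) -> float | None:
    """Built-in solve handler: extend TR to the minimum feasible value.

    If any ``tr_fill`` parameter is negative, the protocol TR source node is
    raised to the minimum feasible TR (a warning is emitted) and the new TR
    in ms is returned; otherwise ``None``.
    """
    worst = 0.0
    for nid in graph.node_ids():
        if nid.endswith("tr_fill") and not graph.is_source(nid):
            fill = graph.evaluate(nid)
            if fill < worst:
                worst = fill
    if worst < 0:
        tr = graph.evaluate("protocol.tr")
        new_tr = tr - worst / MS
        warnings.warn(
            f"requested TR {tr:.3f} ms infeasible; extended to minimum {new_tr:.3f} ms",
            stacklevel=2,
        )
        graph.update("protocol.tr", new_tr)
        return new_tr
    return None


# --------------------------------------------------------------------------
# Sequence bundle (JSON) serialization
# --------------------------------------------------------------------------


def _rule_to_dict(r: Rule) -> dict[str, Any]:
    d: dict[str, Any] = {"func": r.func_name, "deps": list(r.deps)}
    if r.func_name == "const":
        d["value"] = r.value
    return d


def dump_bundle(
    root_name: str, registry: BlueprintRegistry, protocol: Protocol
) -> dict[str, Any]:
    """Serialize a sequence definition to a JSON-ready bundle document.

    Sections: ``blueprints`` (definitions with rules referencing registered
    function names), ``hierarchy`` (the root), ``parameter_rules`` (flat view
    of every blueprint rule), and ``protocol``.  Round-trips losslessly
    through :func:`load_bundle`.
    """
    blueprints = {}
    flat_rules = {}
    for name in registry.names():
        bp = registry.get(name)
        blueprints[name] = {
            "children": [list(c) for c in bp.children],
            "is_loop": bp.is_loop,
            "is_atomic": bp.is_atomic,
            "rules": {local: _rule_to_dict(r) for local, r in sorted(bp.rules.items())},
        }
        for local, r in bp.rules.items():
            flat_rules[f"{name}.{local}"] = _rule_to_dict(r)
    return {
        "format": "mrforge-bundle",
        "version": 1,
        "hierarchy": {"root": root_name},
        "blueprints": blueprints,
        "parameter_rules": flat_rules,
        "protocol": protocol.to_dict(),
    }


def load_bundle(doc: Mapping[str, Any]) -> tuple[str, BlueprintRegistry, Protocol]:
    """Reconstruct a sequence definition from a bundle document."""
    if doc.get("format") != "mrforge-bundle":
        raise ValueError("not an mrforge sequence bundle")
    registry = BlueprintRegistry()
    for name, bd in doc["blueprints"].items():
        rules = {}
        for local, rd in bd["rules"].items():
            if rd["func"] == "const":
                rules[local] = const(rd["value"])
            else:
                if rd["func"] not in RULE_FUNCTIONS:
                    raise ValueError(f"unknown rule function {rd['func']!r}")
                rules[local] = Rule(rd["func"], tuple(rd["deps"]))
        registry.add(
            Blueprint(
                name=name,
                rules=rules,
                children=tuple((c[0], c[1]) for c in bd["children"]),
                is_loop=bd["is_loop"],
                is_atomic=bd["is_atomic"],
            )
        )
    protocol = Protocol.from_dict(doc["protocol"])
    return doc["hierarchy"]["root"], registry, protocol


def save_bundle_json(path: str, root_name: str, registry: BlueprintRegistry, protocol: Protocol) -> None:
    with open(path, "w") as fh:
        json.dump(dump_bundle(root_name, registry, protocol), fh, indent=1, sort_keys=True)


def load_bundle_json(path: str) -> tuple[str, BlueprintRegistry, Protocol]:
    with open(path) as fh:
        return load_bundle(json.load(fh))
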