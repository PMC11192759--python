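"""Signed, weighted, directed signaling-network data structure.

The network is the substrate every simulation runs on: nodes are proteins
(or logical process nodes such as "DNA repair") carrying two state
variables — an *activity* in [0, 1] that evolves during simulation and a
positive *concentration* that scales the node's influence on its
neighbours.  Edges are directed and signed (+1 activating, -1 inhibiting)
with a positive scalar weight.

The canonical on-disk format is a versioned graph-json document
(:func:`save_network` / :func:`load_network`); SIF and GraphML are
import/export conveniences.  SIF carries no numeric attributes, so weights
default to 1 and node parameters to their defaults on SIF import.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import FormatError, UnknownNodeError, ValidationError

GRAPH_JSON_FORMAT = "signaling-network"
GRAPH_JSON_VERSION = 1

ROLES = ("oncogene", "tumor_suppressor", "neutral")
READOUTS = ("none", "cell_cycle", "apoptosis")


@dataclass
class NodeSpec:
    """A single protein or logical-process node.

    ``base_activity``/``base_concentration`` are the untreated, generic
    (not cell-line-specific) values; ``activity_min``/``activity_max``
    bound the activity throughout a simulation and are the handles through
    which mutations and drugs act.
    """

    id: str
    label: str = ""
    base_activity: float = 0.5
    base_concentration: float = 1.0
    activity_min: float = 0.0
    activity_max: float = 1.0
    role: str = "neutral"
    module: str = ""
    readout: str = "none"

    def __post_init__(self) -> None:
        if not self.label:
            self.label = self.id

    def violations(self) -> list[str]:
        out = []
        if not 0.0 <= self.activity_min <= 1.0 or not 0.0 <= self.activity_max <= 1.0:
            out.append(f"node {self.id}: activity bounds outside [0,1]")
        if self.activity_min > self.activity_max:
            out.append(
                f"node {self.id}: activity_min {self.activity_min} > "
                f"activity_max {self.activity_max}"
            )
        if not self.activity_min <= self.base_activity <= self.activity_max:
            out.append(f"node {self.id}: base_activity outside [min, max]")
        if not self.base_concentration > 0:
            out.append(f"node {self.id}: base_concentration must be > 0")
        if self.role not in ROLES:
            out.append(f"node {self.id}: unknown role {self.role!r}")
        if self.readout not in READOUTS:
            out.append(f"node {self.id}: unknown readout {self.readout!r}")
        if self.readout != "none" and self.role != "neutral":
            out.append(f"node {self.id}: readout nodes must have role neutral")
        return out


@dataclass
class EdgeSpec:
    """Directed signed interaction; signed effect = sign * weight."""

    source: str
    target: str
    sign: int = 1
    weight: float = 1.0

    def violations(self, node_ids: set[str], allow_self_loops: bool) -> list[str]:
        out = []
        if self.source not in node_ids:
            out.append(f"edge {self.source}->{self.target}: unknown source {self.source!r}")
        if self.target not in node_ids:
            out.append(f"edge {self.source}->{self.target}: unknown target {self.target!r}")
        if self.sign not in (1, -1):
            out.append(f"edge {self.source}->{self.target}: sign must be +1 or -1")
        if not self.weight > 0:
            out.append(f"edge {self.source}->{self.target}: weight must be > 0")
        if self.source == self.target and not allow_self_loops:
            out.append(f"edge {self.source}->{self.target}: self-loop not allowed")
        return out


@dataclass
class SignalingNetwork:
    """Collection of nodes and signed edges plus pathway-module bookkeeping."""

    nodes: dict[str, NodeSpec] = field(default_factory=dict)
    edges: list[EdgeSpec] = field(default_factory=list)
    modules: dict[str, list[str]] = field(default_factory=dict)
    allow_self_loops: bool = False

    # -- construction helpers -------------------------------------------------

    def add_node(self, node: NodeSpec) -> None:
        if node.id in self.nodes:
            raise ValidationError([f"duplicate node id {node.id!r}"])
        self.nodes[node.id] = node
        if node.module:
            self.modules.setdefault(node.module, []).append(node.id)

    def add_edge(self, edge: EdgeSpec) -> None:
        self.edges.append(edge)

    # -- interrogation --------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return list(self.nodes)

    def readout_ids(self, kind: str) -> list[str]:
        return [n.id for n in self.nodes.values() if n.readout == kind]

    def successors(self, node_id: str) -> list[tuple[str, int]]:
        return [(e.target, e.sign) for e in self.edges if e.source == node_id]

    def copy(self) -> "SignalingNetwork":
        return SignalingNetwork(
            nodes={k: replace(v) for k, v in self.nodes.items()},
            edges=[replace(e) for e in self.edges],
            modules={k: list(v) for k, v in self.modules.items()},
            allow_self_loops=self.allow_self_loops,
        )

    def validate(self, require_readouts: bool = True) -> list[str]:
        return validate_network(self, require_readouts=require_readouts)


def validate_network(net: SignalingNetwork, require_readouts: bool = True) -> list[str]:
    """Return a list of invariant violations; empty iff the network is valid.

    ``require_readouts`` demands at least one cell_cycle and one apoptosis
    readout node (needed for simulation but not for pure graph work).
    """
    report: list[str] = []
    for node in net.nodes.values():
        report.extend(node.violations())
    ids = set(net.nodes)
    for edge in net.edges:
        report.extend(edge.violations(ids, net.allow_self_loops))
    if require_readouts:
        for kind in ("cell_cycle", "apoptosis"):
            if not net.readout_ids(kind):
                report.append(f"network has no {kind} readout node")
    return report


# ---------------------------------------------------------------------------
# graph-json (canonical, lossless)
# ---------------------------------------------------------------------------

def network_to_dict(net: SignalingNetwork) -> dict:
    return {
        "format": GRAPH_JSON_FORMAT,
        "version": GRAPH_JSON_VERSION,
        "allow_self_loops": net.allow_self_loops,
        "nodes": [
            {
                "id": n.id,
                "label": n.label,
                "base_activity": n.base_activity,
                "base_concentration": n.base_concentration,
                "activity_min": n.activity_min,
                "activity_max": n.activity_max,
                "role": n.role,
                "module": n.module,
                "readout": n.readout,
            }
            for n in net.nodes.values()
        ],
        "edges": [
            {"source": e.source, "target": e.target, "sign": e.sign, "weight": e.weight}
            for e in net.edges
        ],
        "modules": {k: list(v) for k, v in net.modules.items()},
    }


def network_from_dict(doc: Mapping) -> SignalingNetwork:
    if doc.get("format") != GRAPH_JSON_FORMAT:
        raise FormatError(
            f"not a {GRAPH_JSON_FORMAT} document (format={doc.get('format')!r})"
        )
    if doc.get("version") != GRAPH_JSON_VERSION:
        raise FormatError(f"unsupported schema version {doc.get('version')!r}")
    net = SignalingNetwork(allow_self_loops=bool(doc.get("allow_self_loops", False)))
    for nd in doc.get("nodes", []):
        try:
            net.nodes[nd["id"]] = NodeSpec(**nd)
        except TypeError as exc:
            raise FormatError(f"bad node element {nd!r}: {exc}") from exc
    for ed in doc.get("edges", []):
        try:
            net.edges.append(EdgeSpec(**ed))
        except TypeError as exc:
            raise FormatError(f"bad edge element {ed!r}: {exc}") from exc
    net.modules = {k: list(v) for k, v in doc.get("modules", {}).items()}
    return net


def save_network(net: SignalingNetwork, path: str | Path, format: str = "graph-json") -> None:
    path = Path(path)
    if format == "graph-json":
        path.write_text(json.dumps(network_to_dict(net), indent=1) + "\n")
    elif format == "sif":
        lines = [
            "\t".join([e.source, "activates" if e.sign > 0 else "inhibits", e.target])
            for e in net.edges
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        nx.write_graphml(_to_networkx(net), path)
    else:
        raise FormatError(f"unknown format {format!r}")


def load_network(path: str | Path, format: str = "graph-json") -> SignalingNetwork:
    """Load and validate a network from disk.

    Raises :class:`FormatError` on parse problems and
    :class:`ValidationError` when structural invariants are violated
    (readout completeness is *not* enforced at load time; run
    :func:`validate_network` with ``require_readouts=True`` before
    simulating).
    """
    path = Path(path)
    if format == "graph-json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        net = network_from_dict(doc)
    elif format == "sif":
        net = _load_sif(path)
    elif format == "graphml":
        net = _from_networkx(nx.read_graphml(path))
    else:
        raise FormatError(f"unknown format {format!r}")
    report = validate_network(net, require_readouts=False)
    if report:
        raise ValidationError(report)
    return net


def _load_sif(path: Path) -> SignalingNetwork:
    net = SignalingNetwork()
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 tab-separated fields")
        src, rel, dst = parts
        sign = {"activates": 1, "inhibits": -1, "+": 1, "-": -1}.get(rel)
        if sign is None:
            raise FormatError(f"{path}: line {lineno}: unknown interaction {rel!r}")
        for nid in (src, dst):
            if nid not in seen:
                net.add_node(NodeSpec(id=nid))
                seen.add(nid)
        net.add_edge(EdgeSpec(source=src, target=dst, sign=sign, weight=1.0))
    return net


def _to_networkx(net: SignalingNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in net.nodes.values():
        g.add_node(
            n.id,
            label=n.label,
            base_activity=n.base_activity,
            base_concentration=n.base_concentration,
            activity_min=n.activity_min,
            activity_max=n.activity_max,
            role=n.role,
            module=n.module,
            readout=n.readout,
        )
    for e in net.edges:
        g.add_edge(e.source, e.target, sign=e.sign, weight=e.weight)
    return g


def _from_networkx(g: nx.DiGraph) -> SignalingNetwork:
    net = SignalingNetwork()
    for nid, attrs in g.nodes(data=True):
        spec = NodeSpec(
            id=str(nid),
            label=attrs.get("label", str(nid)),
            base_activity=float(attrs.get("base_activity", 0.5)),
            base_concentration=float(attrs.get("base_concentration", 1.0)),
            activity_min=float(attrs.get("activity_min", 0.0)),
            activity_max=float(attrs.get("activity_max", 1.0)),
            role=attrs.get("role", "neutral"),
            module=attrs.get("module", ""),
            readout=attrs.get("readout", "none"),
        )
        net.add_node(spec)
    for src, dst, attrs in g.edges(data=True):
        net.add_edge(
            EdgeSpec(
                source=str(src),
                target=str(dst),
                sign=int(attrs.get("sign", 1)),
                weight=float(attrs.get("weight", 1.0)),
            )
        )
    return net


# ---------------------------------------------------------------------------
# Signal tracing
# ---------------------------------------------------------------------------

def trace_signal_path(
    net: SignalingNetwork, source: str, sink: str
) -> list[tuple[str, int | None]]:
    """Shortest directed path from ``source`` to ``sink`` with edge signs.

    Returns ``[(node, sign_of_outgoing_edge), ..., (sink, None)]`` for the
    path with the fewest edges; ties are broken by the lexicographically
    smallest node-id sequence.  An empty list means ``sink`` is unreachable.
    The cumulative sign of the path is the product of the edge signs (see
    :func:`path_sign`).
    """
    for nid in (source, sink):
        if nid not in net.nodes:
            raise UnknownNodeError(f"unknown node id {nid!r}")
    # distance-to-sink on the reverse graph, then a greedy lexicographic walk
    radj: dict[str, list[str]] = {}
    sign_of: dict[tuple[str, str], int] = {}
    adj: dict[str, list[str]] = {}
    for e in net.edges:
        radj.setdefault(e.target, []).append(e.source)
        adj.setdefault(e.source, []).append(e.target)
        # parallel edges: keep the first sign deterministically
        sign_of.setdefault((e.source, e.target), e.sign)
    dist = {sink: 0}
    queue = deque([sink])
    while queue:
        cur = queue.popleft()
        for prev in radj.get(cur, []):
            if prev not in dist:
                dist[prev] = dist[cur] + 1
                queue.append(prev)
    if source not in dist:
        return []
    path: list[tuple[str, int | None]] = []
    cur = source
    while cur != sink:
        nxts = sorted(
            t for t in adj.get(cur, []) if dist.get(t, -1) == dist[cur] - 1
        )
        nxt = nxts[0]
        path.append((cur, sign_of[(cur, nxt)]))
        cur = nxt
    path.append((sink, None))
    return path


def path_sign(path: Iterable[tuple[str, int | None]]) -> int:
    """Cumulative sign (product of edge signs) of a traced path."""
    sign = 1
    for _, s in path:
        if s is not None:
            sign *= s
    return sign
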