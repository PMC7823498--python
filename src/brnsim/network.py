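"""Signed biological regulatory networks (BRNs).

A BRN is a directed graph whose nodes are gene products and whose edges carry
a sign: *activation* or *inhibition*.  The node order is part of the model —
it defines the index order of every state vector used by the Boolean and
continuous semantics.

The module reads and writes two interchange formats:

* signed edge-list TSV — three columns ``source<TAB>target<TAB>sign`` with a
  header row (the single-source-of-truth format for the packaged fixture);
* GraphML — yEd-compatible, with the sign carried as the edge attribute
  ``sign`` (values ``activation``/``inhibition``).

The packaged fixture, :func:`ip3r_reference_network`, is the IP3R-centred
calcium-signalling network whose simulation reproduces the
proliferation-versus-apoptosis switch: IP3R releases Ca2+ from the ER, Ca2+
drives the calmodulin/CaMK-II and calcineurin/NFAT proliferative arms, and
loss of Ca2+ de-represses BAD, firing the intrinsic apoptotic cascade
BAX -> MOMP -> cytochrome c -> apoptosis.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

ACTIVATION = "activation"
INHIBITION = "inhibition"
VALID_SIGNS = (ACTIVATION, INHIBITION)


class NetworkValidationError(ValueError):
    """A network (or state vector) violates a structural invariant."""


class NetworkParseError(ValueError):
    """A network file could not be parsed."""


@dataclass(frozen=True)
class Interaction:
    """One signed directed edge: ``source`` activates or inhibits ``target``."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in VALID_SIGNS:
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: unknown sign "
                f"{self.sign!r}; expected one of {VALID_SIGNS}"
            )


class RegulatoryNetwork:
    """A signed digraph plus per-node Boolean logic.

    Parameters
    ----------
    nodes
        Ordered node names; the order defines state-vector indexing.
    edges
        Signed interactions; every endpoint must be a declared node and a
        given (source, target) pair may appear at most once (dual-sign
        regulation is rejected — it would make the Boolean semantics
        ambiguous).
    logic
        Optional map node -> LogicRule.  When omitted, the default
        OR/AND-NOT rules are attached (see :mod:`brnsim.logic`).
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[Interaction],
        logic: Mapping[str, "LogicRule"] | None = None,
    ) -> None:
        self.nodes: list[str] = list(nodes)
        self.edges: list[Interaction] = list(edges)
        self._validate_structure()
        self._index = {name: i for i, name in enumerate(self.nodes)}
        if logic is None:
            from .logic import default_logic_rule

            logic = {n: default_logic_rule(self, n) for n in self.nodes}
        self.logic: dict[str, "LogicRule"] = dict(logic)

    # -- structure -------------------------------------------------------

    def _validate_structure(self) -> None:
        if any(not isinstance(n, str) or not n for n in self.nodes):
            raise NetworkValidationError("node names must be non-empty strings")
        if len(set(self.nodes)) != len(self.nodes):
            dupes = sorted({n for n in self.nodes if self.nodes.count(n) > 1})
            raise NetworkValidationError(f"duplicate node names: {dupes}")
        declared = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in declared:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target}: undeclared node "
                        f"{endpoint!r}"
                    )
            if (e.source, e.target) in seen:
                raise NetworkValidationError(
                    f"duplicate edge {e.source}->{e.target} "
                    "(dual/multi regulation is rejected)"
                )
            seen.add((e.source, e.target))

    def index(self, node: str) -> int:
        return self._index[node]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def activators_of(self, node: str) -> list[str]:
        return [e.source for e in self.edges if e.target == node and e.sign == ACTIVATION]

    def inhibitors_of(self, node: str) -> list[str]:
        return [e.source for e in self.edges if e.target == node and e.sign == INHIBITION]

    def parents_of(self, node: str) -> list[str]:
        return [e.source for e in self.edges if e.target == node]

    def to_digraph(self) -> nx.DiGraph:
        """The underlying networkx digraph (sign as edge attribute)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and set(self.edges) == set(other.edges)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"RegulatoryNetwork({self.n_nodes} nodes, "
            f"{len(self.edges)} edges)"
        )


@dataclass
class ActivityState:
    """A complete assignment node -> activity level in the closed interval [0, 1]."""

    values: dict[str, float] = field(default_factory=dict)

    def validate(self, net: RegulatoryNetwork) -> "ActivityState":
        missing = [n for n in net.nodes if n not in self.values]
        if missing:
            raise NetworkValidationError(f"state missing nodes: {missing}")
        bad = {n: v for n, v in self.values.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise NetworkValidationError(f"activities outside [0, 1]: {bad}")
        return self

    def as_vector(self, net: RegulatoryNetwork):
        import numpy as np

        return np.array([self.values[n] for n in net.nodes], dtype=float)

    @classmethod
    def from_vector(cls, net: RegulatoryNetwork, vec) -> "ActivityState":
        return cls({n: float(v) for n, v in zip(net.nodes, vec)})

    @classmethod
    def zeros(cls, net: RegulatoryNetwork) -> "ActivityState":
        return cls({n: 0.0 for n in net.nodes})


# -- readers / writers ---------------------------------------------------


def _read_edge_tsv(path: Path) -> RegulatoryNetwork:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise NetworkParseError(f"{path}: empty file (expected a header row)")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:3]] != ["source", "target", "sign"]:
        raise NetworkParseError(
            f"{path}:1: expected header 'source<TAB>target<TAB>sign', got {lines[0]!r}"
        )
    nodes: list[str] = []
    declared_order: list[str] | None = None
    edges: list[Interaction] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if raw.startswith("#!"):
            # structured directive: "#! nodes<TAB>n1<TAB>n2..." pins the node
            # order (and isolated nodes) that plain edge rows cannot express
            parts = raw[2:].strip().split("\t")
            if parts and parts[0] == "nodes":
                declared_order = [p for p in parts[1:] if p]
            continue
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise NetworkParseError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {raw!r}"
            )
        source, target, sign = (p.strip() for p in parts[:3])
        if sign not in VALID_SIGNS:
            raise NetworkValidationError(
                f"{path}:{lineno}: unknown sign label {sign!r}"
            )
        for n in (source, target):
            if n not in nodes:
                nodes.append(n)
        edges.append(Interaction(source, target, sign))
    if declared_order is not None:
        extra = [n for n in nodes if n not in declared_order]
        if extra:
            raise NetworkParseError(
                f"{path}: edge nodes missing from '#! nodes' directive: {extra}"
            )
        nodes = declared_order
    return RegulatoryNetwork(nodes, edges)


def _read_graphml(path: Path) -> RegulatoryNetwork:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise NetworkParseError(f"{path}: malformed GraphML: {exc}") from exc
    if not g.is_directed():
        raise NetworkParseError(f"{path}: GraphML graph must be directed")
    # preserve declared node order (networkx keeps insertion order)
    nodes = [str(n) for n in g.nodes]
    edges = []
    for u, v, data in g.edges(data=True):
        sign = data.get("sign")
        if sign not in VALID_SIGNS:
            raise NetworkValidationError(
                f"{path}: edge {u}->{v}: missing or unknown 'sign' "
                f"attribute {sign!r}"
            )
        edges.append(Interaction(str(u), str(v), sign))
    return RegulatoryNetwork(nodes, edges)


def load_network(path: str | Path, format: str | None = None) -> RegulatoryNetwork:
    """Load a validated RegulatoryNetwork from ``path``.

    ``format`` is ``"graphml"`` or ``"edge_tsv"``; when omitted it is
    inferred from the file suffix.  Default logic rules are attached.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "edge_tsv"
    if format == "graphml":
        return _read_graphml(path)
    if format == "edge_tsv":
        return _read_edge_tsv(path)
    raise ValueError(f"unknown format {format!r}; expected 'graphml' or 'edge_tsv'")


def write_network(net: RegulatoryNetwork, path: str | Path, format: str | None = None) -> None:
    """Write ``net`` so that :func:`load_network` round-trips it losslessly."""
    net._validate_structure()
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "edge_tsv"
    if format == "edge_tsv":
        lines = ["source\ttarget\tsign"]
        if net.nodes:
            lines.append("#! nodes\t" + "\t".join(net.nodes))
        lines += [f"{e.source}\t{e.target}\t{e.sign}" for e in net.edges]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "graphml":
        nx.write_graphml(net.to_digraph(), path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'graphml' or 'edge_tsv'")


def ip3r_reference_network() -> RegulatoryNetwork:
    """The packaged IP3R calcium-signalling network.

    Reconstructed from the published figure and narrative (the authoritative
    appendix edge list is not public); the edge list ships as an annotated
    TSV fixture so it can be amended without code changes.  A constitutively
    clamped ``Stimulus`` source node stands for ligand binding upstream of
    IP3R; ``Cyto.C`` self-activates because cytochrome-c release is
    irreversible, which is what latches the apoptotic outcome.
    """
    ref = importlib.resources.files("brnsim.data") / "ip3r_network.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_network(p, format="edge_tsv")
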