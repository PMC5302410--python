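"""Signed Boolean network data model and the plain-text definition format.

A network is a signed directed graph whose nodes are partitioned into
*control* nodes (inputs whose state is fixed for an entire run; they model
external hormonal or peptidic signals) and *internal* nodes (genes,
proteins or processes whose state evolves under the update rule).  Each
edge carries a sign: ``+1`` for activation, ``-1`` for inhibition.

The on-disk format is line oriented::

    # comment
    [nodes]
    CK0   control
    CK    internal
    [edges]
    CK0 -> CK     # activation
    CKX -| CK     # inhibition

Node declaration order is significant: it fixes the bit position of every
internal node in integer state encodings, so re-parsing a file always
reproduces the same encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "ROLE_CONTROL",
    "ROLE_INTERNAL",
    "Node",
    "Edge",
    "BooleanNetwork",
    "RegulatorSummary",
    "NetworkError",
    "NetworkFormatError",
    "NetworkValidationError",
    "parse_network",
    "write_network",
    "regulator_summary",
    "to_sif",
]

ROLE_CONTROL = "control"
ROLE_INTERNAL = "internal"


class NetworkError(ValueError):
    """Base class for network construction and parsing errors."""


class NetworkFormatError(NetworkError):
    """Raised on malformed network-definition text; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NetworkValidationError(NetworkError):
    """Raised when a structurally invalid network is constructed."""


@dataclass(frozen=True)
class Node:
    """A named node with a role of ``"control"`` or ``"internal"``."""

    name: str
    role: str

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise NetworkValidationError("node name must be a non-empty string")
        if any(ch.isspace() for ch in self.name):
            raise NetworkValidationError(
                f"node name {self.name!r} must not contain whitespace"
            )
        if self.role not in (ROLE_CONTROL, ROLE_INTERNAL):
            raise NetworkValidationError(
                f"node {self.name!r}: role must be 'control' or 'internal', "
                f"got {self.role!r}"
            )


@dataclass(frozen=True)
class Edge:
    """A signed directed edge; ``sign`` is +1 (activation) or -1 (inhibition)."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: sign must be +1 or -1, "
                f"got {self.sign!r}"
            )


@dataclass(frozen=True)
class RegulatorSummary:
    """The regulator set of one internal node, with the update threshold.

    ``threshold`` is the exact rational ``n/2 - m`` where ``n`` is the
    number of regulators and ``m`` the number of inhibitory ones; the
    target switches on exactly when the signed regulator sum strictly
    exceeds it.
    """

    target: str
    regulators: tuple[tuple[str, int], ...]
    n: int
    m: int
    threshold: Fraction


class BooleanNetwork:
    """An immutable validated signed Boolean network.

    Parameters
    ----------
    nodes
        Nodes in declaration order.  Order is preserved and determines
        integer state encodings (bit *k* of the internal encoding is the
        *k*-th declared internal node).
    edges
        Signed edges.  At most one edge per ordered (source, target) pair;
        each regulator of a node counts once in the update rule.  Control
        nodes must have in-degree zero.  Self-loops are allowed.
    """

    def __init__(self, nodes: Iterable[Node], edges: Iterable[Edge] = ()):
        self._nodes: tuple[Node, ...] = tuple(nodes)
        self._edges: tuple[Edge, ...] = tuple(edges)
        seen: set[str] = set()
        for node in self._nodes:
            if node.name in seen:
                raise NetworkValidationError(f"duplicate node {node.name!r}")
            seen.add(node.name)
        self._index: dict[str, int] = {n.name: i for i, n in enumerate(self._nodes)}
        self._roles: dict[str, str] = {n.name: n.role for n in self._nodes}
        self._internal: tuple[str, ...] = tuple(
            n.name for n in self._nodes if n.role == ROLE_INTERNAL
        )
        self._control: tuple[str, ...] = tuple(
            n.name for n in self._nodes if n.role == ROLE_CONTROL
        )
        if not self._internal:
            raise NetworkValidationError("network must have at least one internal node")
        self._internal_bit = {name: k for k, name in enumerate(self._internal)}
        self._control_bit = {name: j for j, name in enumerate(self._control)}

        pair_seen: set[tuple[str, str]] = set()
        regulators: dict[str, list[tuple[str, int]]] = {n.name: [] for n in self._nodes}
        for edge in self._edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self._index:
                    raise NetworkValidationError(
                        f"edge {edge.source}->{edge.target} references unknown "
                        f"node {endpoint!r}"
                    )
            if self._roles[edge.target] == ROLE_CONTROL:
                raise NetworkValidationError(
                    f"control node {edge.target!r} cannot be regulated "
                    f"(edge from {edge.source!r})"
                )
            pair = (edge.source, edge.target)
            if pair in pair_seen:
                raise NetworkValidationError(
                    f"duplicate edge {edge.source} -> {edge.target}"
                )
            pair_seen.add(pair)
            regulators[edge.target].append((edge.source, edge.sign))
        self._regulators = {k: tuple(v) for k, v in regulators.items()}
        self._summary_cache: dict[str, RegulatorSummary] = {}

    # -- basic accessors ------------------------------------------------

    @property
    def nodes(self) -> tuple[Node, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[Edge, ...]:
        return self._edges

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self._nodes)

    @property
    def control_names(self) -> tuple[str, ...]:
        return self._control

    @property
    def internal_names(self) -> tuple[str, ...]:
        return self._internal

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_internal(self) -> int:
        return len(self._internal)

    @property
    def n_control(self) -> int:
        return len(self._control)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def role(self, name: str) -> str:
        self._require(name)
        return self._roles[name]

    def is_control(self, name: str) -> bool:
        return self.role(name) == ROLE_CONTROL

    def internal_bit(self, name: str) -> int:
        """Bit position of an internal node in the internal state encoding."""
        self._require(name)
        if name not in self._internal_bit:
            raise NetworkValidationError(f"{name!r} is not an internal node")
        return self._internal_bit[name]

    def control_bit(self, name: str) -> int:
        self._require(name)
        if name not in self._control_bit:
            raise NetworkValidationError(f"{name!r} is not a control node")
        return self._control_bit[name]

    def regulators(self, target: str) -> tuple[tuple[str, int], ...]:
        """Regulators of ``target`` as (source, sign) pairs in edge order."""
        self._require(target)
        return self._regulators[target]

    def regulator_summary(self, target: str) -> RegulatorSummary:
        """Regulator set and update threshold of an internal node."""
        self._require(target)
        if self._roles[target] == ROLE_CONTROL:
            raise NetworkValidationError(
                f"control node {target!r} has no update rule"
            )
        cached = self._summary_cache.get(target)
        if cached is not None:
            return cached
        regs = self._regulators[target]
        n = len(regs)
        m = sum(1 for _, sign in regs if sign == -1)
        summary = RegulatorSummary(
            target=target,
            regulators=regs,
            n=n,
            m=m,
            threshold=Fraction(n, 2) - m,
        )
        self._summary_cache[target] = summary
        return summary

    def _require(self, name: str) -> None:
        if name not in self._index:
            raise NetworkValidationError(f"unknown node {name!r}")

    # -- conversions ----------------------------------------------------

    def to_graph(self) -> nx.DiGraph:
        """The network as a :class:`networkx.DiGraph` with ``sign`` edge data."""
        g = nx.DiGraph()
        for node in self._nodes:
            g.add_node(node.name, role=node.role)
        for edge in self._edges:
            g.add_edge(edge.source, edge.target, sign=edge.sign)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return self._nodes == other._nodes and set(self._edges) == set(other._edges)

    def __hash__(self) -> int:  # pragma: no cover - identity use only
        return hash((self._nodes, frozenset(self._edges)))

    def __repr__(self) -> str:
        return (
            f"<BooleanNetwork N={self.n_nodes} "
            f"({self.n_control} control, {self.n_internal} internal), "
            f"{len(self._edges)} edges>"
        )


# -- file format --------------------------------------------------------

_REL_TO_SIGN = {"->": 1, "-|": -1}
_SIGN_TO_REL = {1: "->", -1: "-|"}


def _strip_comment(line: str) -> str:
    pos = line.find("#")
    return line if pos < 0 else line[:pos]


def parse_network(text: str) -> BooleanNetwork:
    """Parse a network-definition document into a validated network.

    Raises :class:`NetworkFormatError` (with a line number) on syntax
    problems and :class:`NetworkValidationError` on structural ones.
    """
    nodes: list[Node] = []
    edges: list[Edge] = []
    node_names: set[str] = set()
    section: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if line.startswith("["):
            if line not in ("[nodes]", "[edges]"):
                raise NetworkFormatError(f"unknown section {line!r}", lineno)
            section = line[1:-1]
            continue
        if section is None:
            raise NetworkFormatError(
                "content before any [nodes]/[edges] section header", lineno
            )
        tokens = line.split()
        if section == "nodes":
            if len(tokens) != 2:
                raise NetworkFormatError(
                    f"expected 'NAME control|internal', got {line!r}", lineno
                )
            name, role = tokens
            if role not in (ROLE_CONTROL, ROLE_INTERNAL):
                raise NetworkFormatError(
                    f"node role must be 'control' or 'internal', got {role!r}",
                    lineno,
                )
            if name in node_names:
                raise NetworkFormatError(f"duplicate node {name!r}", lineno)
            node_names.add(name)
            nodes.append(Node(name, role))
        else:
            if len(tokens) != 3 or tokens[1] not in _REL_TO_SIGN:
                raise NetworkFormatError(
                    f"expected 'SOURCE -> TARGET' or 'SOURCE -| TARGET', "
                    f"got {line!r}",
                    lineno,
                )
            src, rel, tgt = tokens
            for endpoint in (src, tgt):
                if endpoint not in node_names:
                    raise NetworkFormatError(
                        f"edge references undeclared node {endpoint!r}", lineno
                    )
            edges.append(Edge(src, tgt, _REL_TO_SIGN[rel]))
    if not nodes:
        raise NetworkFormatError("document declares no nodes")
    return BooleanNetwork(nodes, edges)


def write_network(net: BooleanNetwork) -> str:
    """Serialize a network; ``parse_network(write_network(net)) == net``."""
    width = max(len(n.name) for n in net.nodes)
    lines = ["[nodes]"]
    lines += [f"{n.name:<{width}}  {n.role}" for n in net.nodes]
    lines.append("")
    lines.append("[edges]")
    lines += [
        f"{e.source:<{width}}  {_SIGN_TO_REL[e.sign]}  {e.target}" for e in net.edges
    ]
    return "\n".join(lines) + "\n"


def to_sif(net: BooleanNetwork) -> str:
    """Lossless 3-column (source, relation, target) tab-separated export."""
    relation = {1: "activates", -1: "inhibits"}
    return "".join(
        f"{e.source}\t{relation[e.sign]}\t{e.target}\n" for e in net.edges
    )


def regulator_summary(net: BooleanNetwork, target: str) -> RegulatorSummary:
    """Module-level convenience for :meth:`BooleanNetwork.regulator_summary`."""
    return net.regulator_summary(target)
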