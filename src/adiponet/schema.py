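"""Typed, signed, directed network model for layered adipokine knowledge graphs.

The network schema has six node categories arranged in layers — upstream
physiologic perturbations and sleep disturbances act on adipokines, which
signal to molecular targets, which modulate physiologic functions, which in
turn feed disease processes.  Edges are directed and carry a sign
(positive / negative / uncertain association); only a fixed set of
category-to-category transitions is admissible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Iterable, Tuple

__all__ = [
    "NodeCategory",
    "EdgeSign",
    "ALLOWED_TRANSITIONS",
    "allowed_transition",
    "normalize_name",
    "TypedNetwork",
    "validate",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when input data cannot be mapped onto the layered schema."""


class NodeCategory(str, Enum):
    """The six node categories of the layered network."""

    PHYSIOLOGIC_PERTURBATION = "physiologic_perturbation"
    SLEEP_DISTURBANCE = "sleep_disturbance"
    ADIPOKINE = "adipokine"
    MOLECULAR_TARGET = "molecular_target"
    PHYSIOLOGIC_FUNCTION = "physiologic_function"
    DISEASE_PROCESS = "disease_process"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class EdgeSign(str, Enum):
    """Sign of a directed association."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNCERTAIN = "uncertain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Closed-world set of admissible (source-category, target-category) layer
#: transitions.  Anything not listed is rejected by :func:`validate`.
#: Curators extending the schema (e.g. adding molecular_target ->
#: disease_process relations) can pass their own transition set to
#: :func:`validate` / :func:`~adiponet.construction.build_network`.
ALLOWED_TRANSITIONS: FrozenSet[Tuple[NodeCategory, NodeCategory]] = frozenset(
    {
        (NodeCategory.PHYSIOLOGIC_PERTURBATION, NodeCategory.ADIPOKINE),
        (NodeCategory.SLEEP_DISTURBANCE, NodeCategory.ADIPOKINE),
        (NodeCategory.ADIPOKINE, NodeCategory.MOLECULAR_TARGET),
        (NodeCategory.MOLECULAR_TARGET, NodeCategory.PHYSIOLOGIC_FUNCTION),
        (NodeCategory.PHYSIOLOGIC_FUNCTION, NodeCategory.DISEASE_PROCESS),
        (NodeCategory.ADIPOKINE, NodeCategory.PHYSIOLOGIC_FUNCTION),
        (NodeCategory.ADIPOKINE, NodeCategory.DISEASE_PROCESS),
    }
)

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalization key for entity names: trim, collapse whitespace, casefold.

    Display names are case-preserving; comparisons use this key, so
    ``"AMPK "`` and ``"ampk"`` denote the same entity.
    """
    return _WS.sub(" ", name.strip()).casefold()


def allowed_transition(src: NodeCategory, dst: NodeCategory) -> bool:
    """Whether a directed edge may run from category *src* to category *dst*."""
    return (NodeCategory(src), NodeCategory(dst)) in ALLOWED_TRANSITIONS


@dataclass
class TypedNetwork:
    """Directed signed graph whose nodes carry one of six categories.

    Attributes
    ----------
    nodes:
        Mapping of entity display name to its :class:`NodeCategory`.
    edges:
        Mapping of ordered ``(source, target)`` name pairs to
        :class:`EdgeSign`; the dict keying enforces at most one edge per
        ordered pair.
    """

    nodes: dict[str, NodeCategory] = field(default_factory=dict)
    edges: dict[tuple[str, str], EdgeSign] = field(default_factory=dict)

    # -- degree accessors -------------------------------------------------
    def in_degree(self, node: str) -> int:
        return sum(1 for (_, v) in self.edges if v == node)

    def out_degree(self, node: str) -> int:
        return sum(1 for (u, _) in self.edges if u == node)

    def degree(self, node: str) -> int:
        return self.in_degree(node) + self.out_degree(node)

    @property
    def node_weights(self) -> dict[str, int]:
        """Display weight per node: proportional to (equal to) total degree."""
        w = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            if u in w:
                w[u] += 1
            if v in w:
                w[v] += 1
        return w

    def successors(self) -> dict[str, list[str]]:
        """Adjacency lists, deterministically sorted by node name."""
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for u, v in self.edges:
            adj[u].append(v)
        for n in adj:
            adj[n].sort()
        return adj

    def copy(self) -> "TypedNetwork":
        return TypedNetwork(dict(self.nodes), dict(self.edges))

    def __len__(self) -> int:
        return len(self.nodes)


def validate(
    network: TypedNetwork,
    transitions: Iterable[Tuple[NodeCategory, NodeCategory]] = ALLOWED_TRANSITIONS,
) -> list[str]:
    """Check all structural invariants; return human-readable violations.

    An empty list means the network is schema-valid.  Violations are
    returned (not raised) so callers can report them all at once.
    """
    allowed = frozenset(transitions)
    violations: list[str] = []
    for (u, v), sign in network.edges.items():
        if u == v:
            violations.append(f"self-loop: edge {u!r}->{v!r}")
            continue
        missing = [n for n in (u, v) if n not in network.nodes]
        if missing:
            for n in missing:
                violations.append(f"unknown endpoint: node {n!r} of edge {u!r}->{v!r}")
            continue
        pair = (network.nodes[u], network.nodes[v])
        if pair not in allowed:
            violations.append(
                f"disallowed transition: edge {u!r}->{v!r} "
                f"({pair[0].value} -> {pair[1].value})"
            )
        if not isinstance(sign, EdgeSign):
            violations.append(f"invalid sign on edge {u!r}->{v!r}: {sign!r}")
    # duplicate entities under name normalization
    seen: dict[str, str] = {}
    for name in network.nodes:
        key = normalize_name(name)
        if key in seen and seen[key] != name:
            violations.append(
                f"duplicate entity under normalization: {seen[key]!r} vs {name!r}"
            )
        seen.setdefault(key, name)
    return violations
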