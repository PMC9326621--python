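"""Build a validated :class:`~adiponet.schema.TypedNetwork` from curated assertions.

An assertion table is the raw product of literature curation: one row per
directed signed relation between two named, typed entities.  Construction
follows the layered edge-creation procedure — upstream perturbations and
sleep disturbances point at adipokines, adipokines at their molecular
targets, targets at physiologic functions, functions at disease processes,
plus "shortcut" edges from an adipokine directly to a function or disease
when the mediating mechanism is unknown.

Duplicates collapse to one edge.  An ordered pair asserted with both a
positive and a negative sign is a contradiction and is resolved by a
configurable policy; an ``uncertain`` sign never contradicts a definite one
(the definite sign wins on deduplication).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .schema import (
    ALLOWED_TRANSITIONS,
    EdgeSign,
    NodeCategory,
    SchemaError,
    TypedNetwork,
    allowed_transition,
    normalize_name,
    validate,
)

__all__ = [
    "AssertionRecord",
    "ConflictRecord",
    "build_network",
    "assert_chain",
    "to_assertions",
]

ConflictPolicy = Literal["drop_edge", "exclude_node"]


@dataclass(frozen=True)
class AssertionRecord:
    """One curated directed signed relation between two typed entities."""

    source: str
    source_category: NodeCategory
    target: str
    target_category: NodeCategory
    sign: EdgeSign = EdgeSign.UNCERTAIN
    provenance: str = ""

    def __post_init__(self) -> None:
        if normalize_name(self.source) == normalize_name(self.target):
            raise SchemaError(
                f"assertion source equals target after normalization: {self.source!r}"
            )


@dataclass(frozen=True)
class ConflictRecord:
    """A contradictory ordered pair (asserted both positive and negative)."""

    source: str
    target: str
    signs_seen: frozenset[EdgeSign]
    resolution: Literal["edge_dropped", "node_excluded"]


def _merge_signs(a: EdgeSign, b: EdgeSign) -> EdgeSign | None:
    """Combine two signs for the same ordered pair; None marks a contradiction."""
    if a == b:
        return a
    if EdgeSign.UNCERTAIN in (a, b):
        # a definite sign overrides uncertain
        return a if b == EdgeSign.UNCERTAIN else b
    return None  # positive vs negative


def build_network(
    assertions: Iterable[AssertionRecord],
    conflict_policy: ConflictPolicy = "drop_edge",
    exclude_side: Literal["source", "target", "both"] = "target",
) -> tuple[TypedNetwork, list[ConflictRecord]]:
    """Assemble a schema-valid network from an assertion table.

    Parameters
    ----------
    assertions:
        Curated relations.  Every record must describe an admissible layer
        transition; the same entity name (case-insensitively) must always
        carry the same category.
    conflict_policy:
        ``"drop_edge"`` removes only the contradictory edge;
        ``"exclude_node"`` additionally removes the node(s) on
        *exclude_side* of the contradiction together with all their
        incident edges, mirroring the stricter curation rule of dropping
        entities with inconsistent reported relations.

    Returns
    -------
    (network, conflicts):
        The validated network and a log of every contradiction resolved.

    Notes
    -----
    The result is independent of the order of the assertion list.
    """
    if conflict_policy not in ("drop_edge", "exclude_node"):
        raise ValueError(f"unknown conflict policy: {conflict_policy!r}")

    # canonical display name per normalized key (lexicographically smallest
    # spelling wins, making the build order-invariant)
    display: dict[str, str] = {}
    categories: dict[str, NodeCategory] = {}
    signs: dict[tuple[str, str], set[EdgeSign]] = {}

    records = list(assertions)
    for rec in records:
        for name, cat in (
            (rec.source, NodeCategory(rec.source_category)),
            (rec.target, NodeCategory(rec.target_category)),
        ):
            key = normalize_name(name)
            if key in categories and categories[key] != cat:
                raise SchemaError(
                    f"entity {name!r} used with two categories: "
                    f"{categories[key].value} and {cat.value}"
                )
            categories[key] = cat
            if key not in display or name < display[key]:
                display[key] = name
        if not allowed_transition(rec.source_category, rec.target_category):
            raise SchemaError(
                f"disallowed transition in assertion {rec.source!r}->{rec.target!r}: "
                f"{NodeCategory(rec.source_category).value} -> "
                f"{NodeCategory(rec.target_category).value}"
            )

    for rec in records:
        pair = (normalize_name(rec.source), normalize_name(rec.target))
        signs.setdefault(pair, set()).add(EdgeSign(rec.sign))

    conflicts: list[ConflictRecord] = []
    resolution = "edge_dropped" if conflict_policy == "drop_edge" else "node_excluded"
    excluded_keys: set[str] = set()
    edges: dict[tuple[str, str], EdgeSign] = {}

    for (skey, tkey), seen in sorted(signs.items()):
        merged: EdgeSign | None = None
        definite = seen - {EdgeSign.UNCERTAIN}
        if len(definite) == 2:
            merged = None  # positive and negative both asserted
        elif definite:
            merged = next(iter(definite))
        else:
            merged = EdgeSign.UNCERTAIN
        if merged is None:
            conflicts.append(
                ConflictRecord(
                    source=display[skey],
                    target=display[tkey],
                    signs_seen=frozenset(seen),
                    resolution=resolution,
                )
            )
            if conflict_policy == "exclude_node":
                if exclude_side in ("source", "both"):
                    excluded_keys.add(skey)
                if exclude_side in ("target", "both"):
                    excluded_keys.add(tkey)
        else:
            edges[(display[skey], display[tkey])] = merged

    nodes = {
        display[key]: cat
        for key, cat in categories.items()
        if key not in excluded_keys
    }
    edges = {
        (u, v): s
        for (u, v), s in edges.items()
        if normalize_name(u) not in excluded_keys
        and normalize_name(v) not in excluded_keys
    }
    network = TypedNetwork(nodes=dict(sorted(nodes.items())), edges=dict(sorted(edges.items())))
    problems = validate(network)
    if problems:  # pragma: no cover - guarded by the checks above
        raise SchemaError("constructed network failed validation: " + "; ".join(problems))
    return network, conflicts


def assert_chain(
    adipokine: str,
    path: Sequence[tuple[str, NodeCategory]],
    sign: EdgeSign = EdgeSign.UNCERTAIN,
    provenance: str = "",
) -> list[AssertionRecord]:
    """Expand a mechanism chain into individual assertion records.

    ``assert_chain("leptin", [("AMPK", molecular_target), ("insulin
    signaling", physiologic_function)])`` yields the two records
    leptin→AMPK and AMPK→insulin signaling.  A single-element path with a
    function or disease target expresses the shortcut edge used when the
    mediating mechanism is unknown.
    """
    hops: list[tuple[str, NodeCategory]] = [(adipokine, NodeCategory.ADIPOKINE)]
    hops.extend((name, NodeCategory(cat)) for name, cat in path)
    records: list[AssertionRecord] = []
    for (sname, scat), (tname, tcat) in zip(hops, hops[1:]):
        if not allowed_transition(scat, tcat):
            raise SchemaError(
                f"broken chain: {scat.value} -> {tcat.value} "
                f"({sname!r} -> {tname!r}) is not an admissible transition"
            )
        records.append(
            AssertionRecord(
                source=sname,
                source_category=scat,
                target=tname,
                target_category=tcat,
                sign=sign,
                provenance=provenance,
            )
        )
    return records


def to_assertions(network: TypedNetwork, provenance: str = "") -> list[AssertionRecord]:
    """Flatten a network back into an assertion table (inverse of build)."""
    return [
        AssertionRecord(
            source=u,
            source_category=network.nodes[u],
            target=v,
            target_category=network.nodes[v],
            sign=s,
            provenance=provenance,
        )
        for (u, v), s in sorted(network.edges.items())
    ]
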