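"""Seeded generator of layered signed networks with planted structure.

The generator emulates the statistical shape of a literature-curated
adipokine network: six node categories (default split totalling 94 nodes),
a fixed directed-edge budget (default 264), adipokine attachment weights
following a Zipf law so a small number of adipokines dominate the degree
distribution (the leptin/adiponectin pattern), a configurable fraction of
"shortcut" adipokine->function/disease edges, and one planted low-degree
"bridge" molecular target wired between the planted hub adipokines and a
pair of functions reachable only through it (the AMPK pattern: low degree,
high betweenness).

All randomness flows through one numpy Generator seeded from the config,
so generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .construction import AssertionRecord
from .schema import EdgeSign, NodeCategory, SchemaError

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "figure1_fixtures"]

_C = NodeCategory

DEFAULT_LAYER_SIZES: dict[NodeCategory, int] = {
    _C.PHYSIOLOGIC_PERTURBATION: 6,
    _C.SLEEP_DISTURBANCE: 4,
    _C.ADIPOKINE: 6,
    _C.MOLECULAR_TARGET: 28,
    _C.PHYSIOLOGIC_FUNCTION: 25,
    _C.DISEASE_PROCESS: 25,
}

_PREFIX = {
    _C.PHYSIOLOGIC_PERTURBATION: "perturbation",
    _C.SLEEP_DISTURBANCE: "sleep",
    _C.ADIPOKINE: "adipokine",
    _C.MOLECULAR_TARGET: "target",
    _C.PHYSIOLOGIC_FUNCTION: "function",
    _C.DISEASE_PROCESS: "disease",
}

# split of the non-shortcut edge budget across the chain transitions:
# perturbation->adipokine, sleep->adipokine, adipokine->target,
# target->function, function->disease
_CHAIN_SPLIT = {
    (_C.PHYSIOLOGIC_PERTURBATION, _C.ADIPOKINE): 0.14,
    (_C.SLEEP_DISTURBANCE, _C.ADIPOKINE): 0.09,
    (_C.ADIPOKINE, _C.MOLECULAR_TARGET): 0.26,
    (_C.MOLECULAR_TARGET, _C.PHYSIOLOGIC_FUNCTION): 0.28,
    (_C.PHYSIOLOGIC_FUNCTION, _C.DISEASE_PROCESS): 0.23,
}

_MAX_ATTEMPTS = 10**6


class CapacityError(ValueError):
    """Edge budget exceeds the number of admissible ordered pairs."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the layered-network generator.

    layer_sizes default to a 94-node split with six adipokines;
    ``edge_budget`` is the exact number of directed edges generated;
    ``hub_skew`` is the Zipf exponent over adipokine attachment weights
    (>= 1; larger means stronger hub dominance); ``planted_hub_count``
    adipokines occupy the top Zipf ranks and are reported as ground
    truth; ``shortcut_edge_fraction`` is the share of the budget spent on
    direct adipokine->function/disease edges; ``sign_probs`` are the
    (positive, negative, uncertain) label probabilities.
    """

    layer_sizes: dict[NodeCategory, int] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_SIZES)
    )
    edge_budget: int = 264
    hub_skew: float = 1.6
    planted_hub_count: int = 2
    shortcut_edge_fraction: float = 0.2
    sign_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.sign_probs) - 1.0) > 1e-12:
            raise ValueError("sign_probs must sum to 1")
        if self.hub_skew < 1.0:
            raise ValueError("hub_skew must be >= 1")
        if not 0.0 <= self.shortcut_edge_fraction <= 1.0:
            raise ValueError("shortcut_edge_fraction must lie in [0, 1]")
        sizes = {_C(k): int(v) for k, v in self.layer_sizes.items()}
        if set(sizes) != set(_C) or any(v < 0 for v in sizes.values()):
            raise ValueError("layer_sizes must give a nonnegative count per category")
        if sizes[_C.ADIPOKINE] < max(self.planted_hub_count, 1):
            raise ValueError("need at least planted_hub_count adipokines")
        if self.planted_hub_count < 1:
            raise ValueError("planted_hub_count must be >= 1")
        if sizes[_C.MOLECULAR_TARGET] < 2 or sizes[_C.PHYSIOLOGIC_FUNCTION] < 3:
            raise ValueError("need >= 2 molecular targets and >= 3 physiologic functions")
        if sizes[_C.DISEASE_PROCESS] < 3:
            raise ValueError("need >= 3 disease processes")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated network."""

    planted_hubs: tuple[str, ...]
    bridge_target: str
    reserved_functions: tuple[str, ...]
    reserved_diseases: tuple[str, ...]


def _largest_remainder(fractions: dict, total: int) -> dict:
    """Integer apportionment of *total* proportional to *fractions*."""
    raw = {k: f * total for k, f in fractions.items()}
    out = {k: int(v) for k, v in raw.items()}
    leftover = total - sum(out.values())
    order = sorted(raw, key=lambda k: (out[k] - raw[k], str(k)))
    for k in order[:leftover]:
        out[k] += 1
    return out


def _names(cat: NodeCategory, n: int) -> list[str]:
    return [f"{_PREFIX[cat]}-{i:02d}" for i in range(1, n + 1)]


def generate(config: SyntheticConfig) -> tuple[list[AssertionRecord], GroundTruth]:
    """Draw one layered network as an assertion table plus its ground truth.

    The procedure plants the bridge motif first (hubs -> bridge -> two
    reserved functions -> two reserved diseases, with the reserved nodes
    receiving no other in-edges so every path to them runs through the
    bridge), then guarantees every node at least one incident edge, then
    fills each transition's quota by weighted rejection sampling,
    resampling duplicate pairs until the exact edge budget is met.
    """
    rng = np.random.default_rng(config.seed)
    sizes = {_C(k): int(v) for k, v in config.layer_sizes.items()}
    names = {cat: _names(cat, sizes[cat]) for cat in _C}

    k = config.planted_hub_count
    hubs = tuple(names[_C.ADIPOKINE][:k])
    bridge = names[_C.MOLECULAR_TARGET][0]
    f_res = tuple(names[_C.PHYSIOLOGIC_FUNCTION][:2])
    d_res = tuple(names[_C.DISEASE_PROCESS][:2])
    truth = GroundTruth(hubs, bridge, f_res, d_res)

    free_targets = names[_C.MOLECULAR_TARGET][1:]
    free_functions = names[_C.PHYSIOLOGIC_FUNCTION][2:]
    free_diseases = names[_C.DISEASE_PROCESS][2:]
    adipokines = names[_C.ADIPOKINE]
    # Zipf attachment weights over adipokines only; downstream pools draw
    # uniformly, keeping the median degree high enough that the planted
    # bridge (degree 4 by construction) stays in the low-degree half
    zipf = np.arange(1, len(adipokines) + 1, dtype=float) ** (-config.hub_skew)
    zipf /= zipf.sum()

    E = int(config.edge_budget)
    planted: list[tuple[str, str]] = (
        [(h, bridge) for h in hubs]
        + [(bridge, f) for f in f_res]
        + [(f, d) for f in f_res for d in d_res]
    )
    n_shortcut = round(config.shortcut_edge_fraction * E)
    n_chain = E - n_shortcut
    if n_chain < len(planted):
        raise CapacityError("edge budget too small for the planted bridge motif")
    quotas = _largest_remainder(_CHAIN_SPLIT, n_chain)
    # planted edges count against their transition's quota
    quotas[(_C.ADIPOKINE, _C.MOLECULAR_TARGET)] -= k
    quotas[(_C.MOLECULAR_TARGET, _C.PHYSIOLOGIC_FUNCTION)] -= 2
    quotas[(_C.PHYSIOLOGIC_FUNCTION, _C.DISEASE_PROCESS)] -= 4
    if any(q < 0 for q in quotas.values()):
        raise CapacityError("edge budget too small for the planted bridge motif")

    # pools of admissible (non-reserved) endpoints per transition
    pools: dict[tuple[NodeCategory, NodeCategory], tuple[list[str], list[str]]] = {
        (_C.PHYSIOLOGIC_PERTURBATION, _C.ADIPOKINE): (
            names[_C.PHYSIOLOGIC_PERTURBATION],
            adipokines,
        ),
        (_C.SLEEP_DISTURBANCE, _C.ADIPOKINE): (names[_C.SLEEP_DISTURBANCE], adipokines),
        (_C.ADIPOKINE, _C.MOLECULAR_TARGET): (adipokines, free_targets),
        (_C.MOLECULAR_TARGET, _C.PHYSIOLOGIC_FUNCTION): (free_targets, free_functions),
        (_C.PHYSIOLOGIC_FUNCTION, _C.DISEASE_PROCESS): (free_functions, free_diseases),
    }
    shortcut_pool = free_functions + free_diseases
    for trans, (srcs, dsts) in pools.items():
        if quotas[trans] > len(srcs) * len(dsts):
            raise CapacityError(
                f"quota for {trans[0].value}->{trans[1].value} exceeds pair capacity"
            )
    if n_shortcut > len(adipokines) * len(shortcut_pool):
        raise CapacityError("shortcut quota exceeds pair capacity")

    edges: dict[tuple[str, str], None] = {}

    def add(u: str, v: str) -> bool:
        if (u, v) in edges:
            return False
        edges[(u, v)] = None
        return True

    for u, v in planted:
        add(u, v)

    def pick(pool: list[str], weights: np.ndarray | None = None) -> str:
        idx = rng.choice(len(pool), p=weights)
        return pool[int(idx)]

    attempts = 0

    def sample_into(
        srcs: list[str],
        dsts: list[str],
        count: int,
        src_w: np.ndarray | None = None,
        dst_w: np.ndarray | None = None,
    ) -> None:
        nonlocal attempts
        added = 0
        while added < count:
            attempts += 1
            if attempts > _MAX_ATTEMPTS:
                raise CapacityError("resampling cap reached; edge budget infeasible")
            if add(pick(srcs, src_w), pick(dsts, dst_w)):
                added += 1

    remaining = dict(quotas)

    # coverage pass: every node incident to at least one edge
    def spend(trans: tuple[NodeCategory, NodeCategory], n: int = 1) -> None:
        remaining[trans] -= n
        if remaining[trans] < 0:
            raise CapacityError(
                f"coverage requires more {trans[0].value}->{trans[1].value} edges "
                "than the quota allows"
            )

    for p in names[_C.PHYSIOLOGIC_PERTURBATION]:
        if add(p, pick(adipokines, zipf)):
            spend((_C.PHYSIOLOGIC_PERTURBATION, _C.ADIPOKINE))
    for s in names[_C.SLEEP_DISTURBANCE]:
        if add(s, pick(adipokines, zipf)):
            spend((_C.SLEEP_DISTURBANCE, _C.ADIPOKINE))
    for t in free_targets:
        if add(pick(adipokines, zipf), t):
            spend((_C.ADIPOKINE, _C.MOLECULAR_TARGET))
    covered = {n for e in edges for n in e}
    for a in adipokines:
        if a not in covered and free_targets:
            sample_into([a], free_targets, 1)
            spend((_C.ADIPOKINE, _C.MOLECULAR_TARGET))
    for f in free_functions:
        if add(pick(free_targets), f):
            spend((_C.MOLECULAR_TARGET, _C.PHYSIOLOGIC_FUNCTION))
    for d in free_diseases:
        if add(pick(free_functions), d):
            spend((_C.PHYSIOLOGIC_FUNCTION, _C.DISEASE_PROCESS))

    # quota fill
    for trans, (srcs, dsts) in pools.items():
        if remaining[trans] <= 0:
            continue
        src_w = zipf if trans[0] == _C.ADIPOKINE else None
        dst_w = zipf if trans[1] == _C.ADIPOKINE else None
        sample_into(srcs, dsts, remaining[trans], src_w=src_w, dst_w=dst_w)

    # shortcut edges: adipokine directly to a function or disease
    sample_into(adipokines, shortcut_pool, n_shortcut, src_w=zipf)

    assert len(edges) == E, "generator accounting error"

    category = {n: cat for cat, pool in names.items() for n in pool}
    sign_labels = [EdgeSign.POSITIVE, EdgeSign.NEGATIVE, EdgeSign.UNCERTAIN]
    sign_idx = rng.choice(3, size=E, p=np.asarray(config.sign_probs, dtype=float))
    records = [
        AssertionRecord(
            source=u,
            source_category=category[u],
            target=v,
            target_category=category[v],
            sign=sign_labels[int(i)],
            provenance=f"synthetic seed={config.seed}",
        )
        for ((u, v), i) in zip(edges, sign_idx)
    ]
    return records, truth


def figure1_fixtures() -> dict[str, "object"]:
    """Small pedagogical networks for tests and documentation.

    Returns named :class:`~adiponet.schema.TypedNetwork` toys: a directed
    transcription-factor regulatory graph, a five-protein interaction
    graph stored as symmetric directed pairs, a small random-like digraph,
    a star with one high-degree hub, and a bridged double star whose
    middle node has low degree but maximal betweenness.  The regulatory,
    star, and bridge toys respect the layer schema; the symmetric PPI toy
    predates it and is exempt from transition validation.
    """
    from .schema import TypedNetwork

    U = EdgeSign.UNCERTAIN

    def net(nodes: dict[str, NodeCategory], pairs: list[tuple[str, str]]) -> TypedNetwork:
        return TypedNetwork(nodes=nodes, edges={p: U for p in pairs})

    regulatory = net(
        {
            "TF1": _C.ADIPOKINE,
            "TF2": _C.ADIPOKINE,
            "G1": _C.MOLECULAR_TARGET,
            "G2": _C.MOLECULAR_TARGET,
            "G3": _C.MOLECULAR_TARGET,
        },
        [("TF1", "G1"), ("TF1", "G2"), ("TF2", "G2"), ("TF2", "G3")],
    )
    ppi_pairs = [("P0", "P1"), ("P0", "P2"), ("P0", "P3"), ("P3", "P4")]
    ppi = net(
        {f"P{i}": _C.MOLECULAR_TARGET for i in range(5)},
        ppi_pairs + [(b, a) for a, b in ppi_pairs],
    )
    random_like = net(
        {
            "r1": _C.PHYSIOLOGIC_PERTURBATION,
            "r2": _C.ADIPOKINE,
            "r3": _C.ADIPOKINE,
            "r4": _C.MOLECULAR_TARGET,
            "r5": _C.MOLECULAR_TARGET,
            "r6": _C.PHYSIOLOGIC_FUNCTION,
            "r7": _C.DISEASE_PROCESS,
        },
        [
            ("r1", "r2"),
            ("r1", "r3"),
            ("r2", "r4"),
            ("r3", "r5"),
            ("r4", "r6"),
            ("r5", "r6"),
            ("r2", "r6"),
            ("r6", "r7"),
        ],
    )
    star = net(
        {"hub": _C.ADIPOKINE, **{f"leaf{i}": _C.MOLECULAR_TARGET for i in range(1, 8)}},
        [("hub", f"leaf{i}") for i in range(1, 8)],
    )
    bridge = net(
        {
            "x1": _C.PHYSIOLOGIC_PERTURBATION,
            "x2": _C.PHYSIOLOGIC_PERTURBATION,
            "x3": _C.PHYSIOLOGIC_PERTURBATION,
            "h1": _C.ADIPOKINE,
            "b": _C.MOLECULAR_TARGET,
            "h2": _C.PHYSIOLOGIC_FUNCTION,
            "y1": _C.DISEASE_PROCESS,
            "y2": _C.DISEASE_PROCESS,
            "y3": _C.DISEASE_PROCESS,
        },
        [
            ("x1", "h1"),
            ("x2", "h1"),
            ("x3", "h1"),
            ("h1", "b"),
            ("b", "h2"),
            ("h2", "y1"),
            ("h2", "y2"),
            ("h2", "y3"),
        ],
    )
    return {
        "regulatory": regulatory,
        "ppi": ppi,
        "random": random_like,
        "star_hub": star,
        "bridge_bottleneck": bridge,
    }
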