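"""Degree and betweenness centrality on the directed network.

Degree centrality of node *i* is C_i = deg(i), split into in- and
out-degree on a directed graph.  Betweenness centrality is

    C_bet(i) = sum over ordered pairs (x, y), x != y != i, of
               sigma_xy(i) / sigma_xy

where sigma_xy is the number of shortest directed paths from x to y and
sigma_xy(i) the number of those with i as an *interior* node (endpoints
excluded).  Pairs with sigma_xy = 0 (y unreachable from x) contribute
nothing.  Values are unnormalized by default, matching the raw formula;
edges are unweighted (signs are labels, not weights).

Two independent implementations are provided: :func:`betweenness` uses the
accumulation scheme of Brandes (single-source BFS plus dependency
back-propagation, O(V*E)), and :func:`betweenness_oracle` enumerates every
shortest path explicitly.  They must agree to 1e-9 on any network; the
test suite enforces this.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import pandas as pd

from .schema import TypedNetwork

__all__ = [
    "CENTRALITY_COLUMNS",
    "ShortestPathCounts",
    "degree_table",
    "betweenness",
    "betweenness_oracle",
    "centrality_table",
    "count_shortest_paths",
]

CENTRALITY_COLUMNS = [
    "category",
    "in_degree",
    "out_degree",
    "degree",
    "betweenness",
    "rank_degree",
    "rank_betweenness",
]


@dataclass(frozen=True)
class ShortestPathCounts:
    """Shortest-path counts for one ordered pair (x, y).

    ``sigma_xy`` is the number of distinct shortest directed paths x->y;
    ``sigma_xy_through[i]`` counts those with *i* as an interior node (0
    for the endpoints by convention).
    """

    source: str
    target: str
    sigma_xy: int
    sigma_xy_through: dict[str, int]


def _ordinal_ranks(values: pd.Series) -> pd.Series:
    """1-based ranks, descending by value, ties broken by node name."""
    order = sorted(values.index, key=lambda n: (-values[n], n))
    return pd.Series({n: r for r, n in enumerate(order, start=1)}, dtype=int).reindex(
        values.index
    )


def degree_table(network: TypedNetwork) -> pd.DataFrame:
    """Per-node in/out/total degree with ordinal degree ranks."""
    names = sorted(network.nodes)
    indeg = {n: 0 for n in names}
    outdeg = {n: 0 for n in names}
    for u, v in network.edges:
        outdeg[u] += 1
        indeg[v] += 1
    df = pd.DataFrame(
        {
            "category": pd.Series({n: network.nodes[n].value for n in names}),
            "in_degree": pd.Series(indeg, dtype=int),
            "out_degree": pd.Series(outdeg, dtype=int),
        }
    ).loc[names]
    df["degree"] = df["in_degree"] + df["out_degree"]
    df["rank_degree"] = _ordinal_ranks(df["degree"])
    return df


def betweenness(network: TypedNetwork, normalized: bool = False) -> pd.Series:
    """Betweenness centrality via single-source BFS with dependency accumulation.

    Iterates sources in sorted name order so floating-point accumulation is
    reproducible bit-for-bit across runs.  With ``normalized=True`` values
    are divided by (n-1)(n-2), the number of ordered pairs a node could
    mediate, for cross-tool comparison.
    """
    names = sorted(network.nodes)
    adj = network.successors()
    cb = {n: 0.0 for n in names}

    for s in names:
        # single-source shortest-path counting (BFS; unweighted edges)
        sigma = {n: 0 for n in names}
        dist = {n: -1 for n in names}
        preds: dict[str, list[str]] = {n: [] for n in names}
        sigma[s] = 1
        dist[s] = 0
        order: list[str] = []
        queue: deque[str] = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency back-propagation
        delta = {n: 0.0 for n in names}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]

    series = pd.Series(cb, dtype=float).reindex(names)
    if normalized:
        n = len(names)
        scale = (n - 1) * (n - 2)
        if scale > 0:
            series = series / scale
    series.name = "betweenness"
    return series


def count_shortest_paths(network: TypedNetwork, source: str, target: str) -> ShortestPathCounts:
    """Explicitly enumerate all shortest directed paths from *source* to *target*.

    Brute force: BFS for distances from *source*, then depth-first
    enumeration over the shortest-path DAG, tallying interior-node
    passages.  Intended for verification on small networks.
    """
    adj = network.successors()
    dist = {source: 0}
    queue: deque[str] = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    through = {n: 0 for n in network.nodes}
    if target not in dist or target == source:
        return ShortestPathCounts(source, target, 0, through)

    sigma = 0
    stack: list[tuple[str, list[str]]] = [(source, [source])]
    while stack:
        v, path = stack.pop()
        if v == target:
            sigma += 1
            for interior in path[1:-1]:
                through[interior] += 1
            continue
        for w in adj[v]:
            if w in dist and dist[w] == dist[v] + 1 and dist[w] <= dist[target]:
                stack.append((w, path + [w]))
    return ShortestPathCounts(source, target, sigma, through)


def betweenness_oracle(network: TypedNetwork) -> pd.Series:
    """Betweenness by exhaustive shortest-path enumeration (verification oracle).

    Same contract as :func:`betweenness`; O(paths) runtime, usable up to a
    few hundred nodes.
    """
    names = sorted(network.nodes)
    cb = {n: 0.0 for n in names}
    for x in names:
        for y in names:
            if x == y:
                continue
            counts = count_shortest_paths(network, x, y)
            if counts.sigma_xy == 0:
                continue
            for i, through in counts.sigma_xy_through.items():
                if through:
                    cb[i] += through / counts.sigma_xy
    series = pd.Series(cb, dtype=float).reindex(names)
    series.name = "betweenness"
    return series


def centrality_table(network: TypedNetwork, normalized: bool = False) -> pd.DataFrame:
    """Full per-node centrality table: degrees, betweenness, and both ranks."""
    df = degree_table(network)
    df["betweenness"] = betweenness(network, normalized=normalized)
    df["rank_betweenness"] = _ordinal_ranks(df["betweenness"])
    return df[CENTRALITY_COLUMNS]
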