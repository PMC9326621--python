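"""Stability of hub/bottleneck calls under simulated curation noise.

A literature-curated network is only as complete as its literature:
publication bias means edges may be missing and some reported relations
may not survive scrutiny.  This module operationalizes that caveat by
resampling edges — each replicate independently deletes existing edges and
adds schema-legal absent ones — and measuring how often each node keeps
its hub / bottleneck / nonhub-bottleneck call.

Classification thresholds are frozen at their baseline values across
replicates by default, so the reported frequencies measure instability of
the network, not of the quantile cutoffs; re-quantiling per replicate is
available via ``refit_thresholds``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import centrality_table
from .classification import classify, classify_with_thresholds
from .schema import ALLOWED_TRANSITIONS, EdgeSign, TypedNetwork

__all__ = ["StabilityReport", "stability"]

_CLASSES = ["hub", "bottleneck", "nonhub_bottleneck"]


@dataclass(frozen=True)
class StabilityReport:
    """Per-node membership frequencies over R resampled replicates."""

    #: DataFrame indexed by node, columns hub/bottleneck/nonhub_bottleneck,
    #: values in [0, 1]
    frequencies: pd.DataFrame
    baseline: "object"  # ClassificationResult of the unperturbed network
    parameters: dict


def _legal_absent_pairs(network: TypedNetwork) -> list[tuple[str, str]]:
    nodes = sorted(network.nodes)
    pairs = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v
        and (network.nodes[u], network.nodes[v]) in ALLOWED_TRANSITIONS
        and (u, v) not in network.edges
    ]
    return pairs


def stability(
    network: TypedNetwork,
    edge_drop_prob: float,
    edge_add_prob: float,
    replicates: int,
    seed: int,
    hub_quantile: float = 0.90,
    bottleneck_quantile: float = 0.90,
    low_degree_quantile: float = 0.50,
    refit_thresholds: bool = False,
) -> StabilityReport:
    """Resample edges and report how often each classification call persists.

    Each replicate deletes every edge independently with probability
    *edge_drop_prob* and adds ``Binomial(|E|, edge_add_prob)`` random
    schema-legal absent edges (sign ``uncertain``).  Classification is
    recomputed per replicate with baseline thresholds (or re-quantiled
    when *refit_thresholds* is set).  Deterministic given *seed*.
    """
    if not 0.0 <= edge_drop_prob < 1.0 or not 0.0 <= edge_add_prob < 1.0:
        raise ValueError("perturbation probabilities must lie in [0, 1)")
    if replicates < 1:
        raise ValueError("need at least one replicate")

    rng = np.random.default_rng(seed)
    base_table = centrality_table(network)
    base = classify(
        base_table,
        hub_quantile=hub_quantile,
        bottleneck_quantile=bottleneck_quantile,
        low_degree_quantile=low_degree_quantile,
    )
    cutoffs = {k: v[0] for k, v in base.thresholds.items()}

    nodes = sorted(network.nodes)
    counts = pd.DataFrame(0.0, index=nodes, columns=_CLASSES)
    edge_list = sorted(network.edges)
    n_edges = len(edge_list)

    for _ in range(replicates):
        keep = rng.random(n_edges) >= edge_drop_prob
        edges = {e: network.edges[e] for e, k in zip(edge_list, keep) if k}
        replicate = TypedNetwork(nodes=dict(network.nodes), edges=edges)
        n_add = int(rng.binomial(n_edges, edge_add_prob)) if n_edges else 0
        if n_add:
            candidates = _legal_absent_pairs(replicate)
            n_add = min(n_add, len(candidates))
            for idx in rng.choice(len(candidates), size=n_add, replace=False):
                replicate.edges[candidates[int(idx)]] = EdgeSign.UNCERTAIN
        table = centrality_table(replicate)
        if refit_thresholds:
            result = classify(
                table,
                hub_quantile=hub_quantile,
                bottleneck_quantile=bottleneck_quantile,
                low_degree_quantile=low_degree_quantile,
            )
        else:
            result = classify_with_thresholds(
                table,
                cutoffs["hub_degree_cutoff"],
                cutoffs["bottleneck_betweenness_cutoff"],
                cutoffs["low_degree_cutoff"],
            )
        for cls, members in (
            ("hub", result.hubs),
            ("bottleneck", result.bottlenecks),
            ("nonhub_bottleneck", result.nonhub_bottlenecks),
        ):
            for n in members:
                counts.at[n, cls] += 1

    return StabilityReport(
        frequencies=counts / replicates,
        baseline=base,
        parameters={
            "edge_drop_prob": edge_drop_prob,
            "edge_add_prob": edge_add_prob,
            "replicates": replicates,
            "seed": seed,
            "refit_thresholds": refit_thresholds,
            "hub_quantile": hub_quantile,
            "bottleneck_quantile": bottleneck_quantile,
            "low_degree_quantile": low_degree_quantile,
        },
    )
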