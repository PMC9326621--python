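"""Hub, bottleneck, and nonhub-bottleneck classification.

Hubs are nodes with much higher degree than the rest of the network;
bottlenecks are nodes with high betweenness, controlling information flow;
nonhub bottlenecks combine low degree with high betweenness and often mark
key regulatory points (the AMPK pattern: a target wired between two major
adipokines without itself being highly connected).

The qualitative definitions are made operational with quantile cutoffs,
reported alongside every result so the rule that produced each call is
explicit.  Quantiles use the nearest-rank method for cross-platform
reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import CENTRALITY_COLUMNS
from .schema import NodeCategory, TypedNetwork

__all__ = [
    "ClassificationResult",
    "DegreeDistributionSummary",
    "classify",
    "classify_with_thresholds",
    "rank_by_type",
    "degree_distribution",
    "nearest_rank_quantile",
]


@dataclass(frozen=True)
class ClassificationResult:
    hubs: frozenset[str]
    bottlenecks: frozenset[str]
    nonhub_bottlenecks: frozenset[str]
    #: cutoff values and the rule that produced each, e.g.
    #: {"hub_degree_cutoff": (12, "degree >= 0.90-quantile of degrees"), ...}
    thresholds: dict[str, tuple[float, str]] = field(default_factory=dict)


@dataclass(frozen=True)
class DegreeDistributionSummary:
    """Histogram plus a heuristic heavy-tail diagnostic.

    ``tail_slope`` is the least-squares slope of log(count) against
    log(degree) over observed degrees >= 1; a slope <= -1 together with a
    maximum degree at least 4x the median flags a heavy tail.  This is a
    descriptive heuristic, not a rigorous power-law fit.
    """

    histogram: dict[int, int]
    tail_slope: float
    heavy_tail_flag: bool


def nearest_rank_quantile(values: list[float] | np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th smallest of n sorted values."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("quantile of empty sequence")
    rank = max(1, math.ceil(q * arr.size))
    return float(arr[rank - 1])


def classify(
    table: pd.DataFrame,
    hub_quantile: float = 0.90,
    bottleneck_quantile: float = 0.90,
    low_degree_quantile: float = 0.50,
) -> ClassificationResult:
    """Classify nodes of a centrality table into hubs and bottlenecks.

    hubs: degree >= the *hub_quantile* nearest-rank quantile of the degree
    distribution (and degree >= 1, so an edge-free network has no hubs).
    bottlenecks: betweenness >= the *bottleneck_quantile* quantile of the
    positive-betweenness distribution; empty when no node has positive
    betweenness.  nonhub bottlenecks: bottlenecks whose degree is at or
    below the *low_degree_quantile* quantile of the *distinct* observed
    degrees, minus any hubs.  Distinct values are used for the low-degree
    cutoff because real layered networks carry a large mass of leaf nodes
    (degree 1) that would otherwise drag the cutoff below any node that
    has both an in- and an out-edge.
    """
    if table.empty:
        raise ValueError("cannot classify an empty centrality table")
    for name, q in (
        ("hub_quantile", hub_quantile),
        ("bottleneck_quantile", bottleneck_quantile),
        ("low_degree_quantile", low_degree_quantile),
    ):
        if not 0.0 < q < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {q}")

    degrees = table["degree"].to_numpy(dtype=float)
    hub_cutoff = max(nearest_rank_quantile(degrees, hub_quantile), 1.0)
    low_cutoff = nearest_rank_quantile(np.unique(degrees), low_degree_quantile)

    positive_bet = table.loc[table["betweenness"] > 0, "betweenness"].to_numpy(dtype=float)
    if positive_bet.size:
        bet_cutoff = nearest_rank_quantile(positive_bet, bottleneck_quantile)
    else:
        bet_cutoff = float("inf")

    thresholds = {
        "hub_degree_cutoff": (
            hub_cutoff,
            f"degree >= max({hub_quantile:.2f}-quantile of degrees, 1)",
        ),
        "bottleneck_betweenness_cutoff": (
            bet_cutoff,
            f"betweenness >= {bottleneck_quantile:.2f}-quantile of positive betweenness",
        ),
        "low_degree_cutoff": (
            low_cutoff,
            f"degree <= {low_degree_quantile:.2f}-quantile of distinct degrees",
        ),
    }
    return classify_with_thresholds(table, hub_cutoff, bet_cutoff, low_cutoff, thresholds)


def classify_with_thresholds(
    table: pd.DataFrame,
    hub_degree_cutoff: float,
    bottleneck_betweenness_cutoff: float,
    low_degree_cutoff: float,
    thresholds: dict[str, tuple[float, str]] | None = None,
) -> ClassificationResult:
    """Classify with explicit cutoffs (used to freeze thresholds across resamples)."""
    hubs = frozenset(table.index[table["degree"] >= hub_degree_cutoff])
    bottlenecks = frozenset(
        table.index[
            (table["betweenness"] >= bottleneck_betweenness_cutoff)
            & (table["betweenness"] > 0)
        ]
    )
    nonhub = frozenset(
        n for n in bottlenecks if table.at[n, "degree"] <= low_degree_cutoff
    ) - hubs
    if thresholds is None:
        thresholds = {
            "hub_degree_cutoff": (float(hub_degree_cutoff), "explicit"),
            "bottleneck_betweenness_cutoff": (
                float(bottleneck_betweenness_cutoff),
                "explicit",
            ),
            "low_degree_cutoff": (float(low_degree_cutoff), "explicit"),
        }
    return ClassificationResult(
        hubs=hubs,
        bottlenecks=bottlenecks,
        nonhub_bottlenecks=nonhub,
        thresholds=thresholds,
    )


def rank_by_type(
    table: pd.DataFrame,
    network: TypedNetwork,
    by: str = "degree",
) -> dict[NodeCategory, pd.DataFrame]:
    """Per-category ranking tables sorted by *by* descending, ties by name.

    Mirrors the per-category degree and betweenness bar charts: one table
    per node category, each row a node with its in/out/total degree and
    betweenness.
    """
    if by not in ("degree", "betweenness"):
        raise ValueError(f"rank key must be 'degree' or 'betweenness', got {by!r}")
    if set(table.index) != set(network.nodes):
        raise ValueError("centrality table and network cover different node sets")
    out: dict[NodeCategory, pd.DataFrame] = {}
    cols = [c for c in CENTRALITY_COLUMNS if c != "category"]
    for cat in NodeCategory:
        members = [n for n in table.index if network.nodes[n] == cat]
        sub = table.loc[members, cols]
        sub = sub.sort_values(by=[by], ascending=False, kind="mergesort")
        sub = sub.loc[sorted(sub.index, key=lambda n: (-sub.at[n, by], n))]
        out[cat] = sub
    return out


def degree_distribution(table: pd.DataFrame) -> DegreeDistributionSummary:
    """Summarize the degree distribution and flag a heavy tail.

    The slope is fit by least squares on (log degree, log count) over
    degrees >= 1 present in the histogram; fewer than two such degrees
    yield slope NaN and no flag.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty centrality table")
    degrees = table["degree"].astype(int)
    histogram = degrees.value_counts().sort_index().to_dict()
    pts = [(d, c) for d, c in histogram.items() if d >= 1]
    if len(pts) >= 2:
        logd = np.log([d for d, _ in pts])
        logc = np.log([c for _, c in pts])
        slope = float(np.polyfit(logd, logc, 1)[0])
    else:
        slope = float("nan")
    med = float(np.median(degrees))
    heavy = (
        not math.isnan(slope)
        and slope <= -1.0
        and med > 0
        and float(degrees.max()) >= 4.0 * med
    )
    return DegreeDistributionSummary(
        histogram={int(k): int(v) for k, v in histogram.items()},
        tail_slope=slope,
        heavy_tail_flag=bool(heavy),
    )
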