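"""Hub/bottleneck calls, per-category rankings, degree-distribution summary."""

import math

import pytest
from hypothesis import given, strategies as st

from adiponet import (
    EdgeSign,
    NodeCategory,
    TypedNetwork,
    betweenness_oracle,
    centrality_table,
    classify,
    degree_distribution,
    generate,
    build_network,
    rank_by_type,
)
from adiponet.classification import nearest_rank_quantile
from adiponet.synthetic import SyntheticConfig

C = NodeCategory
U = EdgeSign.UNCERTAIN


def test_star_center_is_hub_and_no_bottlenecks(fixtures1):
    """A directed star has one dominant-degree node and no interior paths."""
    table = centrality_table(fixtures1["star_hub"])
    result = classify(table)
    assert result.hubs == {"hub"}
    assert result.bottlenecks == frozenset()
    assert result.nonhub_bottlenecks == frozenset()


def test_bridge_is_nonhub_bottleneck(fixtures1):
    """In the bridged double star the middle node has degree 2 but maximal
    betweenness (verified against the enumeration oracle)."""
    net = fixtures1["bridge_bottleneck"]
    table = centrality_table(net)
    oracle = betweenness_oracle(net)
    assert oracle.idxmax() == "b" and table.at["b", "degree"] == 2
    result = classify(table)
    assert "b" in result.nonhub_bottlenecks
    assert "b" in result.bottlenecks and "b" not in result.hubs


def test_edge_free_network_has_empty_classes():
    net = TypedNetwork(nodes={"a": C.ADIPOKINE, "b": C.MOLECULAR_TARGET})
    result = classify(centrality_table(net))
    assert result.hubs == result.bottlenecks == result.nonhub_bottlenecks == frozenset()


def test_empty_table_is_an_error():
    with pytest.raises(ValueError):
        classify(centrality_table(TypedNetwork()))


@pytest.mark.parametrize("q", [-0.1, 0.0, 1.0, 1.5])
def test_quantiles_outside_unit_interval_rejected(q, default_synthetic):
    _, _, net, _ = default_synthetic
    with pytest.raises(ValueError):
        classify(centrality_table(net), hub_quantile=q)


def test_thresholds_are_reported(default_synthetic):
    _, _, net, _ = default_synthetic
    result = classify(centrality_table(net))
    assert set(result.thresholds) == {
        "hub_degree_cutoff",
        "bottleneck_betweenness_cutoff",
        "low_degree_cutoff",
    }
    for value, rule in result.thresholds.values():
        assert isinstance(rule, str) and rule


@given(st.floats(min_value=0.5, max_value=0.98), st.floats(min_value=0.01, max_value=0.48))
def test_raising_hub_quantile_never_enlarges_hub_set(default_synthetic, q, dq):
    _, _, net, _ = default_synthetic
    table = centrality_table(net)
    low = classify(table, hub_quantile=q)
    high = classify(table, hub_quantile=min(q + dq, 0.99))
    assert high.hubs <= low.hubs


def test_class_set_invariants(default_synthetic):
    _, _, net, _ = default_synthetic
    result = classify(centrality_table(net))
    assert result.nonhub_bottlenecks <= result.bottlenecks
    assert not (result.nonhub_bottlenecks & result.hubs)


def test_nearest_rank_quantile():
    vals = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    assert nearest_rank_quantile(vals, 0.5) == 5
    assert nearest_rank_quantile(vals, 0.9) == 9
    assert nearest_rank_quantile(vals, 0.05) == 1


def test_rank_by_type_partitions_and_orders(default_synthetic):
    _, _, net, _ = default_synthetic
    table = centrality_table(net)
    ranked = rank_by_type(table, net, by="degree")
    assert set(ranked) == set(C)
    total = sum(len(df) for df in ranked.values())
    assert total == len(net.nodes)
    for df in ranked.values():
        degrees = df["degree"].tolist()
        assert degrees == sorted(degrees, reverse=True)


def test_rank_by_type_adipokine_hubs_lead(default_synthetic):
    """The planted hub adipokines rank first among adipokines by degree and
    the top hub leads the betweenness ranking too."""
    _, truth, net, _ = default_synthetic
    table = centrality_table(net)
    by_deg = rank_by_type(table, net, by="degree")[C.ADIPOKINE]
    assert set(by_deg.index[:2]) == set(truth.planted_hubs)
    by_bet = rank_by_type(table, net, by="betweenness")[C.ADIPOKINE]
    assert by_bet.index[0] in truth.planted_hubs


def test_rank_by_type_single_node():
    net = TypedNetwork(nodes={"leptin": C.ADIPOKINE})
    ranked = rank_by_type(centrality_table(net), net)
    assert len(ranked[C.ADIPOKINE]) == 1
    assert all(len(ranked[c]) == 0 for c in C if c != C.ADIPOKINE)


def test_rank_by_type_node_set_mismatch(default_synthetic):
    _, _, net, _ = default_synthetic
    table = centrality_table(net).drop(index=sorted(net.nodes)[0])
    with pytest.raises(ValueError, match="node set"):
        rank_by_type(table, net)


def test_degree_distribution_cycle():
    nodes = {f"c{i}": C.MOLECULAR_TARGET for i in range(4)}
    names = sorted(nodes)
    edges = {(names[i], names[(i + 1) % 4]): U for i in range(4)}
    summary = degree_distribution(centrality_table(TypedNetwork(nodes, edges)))
    assert summary.histogram == {2: 4}
    assert not summary.heavy_tail_flag and math.isnan(summary.tail_slope)


def test_degree_distribution_star_flags_heavy_tail():
    nodes = {"h": C.ADIPOKINE, **{f"l{i}": C.MOLECULAR_TARGET for i in range(9)}}
    edges = {("h", f"l{i}"): U for i in range(9)}
    summary = degree_distribution(centrality_table(TypedNetwork(nodes, edges)))
    assert summary.histogram == {1: 9, 9: 1}
    assert summary.tail_slope <= -1
    assert summary.heavy_tail_flag


def test_degree_distribution_counts_sum_to_nodes(default_synthetic):
    _, _, net, _ = default_synthetic
    summary = degree_distribution(centrality_table(net))
    assert sum(summary.histogram.values()) == len(net.nodes)
    # dominant hubs: the maximum degree dwarfs the median even though the
    # 94-node histogram is too small for a clean power-law slope
    degrees = sorted(d for d, c in summary.histogram.items() for _ in range(c))
    median = degrees[len(degrees) // 2]
    assert max(degrees) >= 4 * median
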