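"""Degree and betweenness: closed forms, oracle equivalence, invariances."""

import networkx as nx
import numpy as np
import pytest

from adiponet import (
    EdgeSign,
    NodeCategory,
    TypedNetwork,
    betweenness,
    betweenness_oracle,
    build_network,
    centrality_table,
    count_shortest_paths,
    degree_table,
    generate,
)
from adiponet.io import to_networkx
from adiponet.synthetic import SyntheticConfig

from conftest import chain_network, small_config

C = NodeCategory
U = EdgeSign.UNCERTAIN


def test_degree_star():
    net = TypedNetwork(
        nodes={"h": C.ADIPOKINE, "a": C.MOLECULAR_TARGET, "b": C.MOLECULAR_TARGET, "c": C.MOLECULAR_TARGET},
        edges={("h", "a"): U, ("h", "b"): U, ("h", "c"): U},
    )
    t = degree_table(net)
    assert t.at["h", "out_degree"] == 3 and t.at["h", "in_degree"] == 0
    assert t.at["h", "degree"] == 3 and t.at["h", "rank_degree"] == 1
    assert (t.loc[["a", "b", "c"], "degree"] == 1).all()


def test_degree_path():
    t = degree_table(chain_network(3))
    assert t.at["v02", "in_degree"] == 1 and t.at["v02", "out_degree"] == 1
    assert t.at["v02", "degree"] == 2


def test_handshake_identity(default_synthetic):
    _, _, net, _ = default_synthetic
    t = degree_table(net)
    assert int(t["degree"].sum()) == 2 * len(net.edges)
    assert int(t["in_degree"].sum()) == int(t["out_degree"].sum()) == len(net.edges)


@pytest.mark.parametrize("n", [3, 4, 5, 8, 12])
def test_chain_betweenness_closed_form(n):
    """Interior node k of a directed n-chain mediates (k-1)(n-k) pairs."""
    net = chain_network(n)
    b = betweenness(net)
    o = betweenness_oracle(net)
    for k in range(1, n + 1):
        expected = (k - 1) * (n - k)
        assert b[f"v{k:02d}"] == pytest.approx(expected, abs=1e-12)
        assert o[f"v{k:02d}"] == pytest.approx(expected, abs=1e-12)


def test_diamond_splits_fractionally(diamond):
    """Two equal-length a->d paths give each middle node betweenness 1/2."""
    b = betweenness(diamond)
    assert b["b"] == pytest.approx(0.5) and b["c"] == pytest.approx(0.5)
    assert b["a"] == 0 and b["d"] == 0


def test_complete_digraph_all_zero(complete_digraph4):
    """Every pair is adjacent, so no shortest path has an interior node."""
    assert (betweenness(complete_digraph4) == 0).all()
    assert (betweenness_oracle(complete_digraph4) == 0).all()


def test_single_edge_all_zero():
    net = TypedNetwork(
        nodes={"a": C.ADIPOKINE, "b": C.MOLECULAR_TARGET}, edges={("a", "b"): U}
    )
    assert (betweenness_oracle(net) == 0).all()


def test_shortest_path_counts_on_diamond(diamond):
    counts = count_shortest_paths(diamond, "a", "d")
    assert counts.sigma_xy == 2
    assert counts.sigma_xy_through["b"] == 1 and counts.sigma_xy_through["c"] == 1
    assert counts.sigma_xy_through["a"] == 0 and counts.sigma_xy_through["d"] == 0


def test_unreachable_pair_counts_zero(diamond):
    assert count_shortest_paths(diamond, "d", "a").sigma_xy == 0


@pytest.mark.parametrize("seed", range(12))
def test_oracle_equivalence_random_layered(seed):
    """Brandes-style accumulation equals explicit path enumeration."""
    records, _ = generate(small_config(seed))
    net, _ = build_network(records)
    b = betweenness(net)
    o = betweenness_oracle(net)
    assert float((b - o).abs().max()) < 1e-9


def test_oracle_equivalence_figure_fixtures(fixtures1):
    for name, net in fixtures1.items():
        b = betweenness(net)
        o = betweenness_oracle(net)
        assert float((b - o).abs().max()) < 1e-9, name


def test_agrees_with_networkx_cross_check(default_synthetic):
    """Independent library cross-check on the default synthetic network."""
    _, _, net, _ = default_synthetic
    ours = betweenness(net)
    ref = nx.betweenness_centrality(to_networkx(net), normalized=False)
    assert max(abs(ours[k] - v) for k, v in ref.items()) < 1e-9


def test_normalized_flag_scales_by_pair_count(diamond):
    raw = betweenness(diamond)
    norm = betweenness(diamond, normalized=True)
    n = len(diamond.nodes)
    assert np.allclose(norm, raw / ((n - 1) * (n - 2)))


def test_relabeling_invariance():
    records, _ = generate(small_config(7))
    net, _ = build_network(records)
    mapping = {n: f"zz-{i:03d}" for i, n in enumerate(sorted(net.nodes, reverse=True))}
    relabeled = TypedNetwork(
        nodes={mapping[n]: c for n, c in net.nodes.items()},
        edges={(mapping[u], mapping[v]): s for (u, v), s in net.edges.items()},
    )
    b1 = sorted(betweenness(net).round(9))
    b2 = sorted(betweenness(relabeled).round(9))
    assert np.allclose(b1, b2)
    assert sorted(degree_table(net)["degree"]) == sorted(degree_table(relabeled)["degree"])


@pytest.mark.parametrize("seed", range(6))
def test_source_and_sink_nullity(seed):
    """Perturbation, sleep, and disease nodes never lie strictly inside a
    path, so their betweenness is exactly zero."""
    records, _ = generate(small_config(seed))
    net, _ = build_network(records)
    table = centrality_table(net)
    boundary = table["category"].isin(
        ["physiologic_perturbation", "sleep_disturbance", "disease_process"]
    )
    assert (table.loc[boundary, "betweenness"] == 0).all()


def test_betweenness_zero_for_one_sided_nodes(default_synthetic):
    """Any node with in-degree 0 or out-degree 0 has betweenness 0."""
    _, _, net, _ = default_synthetic
    t = centrality_table(net)
    one_sided = (t["in_degree"] == 0) | (t["out_degree"] == 0)
    assert (t.loc[one_sided, "betweenness"] == 0).all()


def test_ranks_are_ordinal_and_tie_broken_by_name(diamond):
    t = centrality_table(diamond)
    assert sorted(t["rank_degree"]) == [1, 2, 3, 4]
    # all degrees equal (=2): ranks follow name order
    assert t.sort_values("rank_degree").index.tolist() == ["a", "b", "c", "d"]


def test_bit_reproducibility(default_synthetic):
    _, _, net, _ = default_synthetic
    b1 = betweenness(net)
    b2 = betweenness(net)
    assert (b1 == b2).all()
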