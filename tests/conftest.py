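import pytest
from hypothesis import settings

from adiponet import (
    EdgeSign,
    NodeCategory,
    TypedNetwork,
    build_network,
    figure1_fixtures,
    generate,
)
from adiponet.synthetic import SyntheticConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

U = EdgeSign.UNCERTAIN
C = NodeCategory


def chain_network(n: int) -> TypedNetwork:
    """Directed path v1 -> v2 -> ... -> vn (categories chosen to be schema-legal
    where possible; centrality does not consult categories)."""
    cats = [
        C.PHYSIOLOGIC_PERTURBATION,
        C.ADIPOKINE,
        C.MOLECULAR_TARGET,
        C.PHYSIOLOGIC_FUNCTION,
        C.DISEASE_PROCESS,
    ]
    nodes = {f"v{i:02d}": cats[min(i - 1, len(cats) - 1)] for i in range(1, n + 1)}
    edges = {(f"v{i:02d}", f"v{i + 1:02d}"): U for i in range(1, n)}
    return TypedNetwork(nodes=nodes, edges=edges)


@pytest.fixture
def diamond() -> TypedNetwork:
    """a -> b, a -> c, b -> d, c -> d: two equal-length a->d paths."""
    return TypedNetwork(
        nodes={
            "a": C.ADIPOKINE,
            "b": C.MOLECULAR_TARGET,
            "c": C.MOLECULAR_TARGET,
            "d": C.PHYSIOLOGIC_FUNCTION,
        },
        edges={("a", "b"): U, ("a", "c"): U, ("b", "d"): U, ("c", "d"): U},
    )


@pytest.fixture
def complete_digraph4() -> TypedNetwork:
    nodes = {f"n{i}": C.MOLECULAR_TARGET for i in range(4)}
    edges = {(u, v): U for u in nodes for v in nodes if u != v}
    return TypedNetwork(nodes=nodes, edges=edges)


@pytest.fixture(scope="session")
def fixtures1():
    return figure1_fixtures()


@pytest.fixture(scope="session")
def default_synthetic():
    """Default-condition synthetic network (seed 42) built through the pipeline."""
    records, truth = generate(SyntheticConfig(seed=42))
    network, conflicts = build_network(records)
    return records, truth, network, conflicts


def small_config(seed: int) -> SyntheticConfig:
    """Reduced-size config for property sweeps (still >= 40 nodes)."""
    sizes = {
        C.PHYSIOLOGIC_PERTURBATION: 4,
        C.SLEEP_DISTURBANCE: 3,
        C.ADIPOKINE: 5,
        C.MOLECULAR_TARGET: 12,
        C.PHYSIOLOGIC_FUNCTION: 11,
        C.DISEASE_PROCESS: 11,
    }
    return SyntheticConfig(layer_sizes=sizes, edge_budget=120, seed=seed)
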