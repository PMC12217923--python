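import pytest

from topoqspr import MolecularGraph, load_drug_fixtures


def path_graph(n: int) -> MolecularGraph:
    return MolecularGraph(f"P{n}", n, frozenset((i, i + 1) for i in range(n - 1)))


def cycle_graph(n: int) -> MolecularGraph:
    edges = {(i, (i + 1) % n) for i in range(n)}
    return MolecularGraph(f"C{n}", n, frozenset(edges))


def complete_graph(n: int) -> MolecularGraph:
    edges = {(a, b) for a in range(n) for b in range(a + 1, n)}
    return MolecularGraph(f"K{n}", n, frozenset(edges))


@pytest.fixture(scope="session")
def fixtures():
    return load_drug_fixtures()


@pytest.fixture(scope="session")
def fixtures_by_name(fixtures):
    return {f.name: f for f in fixtures}


@pytest.fixture(scope="session")
def computed_index_sets(fixtures):
    """Index sets computed from structure, once per session."""
    from topoqspr import compute_index_set

    return {f.name: compute_index_set(f.to_graph()) for f in fixtures}
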