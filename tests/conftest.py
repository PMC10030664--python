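import networkx as nx
import numpy as np
import pandas as pd
import pytest

from agenet import build_sample_network
from agenet.io import ExpressionMatrix, Scaffold


def sample_network_from_graph(graph: nx.Graph, values: dict) -> object:
    """Build a WeightedSampleNetwork from an in-memory graph + node values."""
    named = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    vals = {str(k): float(v) for k, v in values.items()}
    genes = sorted(named.nodes)
    df = pd.DataFrame({"s_3m": [vals[g] for g in genes]}, index=genes)
    expr = ExpressionMatrix(df, {"s_3m": 3})
    return build_sample_network(expr, "s_3m", Scaffold(named))


def two_cliques_linker(k: int = 6) -> nx.Graph:
    """Two K_k cliques joined through a single low-degree linker node."""
    g = nx.Graph()
    a = [f"a{i}" for i in range(k)]
    b = [f"b{i}" for i in range(k)]
    for clique in (a, b):
        g.add_edges_from(
            (x, y) for i, x in enumerate(clique) for y in clique[i + 1:])
    g.add_edge(a[0], "linker")
    g.add_edge("linker", b[0])
    return g


def random_connected_graphs(n_graphs: int, max_nodes: int, seed: int,
                            densities=(0.25, 0.5, 0.75)):
    """Erdos-Renyi samples (several densities) with at least one edge."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_graphs:
        n = int(rng.integers(3, max_nodes + 1))
        p = densities[len(out) % len(densities)]
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() >= 1:
            out.append(g)
    return out


@pytest.fixture
def tiny_scaffold_file(tmp_path):
    path = tmp_path / "scaffold.tsv"
    path.write_text("a\tb\t0.95\nb\tc\t0.85\na\ta\t0.99\n")
    return path


@pytest.fixture
def toy_expression_files(tmp_path):
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "gene\tS1\tS2\tS3\n"
        "g1\t1.0\t2.0\t3.0\n"
        "g2\t0.5\t0.0\t1.5\n"
    )
    groups = tmp_path / "groups.tsv"
    groups.write_text("S1\t3\nS2\t3\nS3\t27\n")
    return expr, groups
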