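"""MCODE dense-module detection (vertex weighting, complex prediction,
post-processing), with cluster score = density x size.

Stage 1 weights each vertex by k x density of the highest k-core of its
closed neighbourhood. Stage 2 grows complexes from the highest-weighted
unassigned seed, recursively admitting neighbours whose weight is within
``node_score_cutoff`` of the seed weight; complexes are node-disjoint.
Stage 3 discards complexes lacking a 2-core and optionally haircuts
singly-connected members. Clusters are scored by density x node count
(2E/(V(V-1)), no self-loops; a K5 scores exactly 5) and filtered at a
minimum score.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import pandas as pd

from . import config as _cfg
from .ageing_network import ConditionNetwork

logger = logging.getLogger("agenet")


@dataclasses.dataclass
class Cluster:
    """One detected complex: members, its seed, density x size score, rank."""

    members: frozenset[str]
    seed: str
    score: float
    rank: int = 0

    @property
    def size(self) -> int:
        return len(self.members)


def _density(graph: nx.Graph) -> float:
    v = graph.number_of_nodes()
    if v < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (v * (v - 1))


def _highest_k_core(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """(k, subgraph) of the highest non-empty k-core; (0, empty) if edgeless."""
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_edges() == 0:
        return 0, nx.Graph()
    core_numbers = nx.core_number(g)
    k = max(core_numbers.values())
    nodes = [v for v, c in core_numbers.items() if c >= k]
    return k, g.subgraph(nodes).copy()


def vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """MCODE stage 1: w(v) = k x density of the highest k-core of N(v) + v."""
    weights = {}
    for v in graph.nodes:
        neighbourhood = graph.subgraph([v, *graph.neighbors(v)])
        k, core = _highest_k_core(neighbourhood)
        weights[v] = k * _density(core) if k > 0 else 0.0
    return weights


def mcode_clusters(graph: nx.Graph,
                   degree_cutoff: int = _cfg.MCODE_DEGREE_CUTOFF,
                   node_score_cutoff: float = _cfg.MCODE_NODE_SCORE_CUTOFF,
                   k_core: int = _cfg.MCODE_K_CORE,
                   max_depth: int = _cfg.MCODE_MAX_DEPTH,
                   haircut: bool = True,
                   fluff: bool = False,
                   score_min: float = 5.0) -> list[Cluster]:
    """Run MCODE with the published defaults and filter at ``score_min``.

    Seeds are processed in descending vertex weight (ties lexicographic);
    each node joins at most one complex. Returns clusters sorted by
    descending score, ties by seed symbol, with 1-based ranks.
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not provided")
    simple = nx.Graph(graph)
    simple.remove_edges_from(nx.selfloop_edges(simple))
    weights = vertex_weights(simple)
    # nodes below the degree cutoff never seed or join a complex
    eligible = {v for v in simple.nodes if simple.degree(v) >= degree_cutoff}
    assigned: set[str] = set()
    clusters: list[Cluster] = []
    for seed in sorted(eligible, key=lambda v: (-weights[v], v)):
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            u, depth = frontier.pop()
            if depth >= max_depth:
                continue
            for w in sorted(simple.neighbors(u)):
                if w in members or w in assigned or w not in eligible:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    frontier.append((w, depth + 1))
        sub = simple.subgraph(members).copy()
        # post-processing: require a k-core, then haircut loose ends
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            assigned.add(seed)
            continue
        if haircut:
            sub = core
        members = set(sub.nodes)
        assigned |= members
        score = _density(sub) * sub.number_of_nodes()
        if score >= score_min:
            clusters.append(Cluster(frozenset(members), seed, score))
    clusters.sort(key=lambda c: (-c.score, c.seed))
    for rank, c in enumerate(clusters, start=1):
        c.rank = rank
    logger.info("mcode_clusters: %d clusters at score >= %g", len(clusters), score_min)
    return clusters


def cluster_report(clusters: list[Cluster],
                   condition_net: ConditionNetwork | None = None) -> pd.DataFrame:
    """Tabulate clusters: members, size, score, rank, seed/neighbour counts."""
    rows = []
    for c in clusters:
        row = {
            "rank": c.rank,
            "seed": c.seed,
            "size": c.size,
            "score": c.score,
            "members": ",".join(str(m) for m in sorted(c.members, key=str)),
        }
        if condition_net is not None:
            prov = condition_net.provenance
            row["n_seed_genes"] = sum(1 for m in c.members if prov.get(m) == "seed")
            row["n_neighbour_genes"] = sum(
                1 for m in c.members if prov.get(m) == "neighbour")
        rows.append(row)
    return pd.DataFrame(rows)
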