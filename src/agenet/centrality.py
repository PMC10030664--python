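"""Hub ranking: Maximal Clique Centrality, Bottleneck, Betweenness.

One local measure and two shortest-path global measures, each a function
F(v) over nodes; a node u outranks v when F(u) > F(v). MCC sums
(|C| - 1)! over the maximal cliques C containing v. Bottleneck counts the
shortest-path trees in which v carries more than a quarter of the tree's
root paths; the shortest-path tree is made deterministic by always choosing
the lexicographically smallest equal-distance parent (the published
definition leaves the tree non-unique). Betweenness is the unnormalized
Brandes sum of shortest-path fractions over unordered pairs.
"""

from __future__ import annotations

import dataclasses
import math
from collections import deque

import networkx as nx
import pandas as pd

MAX_CLIQUES = 10**6


@dataclasses.dataclass
class CentralityRanking:
    """Per-node scores for one metric plus a dense, tie-sharing rank order."""

    metric: str
    scores: dict[str, float]
    ranks: dict[str, int]

    @classmethod
    def from_scores(cls, metric: str, scores: dict[str, float]) -> "CentralityRanking":
        distinct = sorted(set(scores.values()), reverse=True)
        rank_of = {s: r for r, s in enumerate(distinct, start=1)}
        return cls(metric, scores, {v: rank_of[s] for v, s in scores.items()})

    def ordered_nodes(self) -> list[str]:
        """Nodes by descending score, ties lexicographic by symbol."""
        return sorted(self.scores, key=lambda v: (-self.scores[v], v))


def mcc(graph: nx.Graph, max_cliques: int = MAX_CLIQUES) -> CentralityRanking:
    """Maximal Clique Centrality: MCC(v) = sum over maximal cliques C
    containing v of (|C| - 1)!.

    Maximal cliques are enumerated with Bron-Kerbosch (pivoting). An
    isolated node's only maximal clique is itself, so MCC = 0! = 1. Aborts
    if the enumeration exceeds ``max_cliques``.
    """
    scores = {v: 0.0 for v in graph.nodes}
    for n_seen, clique in enumerate(nx.find_cliques(graph), start=1):
        if n_seen > max_cliques:
            raise RuntimeError(f"maximal-clique count exceeds cap {max_cliques}")
        weight = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += weight
    return CentralityRanking.from_scores("MCC", scores)


def _lex_bfs_tree(graph: nx.Graph, source) -> tuple[dict, dict]:
    """Deterministic BFS shortest-path tree over source's component.

    Returns (parent, order): parent of each reached node (source -> None),
    nodes in BFS order. Parent = lexicographically smallest neighbour at
    distance d-1.
    """
    dist = {source: 0}
    order = [source]
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in graph.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                order.append(w)
                queue.append(w)
    parent = {source: None}
    for v in order[1:]:
        parent[v] = min(w for w in graph.neighbors(v) if dist[w] == dist[v] - 1)
    return parent, order


def bottleneck(graph: nx.Graph) -> CentralityRanking:
    """Bottleneck centrality BN(v) = number of shortest-path trees T_s
    (s != v) in which more than |V(T_s)|/4 of the root paths cross v.

    The paths from s crossing v are the tree paths s -> t ending in v's
    subtree (t != v), i.e. v's descendant count in T_s.
    """
    scores = {v: 0.0 for v in graph.nodes}
    for s in graph.nodes:
        parent, order = _lex_bfs_tree(graph, s)
        n_tree = len(order)
        if n_tree == 1:
            continue
        # descendants via reverse BFS order accumulation
        subtree = {v: 1 for v in order}
        for v in reversed(order[1:]):
            subtree[parent[v]] += subtree[v]
        threshold = n_tree / 4.0
        for v in order:
            if v == s:
                continue
            if subtree[v] - 1 > threshold:  # descendants of v, strict
                scores[v] += 1.0
    return CentralityRanking.from_scores("Bottleneck", scores)


def betweenness(graph: nx.Graph) -> CentralityRanking:
    """Unnormalized betweenness over unordered pairs, endpoints excluded.

    BW(v) = sum over pairs s != t in v's component of sigma_st(v)/sigma_st,
    computed by Brandes accumulation.
    """
    scores = nx.betweenness_centrality(graph, normalized=False)
    return CentralityRanking.from_scores("Betweenness", {v: float(s) for v, s in scores.items()})


def top_nodes(rankings: list[CentralityRanking], k: int) -> pd.DataFrame:
    """Per-metric top-k table with ties at the k-th score expanded.

    Returns one row per (metric, node) with score, rank, a tie flag for
    rows beyond position k admitted by a tie, and an ``in_all_metrics``
    flag marking the intersection of the per-metric top sets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frames = []
    top_sets = []
    for ranking in rankings:
        ordered = ranking.ordered_nodes()
        if len(ordered) <= k:
            chosen = ordered
            cutoff_score = -math.inf
        else:
            cutoff_score = ranking.scores[ordered[k - 1]]
            chosen = [v for v in ordered if ranking.scores[v] >= cutoff_score]
        top_sets.append(set(chosen))
        frames.append(pd.DataFrame({
            "metric": ranking.metric,
            "node": chosen,
            "score": [ranking.scores[v] for v in chosen],
            "rank": [ranking.ranks[v] for v in chosen],
            "tie_expanded": [
                i >= k and ranking.scores[v] == cutoff_score
                for i, v in enumerate(chosen)
            ],
        }))
    table = pd.concat(frames, ignore_index=True)
    common = set.intersection(*top_sets) if top_sets else set()
    table["in_all_metrics"] = table["node"].isin(common)
    return table
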