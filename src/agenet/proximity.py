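"""Interactome proximity between condition gene sets.

The closest-distance metric

    d_AB = (1/(|A|+|B|)) (sum_a min_b d(a,b) + sum_b min_a d(a,b))

uses unweighted shortest-path distances on the scaffold. Significance comes
from a degree-preserving permutation null: both sets are resampled
``n_permutations`` times from degree-matched node bins (logarithmic base-2
degree bins merged upward until each holds >= 100 nodes), giving
Z = (d_AB - d_m)/sigma_m plus an empirical p-value. Pairs with Z below the
Z threshold and BH FDR below the FDR threshold are significantly proximal.
Proximity genes are all nodes lying on any shortest path between any
(a in A, b in B) pair.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import ConditionGeneSet, Scaffold

logger = logging.getLogger("agenet")


# ---------------------------------------------------------------------------
# Distance infrastructure
# ---------------------------------------------------------------------------

def _node_order(scaffold: Scaffold) -> tuple[list[str], dict[str, int]]:
    cached = getattr(scaffold, "_agenet_order", None)
    if cached is None:
        nodes = sorted(scaffold.nodes)
        cached = (nodes, {g: i for i, g in enumerate(nodes)})
        scaffold._agenet_order = cached
    return cached


def _adjacency(scaffold: Scaffold) -> csr_matrix:
    cached = getattr(scaffold, "_agenet_adj", None)
    if cached is None:
        nodes, index = _node_order(scaffold)
        rows, cols = [], []
        for a, b in scaffold.edges():
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
        n = len(nodes)
        cached = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                            shape=(n, n))
        scaffold._agenet_adj = cached
    return cached


def _distance_matrix(scaffold: Scaffold) -> np.ndarray:
    """All-pairs unweighted shortest-path matrix (inf where unreachable)."""
    cached = getattr(scaffold, "_agenet_apsp", None)
    if cached is None:
        adj = _adjacency(scaffold)
        cached = shortest_path(adj, method="D", unweighted=True).astype(np.float32)
        scaffold._agenet_apsp = cached
        logger.info("distance matrix computed for %d nodes", adj.shape[0])
    return cached


def _multi_source_distances(scaffold: Scaffold, sources: Iterable[str]) -> dict[str, int]:
    """Hop distance from every node to its nearest source (multi-source BFS)."""
    dist: dict[str, int] = {s: 0 for s in sources}
    queue = deque(dist)
    graph = scaffold.graph
    while queue:
        u = queue.popleft()
        for w in graph.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


# ---------------------------------------------------------------------------
# Closest distance
# ---------------------------------------------------------------------------

def closest_distance(scaffold: Scaffold, a_set: ConditionGeneSet | Iterable[str],
                     b_set: ConditionGeneSet | Iterable[str]) -> float:
    """Mean closest shortest-path distance between two mapped gene sets.

    Genes with no finite distance to the other set are excluded from both
    numerator and denominator (count logged); symmetric in (A, B).
    """
    a = set(a_set) & scaffold.nodes
    b = set(b_set) & scaffold.nodes
    if not a or not b:
        raise ValueError("both gene sets must map onto the scaffold")
    dist_to_b = _multi_source_distances(scaffold, b)
    dist_to_a = _multi_source_distances(scaffold, a)
    terms = [dist_to_b[g] for g in a if g in dist_to_b]
    terms += [dist_to_a[g] for g in b if g in dist_to_a]
    n_unreachable = (len(a) + len(b)) - len(terms)
    if not terms:
        raise ValueError("no finite distances between the two sets")
    if n_unreachable:
        logger.info("closest_distance: excluded %d unreachable genes", n_unreachable)
    return float(np.mean(terms))


def _closest_distance_idx(dist: np.ndarray, a_idx: np.ndarray,
                          b_idx: np.ndarray) -> tuple[float, int]:
    """(d_AB, n excluded as unreachable) from a precomputed distance matrix."""
    sub = dist[np.ix_(a_idx, b_idx)]
    min_a = sub.min(axis=1)
    min_b = sub.min(axis=0)
    terms = np.concatenate([min_a, min_b])
    finite = np.isfinite(terms)
    if not finite.any():
        raise ValueError("no finite distances between the two sets")
    return float(terms[finite].mean()), int((~finite).sum())


# ---------------------------------------------------------------------------
# Degree-matched null
# ---------------------------------------------------------------------------

def _degree_bins(scaffold: Scaffold, min_bin_size: int = 100) -> dict[str, int]:
    """Assign every scaffold node to a merged log2-degree bin.

    Nodes are binned by floor(log2(degree)); consecutive bins are merged
    upward until each merged bin holds >= ``min_bin_size`` nodes (a single
    bin covering the whole graph if it is smaller than that).
    """
    cached = getattr(scaffold, "_agenet_degree_bins", None)
    if cached is not None:
        return cached
    graph = scaffold.graph
    raw_bin = {v: int(np.floor(np.log2(max(graph.degree(v), 1)))) for v in graph.nodes}
    order = sorted(set(raw_bin.values()))
    counts = {b: 0 for b in order}
    for b in raw_bin.values():
        counts[b] += 1
    merged_of: dict[int, int] = {}
    group: list[int] = []
    group_count = 0
    group_id = 0
    for b in order:
        group.append(b)
        group_count += counts[b]
        if group_count >= min_bin_size:
            for g in group:
                merged_of[g] = group_id
            group_id += 1
            group, group_count = [], 0
    if group:  # leftover small tail merges into the previous group
        target = group_id - 1 if group_id > 0 else 0
        for g in group:
            merged_of[g] = target
    assignment = {v: merged_of[b] for v, b in raw_bin.items()}
    scaffold._agenet_degree_bins = assignment
    return assignment


def degree_matched_sample(scaffold: Scaffold,
                          template: ConditionGeneSet | Iterable[str],
                          rng: np.random.Generator) -> set[str]:
    """Draw |template| nodes matching the template's degree-bin histogram.

    One draw per template node from its merged degree bin, without
    replacement within each bin.
    """
    bins = _degree_bins(scaffold)
    members: dict[int, list[str]] = {}
    for v, b in bins.items():
        members.setdefault(b, []).append(v)
    needed: dict[int, int] = {}
    for g in template:
        needed[bins[g]] = needed.get(bins[g], 0) + 1
    sample: set[str] = set()
    for b, count in sorted(needed.items()):
        pool = sorted(members[b])
        if count > len(pool):
            raise ValueError(
                f"degree bin {b} holds {len(pool)} nodes but {count} draws requested"
            )
        chosen = rng.choice(len(pool), size=count, replace=False)
        sample.update(pool[i] for i in chosen)
    return sample


# ---------------------------------------------------------------------------
# Permutation Z
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProximityResult:
    """Observed proximity, its degree-matched null, and significance calls."""

    name_a: str
    name_b: str
    d_ab: float
    d_mean: float
    d_sd: float
    z: float
    p_empirical: float
    q: float = float("nan")
    significant: bool = False
    n_mapped_a: int = 0
    n_mapped_b: int = 0
    n_unreachable: int = 0


def proximity_z(scaffold: Scaffold, a_set: ConditionGeneSet,
                b_set: ConditionGeneSet, config: RunConfig | None = None,
                rng: np.random.Generator | None = None) -> ProximityResult:
    """d_AB with a degree-preserving permutation null of both sets.

    Z = (d_AB - d_m)/sigma_m over ``n_permutations`` independent resamples;
    empirical p = (#{null <= observed} + 1)/(n + 1). A degenerate null
    (sigma_m = 0) yields Z = NaN.
    """
    if config is None:
        config = RunConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    nodes, index = _node_order(scaffold)
    dist = _distance_matrix(scaffold)
    a = sorted(set(a_set) & scaffold.nodes)
    b = sorted(set(b_set) & scaffold.nodes)
    if not a or not b:
        raise ValueError("both gene sets must map onto the scaffold")
    a_idx = np.array([index[g] for g in a])
    b_idx = np.array([index[g] for g in b])
    d_obs, n_unreach = _closest_distance_idx(dist, a_idx, b_idx)
    null = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        ra = degree_matched_sample(scaffold, a, rng)
        rb = degree_matched_sample(scaffold, b, rng)
        ra_idx = np.array([index[g] for g in ra])
        rb_idx = np.array([index[g] for g in rb])
        null[i], _ = _closest_distance_idx(dist, ra_idx, rb_idx)
    d_mean = float(null.mean())
    d_sd = float(null.std())
    z = (d_obs - d_mean) / d_sd if d_sd > 0 else float("nan")
    p_emp = (float(np.sum(null <= d_obs)) + 1.0) / (config.n_permutations + 1.0)
    return ProximityResult(
        name_a=getattr(a_set, "name", "A"), name_b=getattr(b_set, "name", "B"),
        d_ab=d_obs, d_mean=d_mean, d_sd=d_sd, z=z, p_empirical=p_emp,
        n_mapped_a=len(a), n_mapped_b=len(b), n_unreachable=n_unreach,
    )


# ---------------------------------------------------------------------------
# Proximity genes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProximityGeneSet:
    """Nodes on A-B shortest paths with their roles.

    Roles: ``common`` (in both sets), ``endpoint-A``, ``endpoint-B``, or
    ``intermediate`` (on a shortest path but in neither set).
    """

    roles: dict[str, str]

    @property
    def nodes(self) -> set[str]:
        return set(self.roles)

    def with_role(self, role: str) -> set[str]:
        return {v for v, r in self.roles.items() if r == role}


def proximity_genes(scaffold: Scaffold, a_set: ConditionGeneSet,
                    b_set: ConditionGeneSet) -> ProximityGeneSet:
    """Collect all nodes on all shortest paths between every (a, b) pair.

    A node v lies on a shortest a-b path iff d(a,v) + d(v,b) = d(a,b);
    endpoints are included. Unreachable pairs contribute nothing.
    """
    nodes, index = _node_order(scaffold)
    adj = _adjacency(scaffold)
    a = sorted(set(a_set) & scaffold.nodes)
    b = sorted(set(b_set) & scaffold.nodes)
    if not a or not b:
        raise ValueError("both gene sets must map onto the scaffold")
    a_idx = np.array([index[g] for g in a])
    b_idx = np.array([index[g] for g in b])
    dist_a = shortest_path(adj, method="D", unweighted=True, indices=a_idx)
    dist_b = shortest_path(adj, method="D", unweighted=True, indices=b_idx)
    on_path = np.zeros(len(nodes), dtype=bool)
    for i in range(len(a)):
        for j in range(len(b)):
            d_ab = dist_a[i, index[b[j]]]
            if not np.isfinite(d_ab):
                continue
            on_path |= (dist_a[i] + dist_b[j]) == d_ab
    a_genes, b_genes = set(a), set(b)
    roles = {}
    for v in np.flatnonzero(on_path):
        g = nodes[v]
        if g in a_genes and g in b_genes:
            roles[g] = "common"
        elif g in a_genes:
            roles[g] = "endpoint-A"
        elif g in b_genes:
            roles[g] = "endpoint-B"
        else:
            roles[g] = "intermediate"
    return ProximityGeneSet(roles)


# ---------------------------------------------------------------------------
# Pairwise matrix
# ---------------------------------------------------------------------------

def pairwise_proximity_matrix(scaffold: Scaffold,
                              conditions: Sequence[ConditionGeneSet],
                              reference: ConditionGeneSet,
                              config: RunConfig | None = None) -> pd.DataFrame:
    """Proximity of a reference set against each condition set.

    BH correction runs across the tested pairs; significance stars mark
    Z < z_threshold with q < fdr_threshold.
    """
    if config is None:
        config = RunConfig()
    if not conditions:
        return pd.DataFrame(columns=[
            "reference", "condition", "d_ab", "d_mean", "d_sd", "z",
            "p_empirical", "q", "significant",
        ])
    seeds = np.random.SeedSequence(config.rng_seed).spawn(len(conditions))
    results = [
        proximity_z(scaffold, reference, cond, config,
                    rng=np.random.default_rng(seed))
        for cond, seed in zip(conditions, seeds)
    ]
    pvals = np.array([r.p_empirical for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    rows = []
    for r, q in zip(results, qvals):
        r.q = float(q)
        r.significant = bool(
            np.isfinite(r.z) and r.z < config.z_threshold and q < config.fdr_threshold
        )
        rows.append({
            "reference": r.name_a, "condition": r.name_b, "d_ab": r.d_ab,
            "d_mean": r.d_mean, "d_sd": r.d_sd, "z": r.z,
            "p_empirical": r.p_empirical, "q": r.q, "significant": r.significant,
        })
    return pd.DataFrame(rows)


def common_theme(gene_sets: Sequence[ProximityGeneSet]) -> set[str]:
    """Nodes present in every pairwise proximity-gene set."""
    if not gene_sets:
        return set()
    return set.intersection(*(g.nodes for g in gene_sets))
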