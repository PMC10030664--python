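"""Brute-force / definitional oracles used to validate the implementation.

Every oracle here recomputes a quantity from its definition (subset
enumeration, explicit path enumeration, direct constrained optimization,
exhaustive rank assignments) and stays independent of the code paths under
test.
"""
import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
from scipy.optimize import LinearConstraint, linprog, minimize
from scipy.special import xlogy


# ---------------------------------------------------------------------------
# Centrality oracles
# ---------------------------------------------------------------------------

def brute_mcc(graph):
    """MCC via subset enumeration of all maximal cliques."""
    nodes = list(graph.nodes)
    n = len(nodes)
    cliques = []
    for r in range(1, n + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(a, b) for a, b in itertools.combinations(subset, 2)):
                s = set(subset)
                if not any(all(graph.has_edge(x, v) for v in subset)
                           for x in nodes if x not in s):
                    cliques.append(s)
    scores = {v: 0.0 for v in nodes}
    for c in cliques:
        for v in c:
            scores[v] += math.factorial(len(c) - 1)
    return scores

def _oracle_bfs_tree(graph, source):
    """Same deterministic tree rule, built independently: explicit distance
    labelling, parent = min neighbour one level up."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in sorted(frontier):
            for w in graph.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = set(nxt)
    parent = {}
    for v, d in dist.items():
        if v == source:
            continue
        parent[v] = min(u for u in graph.neighbors(v) if dist[u] == d - 1)
    return dist, parent

def brute_bottleneck(graph):
    """BN by walking every root-to-target parent chain explicitly."""
    scores = {v: 0.0 for v in graph.nodes}
    for s in graph.nodes:
        dist, parent = _oracle_bfs_tree(graph, s)
        n_tree = len(dist)
        crossing = {v: 0 for v in dist}
        for t in dist:
            if t == s:
                continue
            node = parent[t]
            while node != s:
                crossing[node] += 1   # paths s->t (t != v) crossing v
                node = parent[node]
        for v in dist:
            if v != s and crossing[v] > n_tree / 4.0:
                scores[v] += 1.0
    return scores

def brute_betweenness(graph):
    """BW by explicit enumeration of all shortest paths per pair."""
    scores = {v: 0.0 for v in graph.nodes}
    nodes = list(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                scores[v] += through / sigma
    return scores


# ---------------------------------------------------------------------------
# Proximity oracles
# ---------------------------------------------------------------------------

def brute_closest_distance(graph, a_set, b_set):
    """Direct min-over-pairs arithmetic with per-pair BFS distances."""
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    terms = []
    for a in a_set:
        d = [lengths[a][b] for b in b_set if b in lengths[a]]
        if d:
            terms.append(min(d))
    for b in b_set:
        d = [lengths[b][a] for a in a_set if a in lengths[b]]
        if d:
            terms.append(min(d))
    if not terms:
        raise ValueError("no finite distances")
    return float(np.mean(terms))

def brute_proximity_genes(graph, a_set, b_set):
    """Union of nodes over explicitly enumerated shortest paths."""
    out = set()
    for a in a_set:
        for b in b_set:
            if nx.has_path(graph, a, b):
                for path in nx.all_shortest_paths(graph, a, b):
                    out.update(path)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum oracle
# ---------------------------------------------------------------------------

def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Mid-ranks for ties; p = P(|W - E[W]| >= |w_obs - E[W]|) under random
    assignment of the pooled values to groups.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Ensemble entropy oracle
# ---------------------------------------------------------------------------

def oracle_entropy(n, edges, bins_of_edges, n_bins):
    """Maximum ensemble entropy by direct constrained optimization.

    Facial reduction (linear programs detect coordinates pinned to zero by
    the constraints) followed by a logarithmic-barrier path solved with
    SLSQP and a trust-constr polish. Handles boundary optima (forced
    links) exactly; independent of the canonical-ensemble solution it
    validates.
    """
    pairs = list(itertools.combinations(range(n), 2))
    deg = np.zeros(n)
    m = np.zeros(n_bins)
    for (i, j), q in zip(edges, bins_of_edges):
        deg[i] += 1
        deg[j] += 1
        m[q] += 1
    npair = len(pairs)
    w = n_bins + 1                      # per pair: [p0, p_1..p_Q]
    nv = npair * w
    A_rows, b_rows = [], []
    for kk in range(npair):             # normalization per pair
        row = np.zeros(nv)
        row[kk * w:(kk + 1) * w] = 1
        A_rows.append(row)
        b_rows.append(1.0)
    for i in range(n):                  # degrees
        row = np.zeros(nv)
        for kk, (a, bb) in enumerate(pairs):
            if i in (a, bb):
                row[kk * w + 1:(kk + 1) * w] = 1
        A_rows.append(row)
        b_rows.append(deg[i])
    for q in range(n_bins):             # bin counts
        row = np.zeros(nv)
        row[q + 1::w] = 1
        A_rows.append(row)
        b_rows.append(m[q])
    A = np.array(A_rows)
    b = np.array(b_rows)

    def drop_dependent(A, b):
        keep = []
        for r in range(A.shape[0]):
            if np.linalg.matrix_rank(A[keep + [r]]) == len(keep) + 1:
                keep.append(r)
        return A[keep], b[keep]

    A, b = drop_dependent(A, b)
    # facial reduction: which coordinates can be strictly positive?
    free = np.zeros(nv, dtype=bool)
    for v in range(nv):
        c = np.zeros(nv)
        c[v] = -1.0
        res = linprog(c, A_eq=A, b_eq=b, bounds=(0, 1), method="highs")
        if res.status != 0:
            raise RuntimeError("oracle feasibility LP failed")
        free[v] = -res.fun > 1e-9
    if (~free).any():
        A, b = drop_dependent(A[:, free], b)
    nfree = int(free.sum())
    if nfree == 0:
        return 0.0

    def negS(p):
        return float(xlogy(p, p).sum())

    def obj(p, mu):
        if (p <= 0).any():
            return np.inf
        return float((p * np.log(p)).sum() - mu * np.log(p).sum())

    def grad(p, mu):
        return np.log(p) + 1 - mu / p

    cons = [{"type": "eq", "fun": lambda p: A @ p - b, "jac": lambda p: A}]
    res = linprog(np.zeros(nfree), A_eq=A, b_eq=b, bounds=(1e-7, 1),
                  method="highs")
    pv = res.x if res.status == 0 else np.linalg.lstsq(A, b, rcond=None)[0]
    pv = np.clip(pv, 1e-7, 1)
    best = None
    for mu in 10.0 ** np.arange(-1.0, -15.0, -0.5):
        sol = minimize(obj, pv, args=(mu,), jac=grad, method="SLSQP",
                       constraints=cons,
                       options={"maxiter": 1000, "ftol": 1e-18})
        cand = sol.x
        if (cand > 0).all() and np.abs(A @ cand - b).max() < 1e-7:
            pv = cand
            s = -negS(cand)
            if best is None or s > best:
                best = s
    # warm-started interior-point polish removes the residual barrier bias
    sol = minimize(lambda p: float(xlogy(p, p).sum()), pv,
                   jac=lambda p: np.log(np.clip(p, 1e-300, None)) + 1,
                   method="trust-constr", bounds=[(0, 1)] * nfree,
                   constraints=[LinearConstraint(A, b, b)],
                   options={"maxiter": 2000, "gtol": 1e-14, "xtol": 1e-16})
    if np.abs(A @ sol.x - b).max() < 1e-8:
        s = -negS(sol.x)
        if best is None or s > best:
            best = s
    return best
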