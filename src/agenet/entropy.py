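"""Maximum-entropy ensemble network entropy and local node entropy.

A sample's weighted network is summarised by two sets of observables: its
degree sequence k_i and its edge-weight bin counts m_q. The network's
entropy is the Shannon entropy of the maximum-entropy ensemble of networks
reproducing those observables in expectation. Each node pair (i, j) is
either unlinked or linked in exactly one weight bin q, with

    p_ij(q) = x_i x_j y_q / (1 + x_i x_j Y),   Y = sum_r y_r,
    p0_ij   = 1 / (1 + x_i x_j Y),

the canonical (soft-constraint) solution for these observables. Because the
bin factor y_q is shared by all pairs, the conditional bin distribution is
the same for every pair and the model factorizes: the linkage part is the
binary configuration model fitted to the degree sequence, and the bin part
is solved in closed form, y_q / Y = m_q / M. The total entropy is then

    S = S_links + M * H(m/M),

where S_links is the configuration-model entropy over pairs and H(m/M) the
Shannon entropy of the normalized bin histogram. The node multipliers x_i
are solved by a damped fixed-point iteration; nodes whose degree equals
(active nodes - 1) force their pair probabilities to 1 and are peeled off
analytically before iterating (a complete graph reduces entirely to forced
pairs, giving S_links = 0 exactly).

Local entropy is the per-node Shannon entropy of the node's normalized
incident edge weights, S_i = -sum_j p_ij ln p_ij with p_ij = w_ij / sum w.
All entropies are in nats.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import ExpressionMatrix, Scaffold
from .sample_network import (WeightBinning, WeightedSampleNetwork,
                             bin_weights, build_sample_network)

logger = logging.getLogger("agenet")


# ---------------------------------------------------------------------------
# Ensemble model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnsembleModel:
    """Fitted maximum-entropy ensemble for one sample network.

    ``x`` holds node multipliers aligned with ``nodes`` (np.inf marks nodes
    whose pairs were peeled as forced, 0 marks degree-zero nodes); ``y`` the
    bin multipliers in the Y = 1 gauge (so y_q = m_q / M); ``residual`` the
    largest relative degree-constraint violation of the fit.
    """

    nodes: list[str]
    x: np.ndarray
    y: np.ndarray
    degrees: np.ndarray
    bin_counts: np.ndarray
    residual: float
    n_nodes: int
    _forced_partners: dict[int, frozenset[int]]

    def link_probability(self, i: int, j: int) -> float:
        """P(pair (i, j) is linked in some bin)."""
        if i == j:
            raise ValueError("self-pairs are not part of the ensemble")
        if j in self._forced_partners.get(i, ()) or i in self._forced_partners.get(j, ()):
            return 1.0
        xi, xj = self.x[i], self.x[j]
        if xi == 0.0 or xj == 0.0:
            return 0.0
        if np.isinf(xi) or np.isinf(xj):
            # forced node paired with a non-partner (zero/removed node)
            return 0.0
        z = xi * xj
        return z / (1.0 + z)

    def pair_probabilities(self, i: int, j: int) -> tuple[float, np.ndarray]:
        """(p0_ij, p_ij(q) per bin) for one node pair."""
        p = self.link_probability(i, j)
        return 1.0 - p, p * self.y

    def expected_degrees(self) -> np.ndarray:
        n = len(self.nodes)
        exp_k = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i != j:
                    exp_k[i] += self.link_probability(i, j)
        return exp_k

    def expected_bin_counts(self) -> np.ndarray:
        total = 0.0
        n = len(self.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                total += self.link_probability(i, j)
        return total * self.y


def _h2(p: np.ndarray) -> np.ndarray:
    """Binary entropy -[p ln p + (1-p) ln(1-p)], elementwise, 0 ln 0 = 0."""
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p)
    mask = (p > 0) & (p < 1)
    pm = p[mask]
    out[mask] = -(pm * np.log(pm) + (1 - pm) * np.log1p(-pm))
    return out


def _solve_multipliers(k_classes: np.ndarray, counts: np.ndarray,
                       tol: float, max_iter: int) -> tuple[np.ndarray, float]:
    """Solve the degree-class multipliers of the link ensemble.

    Classes (one per distinct effective degree, ``counts`` nodes each) share
    a multiplier x_d; the system E_d(x) = sum_e (c_e - delta_de)
    x_d x_e/(1 + x_d x_e) = k_d is solved by damped fixed-point sweeps with
    a Newton phase on theta = ln x (the fixed point alone creeps when the
    degree sequence sits near the graphical boundary, where some link
    probabilities tend to 1). Returns (x, max relative residual).
    """

    def expected(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = theta[:, None] + theta[None, :]
        p = 1.0 / (1.0 + np.exp(-s))
        return p @ counts - np.diag(p), p

    theta = np.log(k_classes / np.sqrt(k_classes @ counts))
    residual = np.inf
    # iterate well past the required tolerance: near the graphical boundary
    # the multipliers are large, and the entropy inherits an error of order
    # residual x |theta|
    target = min(tol, 1e-12)
    for sweep in range(max_iter):
        exp_k, p = expected(theta)
        residual = float(np.max(np.abs(exp_k - k_classes) / k_classes))
        if residual <= target:
            return np.exp(theta), residual
        if sweep < 20:
            # damped multiplicative sweeps to reach the Newton basin
            xs = np.exp(theta)
            denom = (xs[None, :] * (1.0 - p)) @ counts - xs * (1.0 - np.diag(p))
            with np.errstate(divide="ignore"):
                theta = 0.5 * theta + 0.5 * np.log(k_classes / denom)
            continue
        q = p * (1.0 - p)
        jac = q * counts[None, :]
        np.fill_diagonal(jac, np.diag(jac) + q @ counts - 2.0 * np.diag(q))
        try:
            step = np.linalg.solve(jac, exp_k - k_classes)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(jac, exp_k - k_classes, rcond=None)[0]
        step = np.clip(step, -5.0, 5.0)
        theta = theta - step
    return np.exp(theta), residual


def fit_ensemble(net: WeightedSampleNetwork, binning: WeightBinning | None = None,
                 tol: float = 1e-8, max_iter: int = 10_000) -> EnsembleModel:
    """Fit the maximum-entropy ensemble to one sample network.

    Raises on an edgeless network, on degrees that exceed the node count,
    and on non-convergence after ``max_iter`` damped fixed-point sweeps.
    """
    if net.n_edges == 0:
        raise ValueError(f"sample {net.sample_id!r}: cannot fit an edgeless network")
    if binning is None:
        binning = bin_weights(net)
    n = net.n_nodes
    k = net.degrees().astype(float)
    if np.any(k > n - 1):
        bad = net.nodes[int(np.argmax(k))]
        raise ValueError(f"node {bad!r} has degree exceeding n-1: not graphical")
    m = binning.counts.astype(float)
    M = float(m.sum())
    y = m / M  # closed-form bin multipliers in the Y = 1 gauge

    # Peel forced nodes (degree == active - 1: all active pairs linked with
    # certainty) and zero-degree nodes (all pairs unlinked) before iterating.
    active = np.ones(n, dtype=bool)
    k_eff = k.copy()
    forced_partners: dict[int, frozenset[int]] = {}
    x = np.zeros(n)
    changed = True
    while changed:
        changed = False
        act_idx = np.flatnonzero(active)
        n_act = len(act_idx)
        if np.any(k_eff[act_idx] < 0) or np.any(k_eff[act_idx] > n_act - 1):
            raise ValueError("degree sequence infeasible after peeling forced nodes")
        zeros = act_idx[k_eff[act_idx] == 0]
        if len(zeros):
            active[zeros] = False
            x[zeros] = 0.0
            changed = True
            continue
        if n_act > 1:
            full = act_idx[k_eff[act_idx] == n_act - 1]
            if len(full):
                i = int(full[0])
                partners = frozenset(int(j) for j in act_idx if j != i)
                forced_partners[i] = partners
                x[i] = np.inf
                active[i] = False
                k_eff[list(partners)] -= 1.0
                k_eff[i] = 0.0
                changed = True

    act_idx = np.flatnonzero(active)
    residual = 0.0
    if len(act_idx):
        # Degree-class collapse: nodes sharing an effective degree share x.
        k_act = k_eff[act_idx]
        uniq, inverse = np.unique(k_act, return_inverse=True)
        counts = np.bincount(inverse).astype(float)
        xs, residual = _solve_multipliers(uniq, counts, tol, max_iter)
        if residual > tol:
            raise RuntimeError(
                f"ensemble fit did not converge after {max_iter} iterations "
                f"(max relative degree residual {residual:.3e})"
            )
        x[act_idx] = xs[inverse]

    model = EnsembleModel(
        nodes=net.nodes, x=x, y=y, degrees=k.astype(np.int64),
        bin_counts=binning.counts.copy(), residual=residual,
        n_nodes=n, _forced_partners=forced_partners,
    )
    # stash class structure for the closed-form entropy evaluation
    model._class_x = x[act_idx]
    model._class_idx = act_idx
    model._n_forced_pairs = sum(len(p) for p in forced_partners.values())
    return model


def global_entropy(model: EnsembleModel) -> tuple[float, float]:
    """Ensemble Shannon entropy S (nats) and its per-node normalization.

    S = -sum_{i<j} [p0 ln p0 + sum_q p_q ln p_q]; with the factorized model
    this is the configuration-model pair entropy plus M * H(m/M). Forced
    pairs (p = 1) and null pairs (p = 0) contribute zero linkage entropy.
    """
    xs = model._class_x
    s_links = 0.0
    if len(xs):
        # unique multipliers collapse the pair sum
        uniq, inv = np.unique(xs, return_inverse=True)
        c = np.bincount(inv).astype(float)
        z = np.outer(uniq, uniq)
        h = _h2(z / (1.0 + z))
        pair_counts = np.outer(c, c)
        np.fill_diagonal(pair_counts, c * (c - 1) / 2.0)
        s_links = float(np.sum(np.triu(pair_counts * h, k=1)) +
                        np.sum(np.diag(pair_counts) * np.diag(h)))
    m = model.bin_counts.astype(float)
    M = m.sum()
    frac = m[m > 0] / M
    h_bins = float(-(frac * np.log(frac)).sum())
    s = s_links + M * h_bins
    return s, s / model.n_nodes


# ---------------------------------------------------------------------------
# Local entropy
# ---------------------------------------------------------------------------

def local_entropy(net: WeightedSampleNetwork,
                  binning: WeightBinning | None = None) -> dict[str, float]:
    """Per-node Shannon entropy of normalized incident edge weights (nats).

    p_ij = w_ij / sum_j' w_ij'; S_i = -sum_j p_ij ln p_ij. Zero-weight edges
    contribute nothing; nodes whose incident weights are all zero, and
    isolated nodes, get S_i = 0. When ``binning`` is given, raw weights are
    replaced by their bin midpoints (the binned variant).
    """
    w = net.weights
    if binning is not None:
        mids = 0.5 * (binning.bin_edges[:-1] + binning.bin_edges[1:])
        w = mids[binning.bin_of_edge]
    n = net.n_nodes
    wsum = np.zeros(n)
    np.add.at(wsum, net.edges[:, 0], w)
    np.add.at(wsum, net.edges[:, 1], w)
    ent = np.zeros(n)
    for col in (0, 1):
        idx = net.edges[:, col]
        denom = wsum[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, w / np.where(denom > 0, denom, 1.0), 0.0)
            contrib = np.where(p > 0, -p * np.log(p), 0.0)
        np.add.at(ent, idx, contrib)
    n_isolated = int(np.sum(net.degrees() == 0))
    if n_isolated:
        logger.info("local_entropy %s: %d isolated nodes set to 0",
                    net.sample_id, n_isolated)
    return {g: float(ent[i]) for i, g in enumerate(net.nodes)}


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EntropyTable:
    """Per-sample global entropies and the node x sample local-entropy matrix.

    ``samples`` columns: sample, group, n_nodes, n_edges, global_entropy_raw,
    global_entropy_per_node. ``local`` is genes x samples (NaN where a gene
    was absent from that sample's network).
    """

    samples: pd.DataFrame
    local: pd.DataFrame
    groups: dict[str, int]


def cohort_entropy(expr: ExpressionMatrix, scaffold: Scaffold,
                   tol: float = 1e-8, max_iter: int = 10_000) -> EntropyTable:
    """Build every sample's network and compute global + local entropies."""
    rows = []
    local_cols: dict[str, dict[str, float]] = {}
    for sample in expr.samples:
        net = build_sample_network(expr, sample, scaffold)
        binning = bin_weights(net)
        model = fit_ensemble(net, binning, tol=tol, max_iter=max_iter)
        s_raw, s_norm = global_entropy(model)
        rows.append({
            "sample": sample, "group": expr.groups[sample],
            "n_nodes": net.n_nodes, "n_edges": net.n_edges,
            "global_entropy_raw": s_raw, "global_entropy_per_node": s_norm,
        })
        local_cols[sample] = local_entropy(net, binning=None)
    samples_df = pd.DataFrame(rows)
    local_df = pd.DataFrame(local_cols)  # genes x samples, NaN where absent
    local_df = local_df.reindex(columns=expr.samples)
    logger.info("cohort_entropy: %d samples, %d genes with local entropies",
                len(rows), local_df.shape[0])
    return EntropyTable(samples_df, local_df, dict(expr.groups))


# ---------------------------------------------------------------------------
# Differential entropy
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when the combined sample size is <= 20 and there
    are no ties; otherwise the normal approximation with mid-ranked ties and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def differential_entropy(table: EntropyTable, young_groups, old_groups,
                         config: RunConfig | None = None) -> pd.DataFrame:
    """Young-vs-old Wilcoxon test on per-node local entropies.

    Returns a DataFrame indexed by gene with columns stat_young, stat_old,
    shift (old - young location difference), statistic, pvalue, qvalue and
    significant; significant <=> q < fdr_threshold and |shift| >
    median_shift_threshold. Nodes absent from every sample of either side
    are dropped (logged).
    """
    if config is None:
        config = RunConfig()
    young = [s for s in table.local.columns if table.groups[s] in set(young_groups)]
    old = [s for s in table.local.columns if table.groups[s] in set(old_groups)]
    if len(young) < 2 or len(old) < 2:
        raise ValueError(
            f"need >= 2 samples per side, got {len(young)} young / {len(old)} old"
        )
    loc = np.median if config.diff_statistic == "median" else np.mean
    records = []
    n_dropped = 0
    for gene, row in table.local.iterrows():
        yv = row[young].dropna().to_numpy(dtype=float)
        ov = row[old].dropna().to_numpy(dtype=float)
        if len(yv) == 0 or len(ov) == 0:
            n_dropped += 1
            continue
        stat, p = wilcoxon_rank_sum(yv, ov)
        records.append({
            "gene": gene,
            "stat_young": float(loc(yv)),
            "stat_old": float(loc(ov)),
            "shift": float(loc(ov) - loc(yv)),
            "statistic": stat,
            "pvalue": p,
        })
    if n_dropped:
        logger.info("differential_entropy: dropped %d genes absent on one side",
                    n_dropped)
    result = pd.DataFrame(records).set_index("gene")
    _, qvals, _, _ = multipletests(result["pvalue"].to_numpy(), method="fdr_bh")
    result["qvalue"] = qvals
    result["significant"] = (
        (result["qvalue"] < config.fdr_threshold)
        & (result["shift"].abs() > config.median_shift_threshold)
    )
    return result.sort_values("pvalue")
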