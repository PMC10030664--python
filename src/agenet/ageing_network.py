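"""Condition networks: DEG seeds plus first neighbours on the scaffold.

A condition network is the scaffold subgraph induced on a DEG list and the
DEGs' first neighbours; it is the object on which hub ranking and dense-
module detection operate. A deliberately simple Welch-t differential
expression stand-in is provided so fully synthetic runs are self-contained;
real-data users supply externally computed DEG lists.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConditionGeneSet, ExpressionMatrix, Scaffold

logger = logging.getLogger("agenet")


@dataclasses.dataclass
class ConditionNetwork:
    """Scaffold subgraph induced on DEG seeds and their first neighbours."""

    seed_genes: frozenset[str]
    graph: nx.Graph
    provenance: dict[str, str]  # node -> "seed" | "neighbour"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_condition_network(degs: ConditionGeneSet,
                            scaffold: Scaffold) -> ConditionNetwork:
    """Expand DEGs by one hop and take the full induced scaffold subgraph.

    Node set = mapped DEGs plus every scaffold node adjacent to a DEG; the
    induced subgraph keeps neighbour-neighbour edges as well.
    """
    seeds = set(degs.genes) & scaffold.nodes
    if not seeds:
        raise ValueError(f"condition {degs.name!r}: no seed genes on the scaffold")
    neighbours: set[str] = set()
    for s in seeds:
        neighbours.update(scaffold.graph.neighbors(s))
    nodes = seeds | neighbours
    sub = scaffold.graph.subgraph(nodes).copy()
    provenance = {n: ("seed" if n in seeds else "neighbour") for n in sub.nodes}
    logger.info(
        "build_condition_network %s: %d seeds -> %d nodes, %d edges",
        degs.name, len(seeds), sub.number_of_nodes(), sub.number_of_edges(),
    )
    return ConditionNetwork(frozenset(seeds), sub, provenance)


def simple_de(expr: ExpressionMatrix, group_a, group_b,
              q_cutoff: float = 0.05) -> tuple[list[str], np.ndarray]:
    """Per-gene Welch t-test between two sample groups, BH-corrected.

    A plain stand-in for a full differential-expression pipeline, intended
    for synthetic cohorts only. Returns (selected genes at q < q_cutoff,
    signs of their group-B minus group-A change). Zero-variance genes get
    p = 1.
    """
    sa = expr.samples_in_groups(group_a)
    sb = expr.samples_in_groups(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(f"need >= 2 samples per group, got {len(sa)} vs {len(sb)}")
    a = expr.values[sa].to_numpy(dtype=float)
    b = expr.values[sb].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    delta_mean = b.mean(axis=1) - a.mean(axis=1)
    # zero within-group variance: undefined t; equal means -> p = 1,
    # separated means -> p = 0 (complete separation)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    pvals = np.where(degenerate, np.where(delta_mean == 0, 1.0, 0.0), pvals)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    delta = b.mean(axis=1) - a.mean(axis=1)
    selected = qvals < q_cutoff
    genes = [g for g, s in zip(expr.genes, selected) if s]
    signs = np.sign(delta[selected])
    logger.info("simple_de: %d/%d genes at q < %g", len(genes), len(pvals), q_cutoff)
    return genes, signs
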