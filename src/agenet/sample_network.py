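"""Sample-specific weighted networks from expression + PPI scaffold.

One sample's expression profile is laid onto the scaffold: nodes carry the
sample's expression values, zero-expression nodes are removed, and each edge
is weighted by the distance (absolute difference) between its endpoints'
expression values. Edge weights are then discretized into floor(sqrt(N))
equal-width bins spanning the observed weight range, giving the
edge-weight-distribution observable used by the ensemble entropy model.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix, Scaffold

logger = logging.getLogger("agenet")


@dataclasses.dataclass
class WeightedSampleNetwork:
    """One sample's expression-integrated PPI network.

    ``nodes`` lists retained genes (expression > 0) in sorted order;
    ``edges`` is an (M, 2) array of indices into ``nodes``; ``weights`` the
    per-edge absolute expression differences.
    """

    sample_id: str
    nodes: list[str]
    edges: np.ndarray           # (M, 2) int indices into nodes
    weights: np.ndarray         # (M,) float
    expression: np.ndarray      # (N,) float, aligned with nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg


@dataclasses.dataclass
class WeightBinning:
    """Equal-width discretization of a sample network's edge weights."""

    n_bins: int
    bin_edges: np.ndarray       # (n_bins + 1,) ascending
    counts: np.ndarray          # (n_bins,) edges per bin, sums to M
    bin_of_edge: np.ndarray     # (M,) bin index in [0, n_bins)


def build_sample_network(expr: ExpressionMatrix, sample_id: str,
                         scaffold: Scaffold) -> WeightedSampleNetwork:
    """Integrate one sample's expression with the scaffold.

    Nodes are scaffold genes with strictly positive expression in this
    sample; genes absent from the matrix count as zero-expression and are
    removed. Edge weight = |expr(a) - expr(b)|.
    """
    if sample_id not in expr.groups:
        raise KeyError(f"sample {sample_id!r} not in expression matrix")
    col = expr.values[sample_id]
    values = {g: v for g, v in col.items() if v > 0}
    nodes = sorted(g for g in scaffold.nodes if g in values)
    n_missing = sum(1 for g in scaffold.nodes if g not in expr.values.index)
    if len(nodes) < 2:
        raise ValueError(
            f"sample {sample_id!r}: fewer than 2 scaffold genes with positive expression"
        )
    index = {g: i for i, g in enumerate(nodes)}
    expression = np.array([values[g] for g in nodes], dtype=float)
    edge_list = [
        (index[a], index[b])
        for a, b in scaffold.edges()
        if a in index and b in index
    ]
    edges = np.array(edge_list, dtype=np.int64).reshape(-1, 2)
    weights = np.abs(expression[edges[:, 0]] - expression[edges[:, 1]])
    logger.info(
        "build_sample_network %s: %d/%d nodes retained (%d absent from matrix), %d edges",
        sample_id, len(nodes), scaffold.n_nodes, n_missing, len(weights),
    )
    return WeightedSampleNetwork(sample_id, nodes, edges, weights, expression)


def bin_weights(net: WeightedSampleNetwork) -> WeightBinning:
    """Discretize edge weights into floor(sqrt(N)) equal-width bins.

    Bins span [min weight, max weight]; the right-most bin is closed. If all
    weights coincide the single occupied bin is the first.
    """
    if net.n_edges < 1:
        raise ValueError(f"sample {net.sample_id!r}: network has no edges")
    n_bins = max(1, math.floor(math.sqrt(net.n_nodes)))
    lo, hi = float(net.weights.min()), float(net.weights.max())
    if hi == lo:
        bin_edges = np.linspace(lo, lo + 1.0, n_bins + 1)
        bin_of_edge = np.zeros(net.n_edges, dtype=np.int64)
    else:
        bin_edges = np.linspace(lo, hi, n_bins + 1)
        # right-most bin closed: clip index n_bins (w == hi) down
        bin_of_edge = np.minimum(
            np.searchsorted(bin_edges, net.weights, side="right") - 1, n_bins - 1
        )
        bin_of_edge = np.maximum(bin_of_edge, 0)
    counts = np.bincount(bin_of_edge, minlength=n_bins)
    return WeightBinning(n_bins, bin_edges, counts, bin_of_edge)


def write_sample_network(net: WeightedSampleNetwork, binning: WeightBinning,
                         path: str | Path) -> None:
    """Write a per-sample weighted edge list TSV (gene_a, gene_b, weight, bin)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\tbin\n")
        for (i, j), w, q in zip(net.edges, net.weights, binning.bin_of_edge):
            a, b = sorted((net.nodes[i], net.nodes[j]))
            fh.write(f"{a}\t{b}\t{w:.6g}\t{q + 1}\n")
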