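"""Synthetic scaffolds, age-structured cohorts, and condition gene sets
with planted, machine-checkable ground truth.

The generator emulates the study design this pipeline targets: a
heavy-tailed PPI scaffold (preferential attachment), an age-ordered bulk
expression cohort on a VST-like positive scale with a few replicates per
age group, and condition gene sets with controlled network proximity.
Ageing is modelled as rising within-group expression noise, which flattens
each sample's edge-weight distribution and so raises ensemble network
entropy with age; planted local-entropy genes additionally have their
expression displaced far from their network neighbourhood in the old
groups, which uniformizes their incident edge weights (raising their local
entropy); planted DEGs get a mean shift in the oldest group.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import (ConditionGeneSet, ExpressionMatrix, Scaffold,
                 gene_set_from_iterable, write_expression, write_gene_set,
                 write_scaffold)
from .proximity import _multi_source_distances

logger = logging.getLogger("agenet")

# Baseline expression: a bimodal VST-like scale (bulk RNA-seq VST histograms
# are bimodal: a low/off mode and an expressed mode). Edge weights are then
# near 0 (same mode) or near the mode separation (cross mode), a strongly
# non-uniform distribution that added within-group noise visibly flattens.
BASELINE_LOW_MODE = 2.0
BASELINE_HIGH_MODE = 5.5
BASELINE_JITTER = 0.2
EXPRESSION_FLOOR = 0.01
# Expression gain of a planted gene's dedicated partner (satellite) in the
# old groups: the partner's interaction weight then dominates the planted
# gene's incident weight distribution, concentrating it (a large local-
# entropy shift at the planted gene only; the partner itself has a single
# edge and therefore local entropy identically 0). In young groups the
# partner tracks its host's baseline, so the partner edge carries only
# noise-level weight there.
ENTROPY_SHIFT_DISPLACEMENT = 48.0


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every synthetic dataset."""

    params: dict
    entropy_shift_genes: list[str] = dataclasses.field(default_factory=list)
    deg_genes: list[str] = dataclasses.field(default_factory=list)
    planted_cliques: list[list[str]] = dataclasses.field(default_factory=list)
    proximal_genes: list[str] = dataclasses.field(default_factory=list)
    distal_genes: list[str] = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def make_scaffold(n_genes: int, m: int = 3, seed: int = 0,
                  planted_cliques: int = 0, clique_size: int = 6,
                  n_satellites: int = 0) -> tuple[Scaffold, SyntheticTruth]:
    """Preferential-attachment scaffold, optionally with planted cliques
    and satellite partner nodes.

    The base graph is Barabasi-Albert with attachment ``m`` (connected,
    simple, m(n-m) edges). Planted cliques are laid onto disjoint random
    node sets; any direct edge between two distinct planted cliques is
    removed so each planted module is separately identifiable.
    ``n_satellites`` appends degree-1 partner nodes, each pendant on a
    distinct low-degree host; cohorts use them to plant local-entropy
    shifts at their hosts (see :func:`make_cohort`).
    """
    if not n_genes > m >= 1:
        raise ValueError("require n_genes > m >= 1")
    rng = np.random.default_rng(seed)
    base = nx.barabasi_albert_graph(n_genes, m, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(base, {i: _gene_name(i) for i in base.nodes})
    cliques: list[list[str]] = []
    if planted_cliques:
        if planted_cliques * clique_size > n_genes:
            raise ValueError("planted cliques exceed available nodes")
        chosen = rng.choice(n_genes, size=planted_cliques * clique_size,
                            replace=False)
        for c in range(planted_cliques):
            members = sorted(_gene_name(i)
                             for i in chosen[c * clique_size:(c + 1) * clique_size])
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    graph.add_edge(a, b)
            cliques.append(members)
        for i, ca in enumerate(cliques):
            for cb in cliques[i + 1:]:
                for a in ca:
                    for b in cb:
                        if graph.has_edge(a, b):
                            graph.remove_edge(a, b)
    if n_satellites:
        clique_nodes = {g for c in cliques for g in c}
        degrees = dict(graph.degree())
        candidates = sorted((g for g in graph.nodes if g not in clique_nodes),
                            key=lambda g: (degrees[g], g))
        if n_satellites > len(candidates):
            raise ValueError("more satellites requested than available hosts")
        hosts = sorted(rng.choice(candidates[:max(n_satellites * 2, n_satellites)],
                                  size=n_satellites, replace=False).tolist())
        for i, host in enumerate(hosts):
            graph.add_edge(_gene_name(n_genes + i), host)
    truth = SyntheticTruth(
        params={"n_genes": n_genes, "m": m, "seed": seed,
                "planted_cliques": planted_cliques, "clique_size": clique_size,
                "n_satellites": n_satellites},
        planted_cliques=cliques,
    )
    logger.info("make_scaffold: %d nodes, %d edges, %d planted cliques",
                graph.number_of_nodes(), graph.number_of_edges(), planted_cliques)
    return Scaffold(graph), truth


def expected_scaffold_edges(n_genes: int, m: int) -> int:
    """Closed-form edge count of the unplanted scaffold: m * (n - m)."""
    return m * (n_genes - m)


def make_cohort(scaffold: Scaffold,
                groups: Sequence[int] = (3, 9, 15, 21, 27),
                n_per_group: int = 4,
                noise_scale: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
                entropy_shift_genes: int = 0,
                deg_genes: int = 0,
                effect: float = 3.0,
                seed: int = 0,
                n_old_groups: int = 2) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Age-ordered expression cohort with planted entropy shifts and DEGs.

    Per-gene baselines are bimodal (low/expressed modes on a VST-like
    scale); each sample adds Gaussian noise with the group's
    ``noise_scale``. The last ``n_old_groups`` groups are "old": there,
    the dedicated degree-1 partner of each planted entropy-shift gene is
    strongly induced, so the partner edge dominates the planted gene's
    incident weight distribution (a large, neighbour-clean local-entropy
    shift; requires a scaffold built with ``n_satellites`` >=
    ``entropy_shift_genes``). Planted DEGs gain ``effect`` x
    noise_scale[-1] in the final group only. Values are floored at a small
    positive constant so all genes stay on the network.
    """
    if len(noise_scale) != len(groups):
        raise ValueError("noise_scale must match groups in length")
    if any(b < a for a, b in zip(noise_scale, noise_scale[1:])):
        raise ValueError("noise_scale must be non-decreasing")
    if any(s < 0 for s in noise_scale):
        raise ValueError("noise_scale must be non-negative")
    genes = sorted(scaffold.nodes)
    n = len(genes)
    if entropy_shift_genes + deg_genes > n:
        raise ValueError("planted gene counts exceed available genes")
    rng = np.random.default_rng(seed)
    mode = rng.integers(0, 2, size=n)
    baseline = (BASELINE_LOW_MODE
                + (BASELINE_HIGH_MODE - BASELINE_LOW_MODE) * mode
                + rng.normal(0.0, BASELINE_JITTER, size=n))

    # entropy shifts are planted through dedicated degree-1 partner nodes so
    # that no other gene's incident weights are perturbed
    index = {g: i for i, g in enumerate(genes)}
    sat_idx = np.array([], dtype=int)
    host_idx = np.array([], dtype=int)
    if entropy_shift_genes:
        satellites = sorted(g for g in genes if scaffold.graph.degree(g) == 1)
        if entropy_shift_genes > len(satellites):
            raise ValueError(
                f"{entropy_shift_genes} entropy-shift genes requested but the "
                f"scaffold has {len(satellites)} degree-1 partner nodes; "
                "build it with make_scaffold(..., n_satellites=...)"
            )
        chosen = sorted(rng.choice(satellites, size=entropy_shift_genes,
                                   replace=False).tolist())
        sat_idx = np.array([index[s] for s in chosen], dtype=int)
        hosts = [next(iter(scaffold.graph.neighbors(s))) for s in chosen]
        host_idx = np.array(sorted(index[h] for h in hosts), dtype=int)
        # partners track their host's baseline, so in young samples the
        # partner edge weight is pure noise
        baseline[sat_idx] = baseline[[index[h] for h in hosts]]
    excluded = set(sat_idx) | set(host_idx)
    if deg_genes:
        pool = np.array([i for i in rng.permutation(n) if i not in excluded])
        deg_idx = np.array(sorted(pool[:deg_genes]), dtype=int)
    else:
        deg_idx = np.array([], dtype=int)

    old_groups = set(groups[len(groups) - n_old_groups:])
    columns: dict[str, np.ndarray] = {}
    group_map: dict[str, int] = {}
    for g_label, sigma in zip(groups, noise_scale):
        for r in range(1, n_per_group + 1):
            sample = f"{g_label}m_r{r}"
            values = baseline + rng.normal(0.0, sigma, size=n) if sigma > 0 else baseline.copy()
            if g_label in old_groups and len(sat_idx):
                values[sat_idx] = (
                    baseline[sat_idx] + ENTROPY_SHIFT_DISPLACEMENT
                    + (rng.normal(0.0, sigma, size=len(sat_idx)) if sigma > 0 else 0.0)
                )
            if g_label == groups[-1] and len(deg_idx):
                values[deg_idx] += effect * noise_scale[-1]
            columns[sample] = np.maximum(values, EXPRESSION_FLOOR)
            group_map[sample] = int(g_label)
    values_df = pd.DataFrame(columns, index=genes)
    truth = SyntheticTruth(
        params={
            "groups": list(groups), "n_per_group": n_per_group,
            "noise_scale": list(noise_scale),
            "entropy_shift_genes": entropy_shift_genes, "deg_genes": deg_genes,
            "effect": effect, "seed": seed, "n_old_groups": n_old_groups,
        },
        entropy_shift_genes=[genes[i] for i in host_idx],
        deg_genes=[genes[i] for i in deg_idx],
    )
    return ExpressionMatrix(values_df, group_map), truth


def make_condition_sets(scaffold: Scaffold, reference: ConditionGeneSet,
                        proximal_size: int, distal_size: int,
                        seed: int = 0,
                        distal_min_distance: int = 4) -> tuple[ConditionGeneSet, ConditionGeneSet, SyntheticTruth]:
    """Condition gene sets with controlled proximity to a reference set.

    The proximal set is drawn from the reference's closed 1-hop
    neighbourhood; the distal set from nodes at hop distance >=
    ``distal_min_distance`` from every reference gene, falling back to the
    maximum-distance stratum when that one is empty (logged).
    """
    rng = np.random.default_rng(seed)
    dist = _multi_source_distances(scaffold, reference.genes)
    near = sorted(v for v, d in dist.items() if d <= 1)
    if proximal_size > len(near):
        raise ValueError(
            f"proximal stratum holds {len(near)} nodes, {proximal_size} requested")
    reachable = {v: d for v, d in dist.items()}
    far = sorted(v for v, d in reachable.items() if d >= distal_min_distance)
    if not far:
        dmax = max(reachable.values())
        far = sorted(v for v, d in reachable.items() if d == dmax)
        logger.info(
            "make_condition_sets: no nodes at distance >= %d; "
            "falling back to the distance-%d stratum", distal_min_distance, dmax)
    if distal_size > len(far):
        raise ValueError(
            f"distal stratum holds {len(far)} nodes, {distal_size} requested")
    prox = sorted(rng.choice(near, size=proximal_size, replace=False).tolist())
    dist_set = sorted(rng.choice(far, size=distal_size, replace=False).tolist())
    truth = SyntheticTruth(
        params={"proximal_size": proximal_size, "distal_size": distal_size,
                "seed": seed, "distal_min_distance": distal_min_distance,
                "reference": sorted(reference.genes)},
        proximal_genes=prox, distal_genes=dist_set,
    )
    return (gene_set_from_iterable(prox, scaffold, "proximal"),
            gene_set_from_iterable(dist_set, scaffold, "distal"),
            truth)


# ---------------------------------------------------------------------------
# Presets (used by `agenet simulate`)
# ---------------------------------------------------------------------------

def simulate_preset(preset: str, seed: int, out_dir: str | Path,
                    n_genes: int = 500) -> dict[str, Path]:
    """Write a complete synthetic dataset for one preset.

    ``ageing``: scaffold + cohort with planted entropy-shift and DEG genes;
    ``proximity``: scaffold + reference/proximal/distal gene sets;
    ``modules``: scaffold with planted cliques. Outputs are TSV/one-per-line
    text plus a truth JSON; identical parameters and seed give byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    root = np.random.SeedSequence(seed)
    s_scaffold, s_data = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2))
    if preset == "ageing":
        scaffold, _ = make_scaffold(n_genes, m=3, seed=s_scaffold,
                                    n_satellites=50)
        expr, truth = make_cohort(scaffold, entropy_shift_genes=50, deg_genes=50,
                                  seed=s_data)
        paths["scaffold"] = out / "scaffold.tsv"
        write_scaffold(scaffold, paths["scaffold"])
        paths["expression"] = out / "expression.tsv"
        paths["groups"] = out / "groups.tsv"
        write_expression(expr, paths["expression"], paths["groups"])
        paths["truth"] = out / "truth.json"
        truth.to_json(paths["truth"])
    elif preset == "proximity":
        scaffold, _ = make_scaffold(n_genes, m=3, seed=s_scaffold)
        rng = np.random.default_rng(s_data)
        nodes = sorted(scaffold.nodes)
        size = max(10, n_genes // 25)
        ref = gene_set_from_iterable(
            rng.choice(nodes, size=size, replace=False).tolist(),
            scaffold, "reference")
        # preferential-attachment scaffolds have small diameter: relax the
        # distal stratum until it can hold the requested set
        for min_dist in (4, 3, 2):
            try:
                prox, dist_set, truth = make_condition_sets(
                    scaffold, ref, size, size, seed=s_data,
                    distal_min_distance=min_dist)
                break
            except ValueError:
                if min_dist == 2:
                    raise
        paths["scaffold"] = out / "scaffold.tsv"
        write_scaffold(scaffold, paths["scaffold"])
        for name, gs in (("reference", ref), ("proximal", prox), ("distal", dist_set)):
            paths[name] = out / f"{name}.txt"
            write_gene_set(gs.genes, paths[name])
        paths["truth"] = out / "truth.json"
        truth.to_json(paths["truth"])
    elif preset == "modules":
        scaffold, truth = make_scaffold(n_genes, m=3, seed=s_scaffold,
                                        planted_cliques=2, clique_size=6)
        paths["scaffold"] = out / "scaffold.tsv"
        write_scaffold(scaffold, paths["scaffold"])
        paths["degs"] = out / "degs.txt"
        write_gene_set({g for c in truth.planted_cliques for g in c}, paths["degs"])
        paths["truth"] = out / "truth.json"
        truth.to_json(paths["truth"])
    else:
        raise ValueError(f"unknown preset {preset!r}")
    logger.info("simulate_preset %s: wrote %d files to %s", preset, len(paths), out)
    return paths
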