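"""Readers and writers for scaffolds, expression matrices and gene sets.

All tabular formats are plain TSV with a header (except edge lists and
one-gene-per-line sets, which are headerless). Gene identifiers are bare,
case-sensitive symbol strings; no aliasing or ID mapping is attempted.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger("agenet")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Scaffold:
    """An undirected PPI scaffold: simple graph, optional edge confidences.

    ``graph`` is a :class:`networkx.Graph`; edges may carry a ``score``
    attribute in [0, 1]. No self-loops, no duplicate edges.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str]]:
        return self.graph.edges()


@dataclasses.dataclass
class ExpressionMatrix:
    """A normalized gene-by-sample expression matrix with group labels.

    ``values`` is a genes x samples DataFrame of finite non-negative reals
    (e.g. VST-normalized RNA-seq); ``groups`` maps every sample ID to an
    ordinal group label such as age in months.
    """

    values: pd.DataFrame
    groups: dict[str, int]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        arr = self.values.to_numpy()
        if not pd.notna(arr).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_groups(self, groups: Iterable[int]) -> list[str]:
        wanted = set(groups)
        return [s for s in self.samples if self.groups[s] in wanted]


@dataclasses.dataclass(frozen=True)
class ConditionGeneSet:
    """A named condition gene list restricted to scaffold nodes."""

    name: str
    genes: frozenset[str]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


# ---------------------------------------------------------------------------
# Scaffold I/O
# ---------------------------------------------------------------------------

def read_scaffold(path: str | Path, confidence_cutoff: float = 0.9) -> Scaffold:
    """Read a 2- or 3-column edge list, dropping low-confidence edges.

    The third column, when present, is an interaction confidence score;
    edges with score < ``confidence_cutoff`` are dropped. Edges without a
    score pass any cutoff. Self-loops are discarded; duplicate edges in
    either orientation collapse to one (keeping the maximum score).
    """
    if not 0.0 <= confidence_cutoff <= 1.0:
        raise ValueError(f"confidence_cutoff must be in [0, 1], got {confidence_cutoff}")
    graph: nx.Graph = nx.Graph()
    n_read = n_dropped_score = n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            score = None
            if len(parts) == 3:
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: malformed score {parts[2]!r}"
                    ) from exc
            n_read += 1
            if a == b:
                n_self += 1
                continue
            if score is not None and score < confidence_cutoff:
                n_dropped_score += 1
                continue
            if graph.has_edge(a, b):
                prev = graph.edges[a, b].get("score")
                if score is not None and (prev is None or score > prev):
                    graph.edges[a, b]["score"] = score
            elif score is not None:
                graph.add_edge(a, b, score=score)
            else:
                graph.add_edge(a, b)
    if graph.number_of_edges() == 0:
        raise ValueError(
            f"{path}: no edges remain at confidence cutoff {confidence_cutoff}"
        )
    logger.info(
        "read_scaffold: %d lines, kept %d nodes and %d edges "
        "(dropped %d below cutoff %.2f, %d self-loops)",
        n_read, graph.number_of_nodes(), graph.number_of_edges(),
        n_dropped_score, confidence_cutoff, n_self,
    )
    return Scaffold(graph)


def write_scaffold(scaffold: Scaffold, path: str | Path) -> None:
    """Write a scaffold as a TSV edge list (score column if any edge has one)."""
    with open(path, "w") as fh:
        for a, b, data in sorted(scaffold.graph.edges(data=True)):
            score = data.get("score")
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Expression I/O
# ---------------------------------------------------------------------------

_SAMPLE_GROUP_RE = re.compile(r"(?:^|_)(\d+)m(?:_|$)")


def _parse_group_from_name(sample: str) -> int | None:
    """Parse an age-in-months group from sample names like ``S1_3m``."""
    m = _SAMPLE_GROUP_RE.search(sample)
    return int(m.group(1)) if m else None


def read_expression(
    path: str | Path, groups_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a gene-by-sample TSV/CSV (genes in the first column).

    Group labels come from a two-column sidecar table (sample TAB group) when
    given, otherwise from sample names of the form ``<anything>_<G>m``.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    values = pd.read_csv(path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene rows: {dups[:5]}")
    for col in values.columns:
        bad = pd.to_numeric(values[col], errors="coerce")
        if bad.isna().any():
            gene = values.index[bad.isna()][0]
            raise ValueError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        values[col] = bad

    groups: dict[str, int] = {}
    if groups_path is not None:
        sidecar = pd.read_csv(groups_path, sep="\t", header=None, comment="#",
                              names=["sample", "group"], dtype=str)
        # tolerate a header row
        if sidecar.iloc[0]["sample"].lower() in ("sample", "sample_id"):
            sidecar = sidecar.iloc[1:]
        groups = {str(r["sample"]): int(r["group"]) for _, r in sidecar.iterrows()}
    else:
        for s in values.columns:
            g = _parse_group_from_name(s)
            if g is not None:
                groups[s] = g
    missing = [s for s in values.columns if s not in groups]
    if missing:
        raise ValueError(f"{path}: no group label for samples {missing[:5]}")
    groups = {s: groups[s] for s in values.columns}
    logger.info(
        "read_expression: %d genes x %d samples, %d groups",
        values.shape[0], values.shape[1], len(set(groups.values())),
    )
    return ExpressionMatrix(values, groups)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     groups_path: str | Path | None = None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            fh.write("sample\tgroup\n")
            for s in expr.samples:
                fh.write(f"{s}\t{expr.groups[s]}\n")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gene_set(path: str | Path, scaffold: Scaffold,
                  name: str | None = None) -> ConditionGeneSet:
    """Read a one-symbol-per-line gene list and map it onto the scaffold.

    Off-network genes are dropped (count logged); downstream proximity
    analysis operates only on mapped genes.
    """
    raw: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                raw.add(sym)
    mapped = raw & scaffold.nodes
    if not mapped:
        raise ValueError(f"{path}: no genes map onto the scaffold")
    n_dropped = len(raw) - len(mapped)
    set_name = name if name is not None else Path(path).stem
    logger.info(
        "read_gene_set %s: %d of %d genes mapped (%d dropped)",
        set_name, len(mapped), len(raw), n_dropped,
    )
    return ConditionGeneSet(set_name, frozenset(mapped), n_dropped)


def gene_set_from_iterable(genes: Iterable[str], scaffold: Scaffold,
                           name: str = "set") -> ConditionGeneSet:
    """Build a ConditionGeneSet from in-memory symbols (same mapping rule)."""
    raw = set(genes)
    mapped = raw & scaffold.nodes
    if not mapped:
        raise ValueError(f"gene set {name!r}: no genes map onto the scaffold")
    return ConditionGeneSet(name, frozenset(mapped), len(raw) - len(mapped))


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
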