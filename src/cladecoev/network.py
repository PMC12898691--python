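"""Clade-annotated co-evolution networks.

Genes are nodes; an edge connects two genes whenever their profile
correlation reaches the threshold (default 0.7) in at least one clade, and
carries every qualifying clade with its correlation.  The edge list is the
canonical export format for downstream network tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .profiles import ProfileError
from .scores import CorrelationMatrix

__all__ = ["CoevolutionNetwork", "build_network", "export_edge_list", "read_edge_list"]


@dataclass
class CoevolutionNetwork:
    """Undirected co-evolution graph with per-clade edge annotations.

    ``graph`` is a networkx Graph whose edges carry a ``clades`` attribute:
    a dict mapping clade name -> correlation (only clades where the pair
    passes the threshold).
    """

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_clades(self, g1: str, g2: str) -> dict[str, float]:
        return dict(self.graph.edges[g1, g2]["clades"])

    def isolated_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.degree[n] == 0]


def build_network(
    per_clade: Mapping[str, CorrelationMatrix],
    t: float = 0.7,
    nodes: Sequence[str] | None = None,
) -> CoevolutionNetwork:
    """Union the per-clade correlation matrices into one annotated graph.

    An edge (g1, g2) exists iff r >= t in at least one clade; isolated
    query genes remain as nodes.  All matrices must draw their genes from a
    common superset (``nodes`` when given, else their union).
    """
    if not 0.0 < t < 1.0:
        raise ProfileError("network threshold must lie in (0, 1)")
    universe: list[str] = list(nodes) if nodes is not None else []
    seen = set(universe)
    for clade, corr in per_clade.items():
        for g in corr.genes:
            if nodes is not None and g not in seen:
                raise ProfileError(
                    f"gene {g!r} of clade {clade!r} not in the declared gene set"
                )
            if g not in seen:
                seen.add(g)
                universe.append(g)
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for clade in sorted(per_clade):
        corr = per_clade[clade]
        genes = corr.genes
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                r = float(corr.r[i, j])
                if r >= t:
                    g1, g2 = genes[i], genes[j]
                    if graph.has_edge(g1, g2):
                        graph.edges[g1, g2]["clades"][clade] = r
                    else:
                        graph.add_edge(g1, g2, clades={clade: r})
    return CoevolutionNetwork(graph, t)


def export_edge_list(net: CoevolutionNetwork, path: str | Path) -> pd.DataFrame:
    """Write one CSV row per (edge, clade) annotation.

    Genes within a row are ordered lexicographically and rows are sorted by
    (gene1, gene2, clade), so identical networks export identical bytes.
    """
    rows = []
    for g1, g2, data in net.graph.edges(data=True):
        a, b = sorted((g1, g2))
        for clade, r in data["clades"].items():
            rows.append((a, b, clade, r))
    rows.sort()
    df = pd.DataFrame(rows, columns=["gene1", "gene2", "clade", "correlation"])
    try:
        df.to_csv(path, index=False, float_format="%.10g")
    except OSError as exc:
        raise ProfileError(f"cannot write edge list to {path}: {exc}") from exc
    return df


def read_edge_list(path: str | Path, threshold: float = 0.7) -> CoevolutionNetwork:
    """Reconstruct a network from an exported edge-list CSV."""
    df = pd.read_csv(path)
    expected = ["gene1", "gene2", "clade", "correlation"]
    if list(df.columns) != expected:
        raise ProfileError(f"edge list {path} must have columns {expected}")
    graph = nx.Graph()
    for g1, g2, clade, r in df.itertuples(index=False):
        graph.add_nodes_from([g1, g2])
        if graph.has_edge(g1, g2):
            graph.edges[g1, g2]["clades"][clade] = float(r)
        else:
            graph.add_edge(g1, g2, clades={clade: float(r)})
    return CoevolutionNetwork(graph, threshold)


def export_graphml(net: CoevolutionNetwork, path: str | Path) -> None:
    """GraphML export for network tools; clade annotations are flattened to
    a semicolon-joined string attribute plus the maximum correlation."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for g1, g2, data in net.graph.edges(data=True):
        clades = data["clades"]
        g.add_edge(
            g1,
            g2,
            clades=";".join(sorted(clades)),
            max_correlation=max(clades.values()),
        )
    nx.write_graphml(g, path)
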