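"""Pathway-level result graphs and GraphML export.

The pathway graph has one node per tested pathway, carrying the test
statistic, p-value, FDR q-value and a significance flag; two pathways are
connected if at least one gene of one is connected to at least one gene of
the other in the binary interaction structure, with the number of such
distinct cross edges kept as an edge attribute.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import BinaryAdjacency
from .io import PathwaySet, ValidationError

__all__ = ["build_pathway_graph", "subgraph_significant", "export_graphml"]


def build_pathway_graph(
    results: pd.DataFrame,
    pathways: PathwaySet,
    adj: BinaryAdjacency,
    fdr_cut: float = 0.05,
) -> nx.Graph:
    """Pathway-level graph from a results table (columns pathway, size,
    stat, pvalue, qvalue)."""
    missing = [p for p in results["pathway"] if p not in pathways.names]
    if missing:
        raise ValidationError(
            f"result pathway(s) missing from membership: {missing[:5]}"
        )
    g = nx.Graph(fdr_cut=float(fdr_cut))
    for _, row in results.iterrows():
        attrs = {
            "size": int(row["size"]),
            "stat": float(row["stat"]),
            "pvalue": float(row["pvalue"]),
            "qvalue": float(row["qvalue"]),
            "significant": bool(row["qvalue"] <= fdr_cut),
        }
        if not all(math.isfinite(v) for v in
                   (attrs["stat"], attrs["pvalue"], attrs["qvalue"])):
            raise ValidationError(
                f"non-finite attribute for pathway {row['pathway']!r}"
            )
        g.add_node(row["pathway"], **attrs)

    names = [p for p in pathways.names if p in g]
    member_idx = {
        p: {adj.genes.get_loc(m) for m in pathways.members(p)} for p in names
    }
    u = adj.undirected_view()
    src, dst = np.nonzero(np.triu(u, 1))
    edges = list(zip(src.tolist(), dst.tolist()))
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            count = sum(
                1 for (x, y) in edges
                if (x in member_idx[a] and y in member_idx[b])
                or (y in member_idx[a] and x in member_idx[b])
            )
            if count > 0:
                g.add_edge(a, b, cross_edge_count=int(count))
    return g


def subgraph_significant(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on pathways flagged significant."""
    keep = [n for n, d in graph.nodes(data=True) if d.get("significant")]
    return graph.subgraph(keep).copy()


def export_graphml(graph: nx.Graph, path) -> None:
    """Write GraphML with typed node/edge attributes (floats stay floats)."""
    nx.write_graphml(graph, path)
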