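"""Connected components, community detection and block-diagonal ordering.

Oversized connected components (more genes than ``max_size``) are split by
running six community-detection algorithms on their undirected view;
candidates whose largest cluster still exceeds ``max_size`` are discarded and,
among the survivors, the partition losing the fewest edges is kept. Within-
cluster edges then form a block-diagonal adjacency under the cluster ordering,
which is what makes per-cluster estimation of the weighted adjacency exact.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc

from .io import EdgeList, ValidationError

logger = logging.getLogger("pynetgsa")

__all__ = [
    "BinaryAdjacency",
    "ClusterPartition",
    "ALGORITHM_PRIORITY",
    "build_binary_adjacency",
    "connected_components",
    "edge_loss",
    "cluster_component",
    "block_order",
    "cluster_network",
    "component_partition",
]

#: Fixed priority used to break ties on equal edge loss.
ALGORITHM_PRIORITY = (
    "walktrap",
    "leading_eigenvector",
    "fast_greedy",
    "label_propagation",
    "infomap",
    "louvain",
)


@dataclass
class BinaryAdjacency:
    """0/1 interaction structure over the canonical gene order.

    Zero diagonal; symmetric when undirected. Entry (i, j) = 1 for a directed
    edge i -> j; undirected edges set both (i, j) and (j, i).
    """

    matrix: np.ndarray
    genes: pd.Index
    directed: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("adjacency must be square")
        if m.shape[0] != len(self.genes):
            raise ValidationError("adjacency size does not match gene list")
        if np.any(np.diag(m) != 0):
            raise ValidationError("adjacency has nonzero diagonal")
        if not self.directed and not np.array_equal(m, m.T):
            raise ValidationError("undirected adjacency must be symmetric")
        self.matrix = m
        self.genes = pd.Index(self.genes)

    @property
    def p(self) -> int:
        return len(self.genes)

    def undirected_view(self) -> np.ndarray:
        """Symmetric 0/1 matrix ignoring edge direction."""
        m = self.matrix
        return ((m + m.T) > 0).astype(np.int8)

    def n_edges(self) -> int:
        """Number of distinct edges (unordered pairs with any connection)."""
        return int(np.triu(self.undirected_view(), 1).sum())

    def to_igraph(self, nodes: Sequence[int] | None = None) -> ig.Graph:
        u = self.undirected_view()
        if nodes is not None:
            u = u[np.ix_(nodes, nodes)]
        src, dst = np.nonzero(np.triu(u, 1))
        return ig.Graph(n=u.shape[0], edges=list(zip(src.tolist(), dst.tolist())))


def build_binary_adjacency(edges: EdgeList, universe: Iterable[str]) -> BinaryAdjacency:
    """0/1 adjacency in canonical gene order from a validated edge list."""
    genes = pd.Index(universe)
    pos = {g: i for i, g in enumerate(genes)}
    p = len(genes)
    m = np.zeros((p, p), dtype=np.int8)
    directed = edges.directed
    for src, dst, is_dir in zip(
        edges.records["src"], edges.records["dst"], edges.records["directed"]
    ):
        i, j = pos[src], pos[dst]
        m[i, j] = 1
        if not is_dir:
            m[j, i] = 1
    return BinaryAdjacency(m, genes, directed=directed)


def connected_components(adj: BinaryAdjacency) -> list[list[str]]:
    """Maximal (weakly) connected gene sets, ordered by decreasing size then
    lexicographically smallest member."""
    n, labels = _cc(sparse.csr_matrix(adj.matrix), directed=adj.directed,
                    connection="weak")
    comps: list[list[str]] = []
    for c in range(n):
        members = sorted(adj.genes[labels == c])
        comps.append(members)
    comps.sort(key=lambda mem: (-len(mem), mem[0]))
    return comps


def edge_loss(adj: BinaryAdjacency, cluster_of: Mapping[str, int]) -> int:
    """Count of distinct edges whose endpoints lie in different clusters."""
    missing = [g for g in adj.genes if g not in cluster_of]
    if missing:
        raise ValidationError(
            f"partition does not cover node(s): {', '.join(missing[:10])}"
        )
    labels = np.array([cluster_of[g] for g in adj.genes])
    u = np.triu(adj.undirected_view(), 1)
    src, dst = np.nonzero(u)
    return int(np.sum(labels[src] != labels[dst]))


def _run_candidate(g: ig.Graph, name: str, seed: int) -> list[int] | None:
    """Membership vector of one community-detection algorithm, or None on
    failure (treated as discarded)."""
    random.seed(seed)
    try:
        if name == "walktrap":
            return g.community_walktrap().as_clustering().membership
        if name == "leading_eigenvector":
            return g.community_leading_eigenvector().membership
        if name == "fast_greedy":
            return g.community_fastgreedy().as_clustering().membership
        if name == "label_propagation":
            return g.community_label_propagation().membership
        if name == "infomap":
            return g.community_infomap().membership
        if name == "louvain":
            return g.community_multilevel().membership
    except Exception as exc:  # pragma: no cover - algorithm-specific failures
        logger.warning("community algorithm %s failed: %s", name, exc)
        return None
    raise ValueError(f"unknown algorithm {name!r}")


def _component_edge_loss(u: np.ndarray, membership: Sequence[int]) -> int:
    labels = np.asarray(membership)
    src, dst = np.nonzero(np.triu(u, 1))
    return int(np.sum(labels[src] != labels[dst]))


def cluster_component(
    adj: BinaryAdjacency,
    component: Sequence[str],
    max_size: int = 1000,
    seed: int = 0,
    _round: int = 0,
) -> tuple[dict[str, int], str]:
    """Partition one connected component, honouring the size cap.

    Components of at most ``max_size`` genes stay whole (label ``"none"``).
    Larger ones are split on their undirected view by the six candidate
    algorithms; candidates whose largest cluster exceeds ``max_size`` are
    discarded and the surviving partition with minimum edge loss is chosen
    (ties broken by the fixed priority order). If every candidate is
    discarded, the minimum-loss candidate is re-clustered recursively on its
    oversized clusters (up to 3 rounds) and, failing that, the component is
    kept whole with a warning.

    Returns a gene -> local-cluster-id map and the chosen algorithm label.
    """
    members = list(component)
    if len(members) <= max_size:
        return {g: 0 for g in members}, "none"

    idx = [adj.genes.get_loc(g) for g in members]
    u = adj.undirected_view()[np.ix_(idx, idx)]
    g = ig.Graph(
        n=len(members),
        edges=list(zip(*(a.tolist() for a in np.nonzero(np.triu(u, 1))))),
    )

    candidates: dict[str, list[int]] = {}
    for name in ALGORITHM_PRIORITY:
        memb = _run_candidate(g, name, seed)
        if memb is not None:
            candidates[name] = memb
    losses = {n: _component_edge_loss(u, m) for n, m in candidates.items()}
    max_sizes = {
        n: int(np.bincount(m).max()) for n, m in candidates.items()
    }
    surviving = [n for n in ALGORITHM_PRIORITY
                 if n in candidates and max_sizes[n] <= max_size]

    if surviving:
        chosen = min(surviving, key=lambda n: (losses[n], ALGORITHM_PRIORITY.index(n)))
        memb = candidates[chosen]
        return {g_: int(c) for g_, c in zip(members, memb)}, chosen

    if not candidates or _round >= 3:
        logger.warning(
            "component of size %d could not be split below max_size=%d; "
            "keeping whole", len(members), max_size,
        )
        return {g_: 0 for g_ in members}, "none(fallback)"

    # All candidates oversize: recurse on the oversized clusters of the
    # minimum-loss candidate.
    base = min(candidates, key=lambda n: (losses[n], ALGORITHM_PRIORITY.index(n)))
    memb = np.asarray(candidates[base])
    out: dict[str, int] = {}
    next_id = 0
    for c in np.unique(memb):
        sub = [members[i] for i in np.nonzero(memb == c)[0]]
        if len(sub) <= max_size:
            for g_ in sub:
                out[g_] = next_id
            next_id += 1
        else:
            sub_map, _ = cluster_component(
                adj, sub, max_size=max_size, seed=seed, _round=_round + 1
            )
            for g_, local in sub_map.items():
                out[g_] = next_id + local
            next_id += max(sub_map.values()) + 1
    return out, f"{base}(recursive)"


@dataclass
class ClusterPartition:
    """Global cluster assignment with a block-diagonal gene ordering.

    ``cluster_of`` maps every gene to a global cluster id; ``component_of``
    to its connected component; ``order`` is the permutation of the canonical
    gene order under which within-cluster adjacency is block diagonal.
    """

    cluster_of: pd.Series
    component_of: pd.Series
    algorithm_chosen: dict[int, str]
    edge_loss_total: int
    order: pd.Index

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_of.nunique())

    def clusters(self) -> list[list[str]]:
        """Member lists per cluster, in block order."""
        by_id: dict[int, list[str]] = {}
        for g in self.order:
            by_id.setdefault(int(self.cluster_of[g]), []).append(g)
        return [by_id[c] for c in sorted(by_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.cluster_of.index,
             "cluster_id": self.cluster_of.values,
             "component_id": self.component_of.reindex(self.cluster_of.index).values}
        )


def block_order(
    adj: BinaryAdjacency,
    partitions: Sequence[tuple[dict[str, int], str]],
) -> ClusterPartition:
    """Assemble per-component partitions into a global block ordering.

    Raises on overlap or gap in coverage. Global cluster ids number clusters
    consecutively in component order; ``order`` lists genes cluster by
    cluster so that within-cluster adjacency is block diagonal.
    """
    cluster_of: dict[str, int] = {}
    component_of: dict[str, int] = {}
    algorithm_chosen: dict[int, str] = {}
    order: list[str] = []
    next_id = 0
    for comp_id, (mapping, label) in enumerate(partitions):
        algorithm_chosen[comp_id] = label
        local_ids = sorted(set(mapping.values()))
        remap = {c: next_id + k for k, c in enumerate(local_ids)}
        for g, c in mapping.items():
            if g in cluster_of:
                raise ValidationError(f"gene {g!r} assigned to two partitions")
            cluster_of[g] = remap[c]
            component_of[g] = comp_id
        for c in local_ids:
            order.extend(sorted(g for g, cc in mapping.items() if remap[cc] == remap[c]))
        next_id += len(local_ids)
    missing = [g for g in adj.genes if g not in cluster_of]
    if missing:
        raise ValidationError(
            f"partitions do not cover gene(s): {', '.join(missing[:10])}"
        )
    extra = set(cluster_of) - set(adj.genes)
    if extra:
        raise ValidationError(
            f"partitions cover unknown gene(s): {', '.join(sorted(extra)[:10])}"
        )
    loss = edge_loss(adj, cluster_of)
    return ClusterPartition(
        cluster_of=pd.Series(cluster_of).reindex(adj.genes),
        component_of=pd.Series(component_of).reindex(adj.genes),
        algorithm_chosen=algorithm_chosen,
        edge_loss_total=loss,
        order=pd.Index(order),
    )


def cluster_network(
    adj: BinaryAdjacency, max_size: int = 1000, seed: int = 0
) -> ClusterPartition:
    """Full clustering pass: components, per-component splitting, block order."""
    comps = connected_components(adj)
    parts = [cluster_component(adj, c, max_size=max_size, seed=seed) for c in comps]
    part = block_order(adj, parts)
    logger.info(
        "clustering: %d component(s) -> %d cluster(s), edge loss %d "
        "(algorithms: %s)",
        len(comps), part.n_clusters, part.edge_loss_total,
        ", ".join(sorted(set(part.algorithm_chosen.values()))),
    )
    return part


def component_partition(adj: BinaryAdjacency) -> ClusterPartition:
    """No-clustering partition: one cluster per connected component."""
    comps = connected_components(adj)
    parts = [({g: 0 for g in c}, "none") for c in comps]
    return block_order(adj, parts)
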