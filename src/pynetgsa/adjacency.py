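"""Condition-specific weighted adjacency estimation under known-edge
constraints, and the influence matrices Lambda_k = (I - A_k)^-1.

Undirected networks: each gene is regressed on the other genes of its
cluster with an L1 penalty whose per-coefficient weight is 0 for known-edge
partners and ``nonedge_weight`` (default infinite, i.e. excluded) for
non-edge partners; the two regression coefficients of a pair are combined
into a signed partial-correlation-scaled weight. Directed (acyclic)
networks: each gene is regressed by OLS on its parents.

Estimation is performed cluster by cluster and reassembled into a
block-diagonal matrix, which is exact because clusters share no allowed
edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import BinaryAdjacency, ClusterPartition, component_partition
from .io import ExpressionDataset, ValidationError

logger = logging.getLogger("pynetgsa")

__all__ = [
    "WeightedAdjacencySet",
    "InfluenceSet",
    "estimate_undirected",
    "estimate_directed",
    "assemble_adjacency",
    "influence_matrix",
    "estimate_adjacency",
    "influence_set",
]

_COND_LIMIT = 1e12


@dataclass
class WeightedAdjacencySet:
    """Per-condition weighted adjacency matrices A_k on the canonical gene
    order. Diagonals are zero; cross-cluster entries are exactly zero when a
    partition was active; I - A_k must be invertible."""

    matrices: dict[str, np.ndarray]
    genes: pd.Index
    directed: bool = False
    lambda_used: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.matrices)

    @property
    def p(self) -> int:
        return len(self.genes)

    def __getitem__(self, condition: str) -> np.ndarray:
        return self.matrices[condition]


@dataclass
class InfluenceSet:
    """Per-condition influence matrices Lambda_k with
    (I - A_k) Lambda_k = I to numerical tolerance."""

    matrices: dict[str, np.ndarray]
    genes: pd.Index

    @property
    def conditions(self) -> list[str]:
        return list(self.matrices)

    def __getitem__(self, condition: str) -> np.ndarray:
        return self.matrices[condition]


# ---------------------------------------------------------------------------
# Core solvers
# ---------------------------------------------------------------------------

def _center_scale(X: np.ndarray, genes: Sequence[str], scale: bool) -> np.ndarray:
    """Center (and optionally scale to unit variance) each gene's row."""
    X = np.asarray(X, dtype=float)
    out = X - X.mean(axis=1, keepdims=True)
    if scale:
        sd = out.std(axis=1, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            raise ValidationError(
                f"constant gene(s) within condition: "
                f"{', '.join(str(genes[i]) for i in zero[:5])}"
            )
        out = out / sd[:, None]
    return out


def _weighted_lasso(
    Z: np.ndarray,
    y: np.ndarray,
    lam: float,
    weights: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """Coordinate descent for (1/2n)||y - Zb||^2 + lam * sum_j w_j |b_j|.

    Coefficients with w_j = 0 are unpenalized. Deterministic cyclic order.
    """
    n, m = Z.shape
    b = np.zeros(m)
    col_sq = (Z ** 2).sum(axis=0) / n
    r = y.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(m):
            if col_sq[j] == 0:
                continue
            rho = Z[:, j] @ r / n + col_sq[j] * b[j]
            thr = lam * weights[j]
            if rho > thr:
                new = (rho - thr) / col_sq[j]
            elif rho < -thr:
                new = (rho + thr) / col_sq[j]
            else:
                new = 0.0
            delta = new - b[j]
            if delta != 0.0:
                r -= delta * Z[:, j]
                b[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return b


def _auto_lambda(p: int, n: int, c: float) -> float:
    return c * math.sqrt(math.log(max(p, 2)) / n)


def estimate_undirected(
    X: np.ndarray,
    known: np.ndarray,
    genes: Sequence[str],
    penalty: float | str = "auto",
    nonedge_weight: float = np.inf,
    penalty_scale: float = 1.0,
    scale: bool = True,
) -> np.ndarray:
    """Estimate one cluster block of A_k for an undirected network.

    ``X`` is the gene-by-sample matrix of one condition restricted to the
    cluster; ``known`` the matching 0/1 symmetric structure. Known-edge
    partners enter each per-node regression unpenalized; non-edge partners
    are excluded when ``nonedge_weight`` is infinite (the default,
    external-knowledge mode) or penalized with weight ``nonedge_weight``
    otherwise (discovery mode). The pairwise regression coefficients are
    symmetrized by the signed geometric mean, which equals the partial
    correlation when the neighborhood regressions are exact.
    """
    X = np.asarray(X, float)
    p, n = X.shape
    if n < 3:
        raise ValidationError("need at least 3 samples per condition")
    if isinstance(penalty, str):
        if penalty != "auto":
            raise ValueError(f"penalty must be a number or 'auto', got {penalty!r}")
        lam = _auto_lambda(p, n, penalty_scale)
    else:
        lam = float(penalty)
        if lam < 0:
            raise ValidationError("penalty must be nonnegative")
    Xc = _center_scale(X, genes, scale)
    known = np.asarray(known)
    discovery = np.isfinite(nonedge_weight)

    B = np.zeros((p, p))
    for i in range(p):
        partners = np.nonzero(known[i])[0]
        w = np.zeros(len(partners))
        if discovery:
            others = np.array(
                [j for j in range(p) if j != i and known[i, j] == 0], dtype=int
            )
            partners = np.concatenate([partners, others])
            w = np.concatenate([w, np.full(len(others), float(nonedge_weight))])
        if partners.size == 0:
            continue
        Z = Xc[partners].T
        y = Xc[i]
        if not discovery:
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        else:
            coef = _weighted_lasso(Z, y, lam, w)
        B[i, partners] = coef

    prod = B * B.T
    W = np.where(prod > 0, np.sign(B) * np.sqrt(np.abs(prod)), 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def estimate_directed(
    X: np.ndarray,
    known: np.ndarray,
    genes: Sequence[str],
) -> np.ndarray:
    """Estimate one cluster block of A_k for a known directed acyclic
    structure: OLS of each gene on its parents; A[child, parent] holds the
    coefficient. Genes are centered but not scaled so coefficients stay on
    the data scale."""
    X = np.asarray(X, float)
    p, _ = X.shape
    known = np.asarray(known)
    g = nx.DiGraph(
        [(int(i), int(j)) for i, j in zip(*np.nonzero(known))]
    )
    g.add_nodes_from(range(p))
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        names = " -> ".join(str(genes[u]) for u, _ in cycle)
        raise ValidationError(f"directed structure contains a cycle: {names}")
    Xc = _center_scale(X, genes, scale=False)
    A = np.zeros((p, p))
    for child in range(p):
        parents = np.nonzero(known[:, child])[0]
        if parents.size == 0:
            continue
        coef, *_ = np.linalg.lstsq(Xc[parents].T, Xc[child], rcond=None)
        A[child, parents] = coef
    return A


# ---------------------------------------------------------------------------
# Assembly and inversion
# ---------------------------------------------------------------------------

def assemble_adjacency(
    blocks: Mapping[str, Mapping[int, np.ndarray]],
    partition: ClusterPartition,
    genes: pd.Index,
    directed: bool = False,
    lambda_used: dict[str, dict[int, float]] | None = None,
) -> WeightedAdjacencySet:
    """Place per-cluster blocks into global A_k matrices with cross-cluster
    entries exactly zero."""
    pos = {g: i for i, g in enumerate(genes)}
    clusters = partition.clusters()
    out: dict[str, np.ndarray] = {}
    for cond, cond_blocks in blocks.items():
        A = np.zeros((len(genes), len(genes)))
        for cid, members in enumerate(clusters):
            block = np.asarray(cond_blocks[cid])
            if block.shape != (len(members), len(members)):
                raise ValidationError(
                    f"block {cid} for condition {cond!r} has shape "
                    f"{block.shape}, expected ({len(members)}, {len(members)})"
                )
            idx = [pos[g] for g in members]
            A[np.ix_(idx, idx)] = block
        out[cond] = A
    return WeightedAdjacencySet(
        out, genes, directed=directed, lambda_used=lambda_used or {}
    )


def influence_matrix(A: np.ndarray) -> np.ndarray:
    """Lambda = (I - A)^-1, with a conditioning check."""
    A = np.asarray(A, float)
    M = np.eye(A.shape[0]) - A
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ValidationError(
            f"I - A is numerically singular (condition estimate {cond:.2e}); "
            "use a stronger penalty"
        )
    return np.linalg.solve(M, np.eye(A.shape[0]))


def influence_set(
    adjset: WeightedAdjacencySet,
    partition: ClusterPartition | None = None,
) -> InfluenceSet:
    """Influence matrices per condition, computed blockwise when a partition
    is given (exact: A_k is block diagonal under the cluster ordering)."""
    out: dict[str, np.ndarray] = {}
    for cond, A in adjset.matrices.items():
        if partition is None:
            out[cond] = influence_matrix(A)
        else:
            pos = {g: i for i, g in enumerate(adjset.genes)}
            L = np.zeros_like(A)
            for members in partition.clusters():
                idx = [pos[g] for g in members]
                L[np.ix_(idx, idx)] = influence_matrix(A[np.ix_(idx, idx)])
            out[cond] = L
    return InfluenceSet(out, adjset.genes)


# ---------------------------------------------------------------------------
# High-level driver
# ---------------------------------------------------------------------------

def estimate_adjacency(
    data: ExpressionDataset,
    known: BinaryAdjacency,
    partition: ClusterPartition | None = None,
    penalty: float | str = "auto",
    nonedge_weight: float = np.inf,
    penalty_scale: float = 1.0,
    scale: bool = True,
) -> WeightedAdjacencySet:
    """Estimate A_k for every condition, cluster by cluster.

    With ``partition=None`` the network is still processed per connected
    component (estimation never couples disconnected genes), which makes the
    unclustered path identical to clustering whenever no component exceeds
    the size cap.
    """
    if partition is None:
        partition = component_partition(known)
    genes = data.genes
    if not genes.equals(known.genes):
        raise ValidationError("expression and adjacency gene orders differ")
    pos = {g: i for i, g in enumerate(genes)}
    clusters = partition.clusters()
    blocks: dict[str, dict[int, np.ndarray]] = {}
    lambda_used: dict[str, dict[int, float]] = {}
    for cond in data.conditions:
        Xc = data.matrix(cond)
        cond_blocks: dict[int, np.ndarray] = {}
        cond_lams: dict[int, float] = {}
        for cid, members in enumerate(clusters):
            idx = [pos[g] for g in members]
            sub_known = known.matrix[np.ix_(idx, idx)]
            sub_X = Xc[idx]
            lam = (
                _auto_lambda(len(idx), sub_X.shape[1], penalty_scale)
                if isinstance(penalty, str) else float(penalty)
            )
            cond_lams[cid] = lam
            if known.directed:
                cond_blocks[cid] = estimate_directed(
                    sub_X, sub_known, [genes[i] for i in idx]
                )
            else:
                cond_blocks[cid] = estimate_undirected(
                    sub_X, sub_known, [genes[i] for i in idx],
                    penalty=penalty, nonedge_weight=nonedge_weight,
                    penalty_scale=penalty_scale, scale=scale,
                )
        blocks[cond] = cond_blocks
        lambda_used[cond] = cond_lams
    return assemble_adjacency(
        blocks, partition, genes, directed=known.directed, lambda_used=lambda_used
    )
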