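"""Synthetic networks and expression data under the latent-variable model,
and the dysregulation / power / type-I-error study design.

The generator emulates a two-condition study: a random interaction network
with a few connected components, condition-specific weighted adjacencies
with spectral radius capped below 1 (so the influence matrix exists), and
samples drawn from y = Lambda beta + Lambda gamma + eps. For power studies,
every gene is first standardized across all samples, a subset of genes is
selected for dysregulation, and a mean signal mu (0.2 / 0.3 / 0.4 in the
reference design) is added to those genes in the target condition only.
Pathways are then binned by their number of dysregulated members
(None, (0,5], (5,10], >10): the None group estimates type-I error and the
others statistical power at the FDR cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .adjacency import WeightedAdjacencySet, influence_matrix
from .clustering import BinaryAdjacency
from .inference import run_netgsa
from .io import ExpressionDataset, PathwaySet, ValidationError

logger = logging.getLogger("pynetgsa")

__all__ = [
    "SimulationDesign",
    "GROUPS",
    "generate_network",
    "generate_pathways",
    "generate_expression",
    "standardize_and_dysregulate",
    "select_dysregulated",
    "dysregulation_group",
    "run_power_study",
]

GROUPS = ("None", "(0,5]", "(5,10]", ">10")
FRAMEWORKS = ("uniform-random", "betweenness-ranked", "neighborhood-seeded")


@dataclass
class SimulationDesign:
    """Study conditions for a desk-scale power / type-I simulation.

    Defaults describe the scaled-down two-condition design: 150 genes in
    3 network components, 15 pathways, 40 samples per condition, mean
    signals 0.2 / 0.3 / 0.4 added to dysregulated genes of the second
    condition, FDR cut-off 0.05.
    """

    p: int = 150
    n_k: tuple[int, int] = (40, 40)
    n_components: int = 3
    edge_density: float = 0.05
    weight_range: tuple[float, float] = (0.2, 0.6)
    spectral_cap: float = 0.9
    perturb: float = 0.0
    n_pathways: int = 15
    pathway_size_range: tuple[int, int] = (5, 30)
    mu: tuple[float, ...] = (0.2, 0.3, 0.4)
    framework: str = "uniform-random"
    fraction: float = 0.3
    sigma2_g: float = 0.3
    sigma2_e: float = 0.7
    replicates: int = 20
    seed: int = 0
    fdr: float = 0.05
    estimator: str = "rehe"
    cluster: bool = True
    max_size: int = 1000
    conditions: tuple[str, str] = ("cond1", "cond2")

    def __post_init__(self) -> None:
        if isinstance(self.mu, (int, float)):
            self.mu = (float(self.mu),)
        if any(m < 0 for m in self.mu):
            raise ValidationError("mean signal mu must be nonnegative")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.pathway_size_range[0] < 1:
            raise ValidationError("pathway sizes must be >= 1")
        if not 0 <= self.edge_density <= 1:
            raise ValidationError("edge density must be in [0, 1]")
        if self.p < self.n_components:
            raise ValidationError("p must be at least n_components")
        if self.framework not in FRAMEWORKS:
            raise ValidationError(
                f"framework must be one of {FRAMEWORKS}, got {self.framework!r}"
            )


def _gene_names(p: int) -> pd.Index:
    width = len(str(p))
    return pd.Index([f"g{i:0{width}d}" for i in range(1, p + 1)])


def generate_network(
    design: SimulationDesign, seed: int | None = None
) -> tuple[BinaryAdjacency, WeightedAdjacencySet]:
    """Random undirected network with the design's component structure and
    per-condition weighted adjacencies.

    Component memberships split the genes evenly; edges within a component
    are Erdos-Renyi with the design density. Weights are drawn uniformly on
    +/-[w_lo, w_hi], shared between conditions (condition 2 optionally
    perturbed by ``design.perturb`` Gaussian noise on the same support), and
    each A_k is rescaled so its spectral radius is at most
    ``design.spectral_cap`` (guaranteeing I - A_k is invertible).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    p = design.p
    genes = _gene_names(p)
    sizes = [p // design.n_components] * design.n_components
    for i in range(p - sum(sizes)):
        sizes[i] += 1
    m = np.zeros((p, p), dtype=np.int8)
    start = 0
    for size in sizes:
        block = rng.random((size, size)) < design.edge_density
        block = np.triu(block, 1)
        sub = block + block.T
        m[start:start + size, start:start + size] = sub
        start += size
    adj = BinaryAdjacency(m, genes, directed=False)

    lo, hi = design.weight_range
    src, dst = np.nonzero(np.triu(m, 1))
    base = rng.uniform(lo, hi, size=len(src)) * rng.choice([-1.0, 1.0], size=len(src))
    matrices: dict[str, np.ndarray] = {}
    for idx, cond in enumerate(design.conditions):
        w = base.copy()
        if idx > 0 and design.perturb > 0:
            w = w + rng.normal(0.0, design.perturb, size=len(w))
        A = np.zeros((p, p))
        A[src, dst] = w
        A[dst, src] = w
        if len(src):
            rho = float(np.max(np.abs(np.linalg.eigvalsh(A))))
            if rho > design.spectral_cap:
                A *= design.spectral_cap / rho
        matrices[cond] = A
    return adj, WeightedAdjacencySet(matrices, genes, directed=False)


def generate_pathways(
    design: SimulationDesign, seed: int | None = None
) -> PathwaySet:
    """Random pathway membership: sizes uniform in the design range, members
    sampled without replacement from the gene universe."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = _gene_names(design.p)
    lo, hi = design.pathway_size_range
    hi = min(hi, design.p)
    memb = np.zeros((design.n_pathways, design.p), dtype=np.int8)
    for i in range(design.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(design.p, size=size, replace=False)
        memb[i, members] = 1
    names = [f"pw{i + 1:02d}" for i in range(design.n_pathways)]
    return PathwaySet(pd.DataFrame(memb, index=names, columns=genes))


def generate_expression(
    adjset: WeightedAdjacencySet,
    beta: dict[str, np.ndarray] | None,
    sigma2_g: float,
    sigma2_e: float,
    n_k: dict[str, int],
    seed: int = 0,
) -> ExpressionDataset:
    """Draw samples from y_i = Lambda_k (beta_k + gamma_i) + eps_i."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValidationError("variances must be nonnegative")
    rng = np.random.default_rng(seed)
    p = adjset.p
    cols: list[str] = []
    cond_of: list[str] = []
    blocks: list[np.ndarray] = []
    for cond in adjset.conditions:
        n = n_k[cond]
        L = influence_matrix(adjset[cond])
        bk = np.zeros(p) if beta is None else np.asarray(beta[cond], float)
        gamma = rng.normal(0.0, np.sqrt(sigma2_g), size=(p, n))
        eps = rng.normal(0.0, np.sqrt(sigma2_e), size=(p, n))
        Y = (L @ (bk[:, None] + gamma)) + eps
        blocks.append(Y)
        cols.extend(f"{cond}_s{i + 1:04d}" for i in range(n))
        cond_of.extend([cond] * n)
    values = pd.DataFrame(np.hstack(blocks), index=adjset.genes, columns=cols)
    return ExpressionDataset(values, pd.Series(cond_of, index=cols))


def standardize_and_dysregulate(
    data: ExpressionDataset,
    dysregulated: Iterable[str],
    mu: float,
    target_condition: str,
) -> ExpressionDataset:
    """Center and scale each gene to zero mean and unit variance across all
    samples, then add the mean signal ``mu`` to the dysregulated genes in
    the target condition only."""
    if mu < 0:
        raise ValidationError("mean signal mu must be nonnegative")
    dys = set(dysregulated)
    unknown = dys - set(data.genes)
    if unknown:
        raise ValidationError(
            f"dysregulated gene(s) outside the universe: {sorted(unknown)[:5]}"
        )
    vals = data.values.copy()
    centered = vals.sub(vals.mean(axis=1), axis=0)
    sd = vals.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValidationError("cannot standardize constant gene(s)")
    std = centered.div(sd, axis=0)
    if mu > 0 and dys:
        target_cols = data.condition_of.index[data.condition_of == target_condition]
        std.loc[sorted(dys), target_cols] += mu
    return ExpressionDataset(std, data.condition_of)


def select_dysregulated(
    adj: BinaryAdjacency,
    framework: str,
    fraction: float,
    seed: int = 0,
) -> set[str]:
    """Choose the dysregulated gene set under one of three seedable rules.

    uniform-random samples genes uniformly; betweenness-ranked takes the
    top fraction by betweenness centrality (deterministic ties broken by
    gene order); neighborhood-seeded grows sets outward from random seed
    genes along network edges, concentrating the signal topologically.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if framework not in FRAMEWORKS:
        raise ValidationError(
            f"framework must be one of {FRAMEWORKS}, got {framework!r}"
        )
    rng = np.random.default_rng(seed)
    p = adj.p
    k = max(1, int(round(fraction * p)))
    genes = list(adj.genes)
    if framework == "uniform-random":
        idx = rng.choice(p, size=k, replace=False)
        return {genes[i] for i in idx}
    if framework == "betweenness-ranked":
        g = adj.to_igraph()
        btw = np.asarray(g.betweenness())
        order = np.lexsort((np.arange(p), -btw))  # stable: ties by gene order
        return {genes[i] for i in order[:k]}
    # neighborhood-seeded: BFS growth from random seeds
    u = adj.undirected_view()
    chosen: list[int] = []
    in_set = np.zeros(p, dtype=bool)
    frontier: list[int] = []
    while len(chosen) < k:
        if not frontier:
            remaining = np.nonzero(~in_set)[0]
            seed_gene = int(rng.choice(remaining))
            frontier = [seed_gene]
        node = frontier.pop(0)
        if in_set[node]:
            continue
        in_set[node] = True
        chosen.append(node)
        nbrs = [int(j) for j in np.nonzero(u[node])[0] if not in_set[j]]
        rng.shuffle(nbrs)
        frontier.extend(nbrs)
    return {genes[i] for i in chosen}


def dysregulation_group(count: int) -> str:
    """Bin a pathway by its number of dysregulated member genes."""
    if count == 0:
        return "None"
    if count <= 5:
        return "(0,5]"
    if count <= 10:
        return "(5,10]"
    return ">10"


def run_power_study(design: SimulationDesign) -> pd.DataFrame:
    """Replicate the dysregulation study and aggregate power / type-I error.

    For each replicate, a network, pathway set and null expression dataset
    are generated; the same base data is reused across all mean signals
    (common random numbers). Per (group, mu) cell the table reports the mean
    rejection indicator at the FDR cut-off, its standard error, and the
    number of pathway instances. The None group estimates type-I error, the
    others power.
    """
    records: list[dict] = []
    target = design.conditions[1]
    for r in range(design.replicates):
        rep_seed = int(np.random.SeedSequence([design.seed, r]).generate_state(1)[0]
                       % (2**31 - 1))
        rep = replace(design, seed=rep_seed)
        adj, adjset = generate_network(rep)
        pathways = generate_pathways(rep)
        base = generate_expression(
            adjset, None, design.sigma2_g, design.sigma2_e,
            {c: n for c, n in zip(design.conditions, design.n_k)},
            seed=rep_seed,
        )
        dys_all = select_dysregulated(
            adj, design.framework, design.fraction, seed=rep_seed
        )
        for mu in design.mu:
            dys = dys_all if mu > 0 else set()
            data = standardize_and_dysregulate(base, dys, mu, target)
            res = run_netgsa(
                data, pathways, edges=adj,
                estimator=design.estimator, cluster=design.cluster,
                max_size=design.max_size, fdr=design.fdr, seed=rep_seed,
                conditions=design.conditions,
            )
            counts = {
                name: len(set(pathways.members(name)) & dys)
                for name in pathways.names
            }
            for _, row in res.iterrows():
                records.append(
                    {
                        "replicate": r,
                        "mu": mu,
                        "pathway": row["pathway"],
                        "group": dysregulation_group(counts[row["pathway"]]),
                        "rejected": bool(row["qvalue"] <= design.fdr),
                    }
                )
    raw = pd.DataFrame(records)
    rows = []
    for (group, mu), sub in raw.groupby(["group", "mu"], sort=False):
        x = sub["rejected"].to_numpy(float)
        se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        rows.append(
            {
                "group": group, "mu": mu, "power": float(x.mean()),
                "se": se, "n_pathway_instances": int(len(x)),
            }
        )
    table = pd.DataFrame(rows)
    order = {g: i for i, g in enumerate(GROUPS)}
    table = table.sort_values(
        ["group", "mu"], key=lambda s: s.map(order) if s.name == "group" else s
    ).reset_index(drop=True)
    return table
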