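"""Latent-variable mixed-model inference for topology-based pathway
enrichment.

Model per condition k (gene vector y_i of a sample in condition k):

    y_i = Lambda_k beta_k + Lambda_k gamma_i + eps_i,
    gamma_i ~ N(0, sigma2_g I),  eps_i ~ N(0, sigma2_e I),

so Cov(y_i) = sigma2_g Lambda_k Lambda_k' + sigma2_e I. The influence matrix
Lambda_k = (I - A_k)^-1 propagates each gene's baseline effect beta through
the condition-specific network. The variance components (sigma2_g, sigma2_e)
are shared across conditions and estimated either by REHE (restricted
Haseman-Elston: nonnegative least squares of the sample covariances on the
two covariance structures; the default) or by REML (Newton iterations on the
restricted Gaussian log-likelihood with analytic gradient and Hessian).

A pathway with indicator vector b is tested between two conditions with the
contrast l = (-b'Lambda_1, b'Lambda_2) on the stacked means, i.e.

    T = l beta_hat / sqrt(l C l'),   C = blockdiag(Cov(beta_hat_k)),

with Cov(beta_hat_k) = Lambda_k^-1 (sigma2_g Lambda_k Lambda_k' +
sigma2_e I) Lambda_k^-T / n_k, referred to a t distribution on
n_1 + n_2 - 2 degrees of freedom (a normal reference is available for
large samples). P-values across pathways are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .adjacency import (
    InfluenceSet,
    WeightedAdjacencySet,
    estimate_adjacency,
    influence_matrix,
    influence_set,
)
from .clustering import (
    BinaryAdjacency,
    ClusterPartition,
    build_binary_adjacency,
    cluster_network,
    component_partition,
)
from .io import EdgeList, ExpressionDataset, PathwaySet, ValidationError, harmonize

logger = logging.getLogger("pynetgsa")

__all__ = [
    "VarianceComponents",
    "ModelFit",
    "PathwayTestResult",
    "fit_means",
    "rehe_estimate",
    "reml_estimate",
    "restricted_loglik",
    "fit_model",
    "pathway_test",
    "bh_adjust",
    "run_netgsa",
]


@dataclass
class VarianceComponents:
    """Nonnegative variance components of the latent-variable model."""

    sigma2_g: float
    sigma2_e: float
    method: str

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValidationError("variance components must be nonnegative")


@dataclass
class ModelFit:
    """Per-condition mean estimates and shared variance components."""

    beta_hat: dict[str, np.ndarray]
    var_components: VarianceComponents
    cov_beta: dict[str, np.ndarray]
    n_k: dict[str, int]
    genes: pd.Index


@dataclass
class PathwayTestResult:
    pathway: str
    size: int
    stat: float
    df: float
    pvalue: float
    qvalue: float | None = None


# ---------------------------------------------------------------------------
# Mean and variance-component estimation
# ---------------------------------------------------------------------------

def fit_means(data: ExpressionDataset, infl: InfluenceSet) -> dict[str, np.ndarray]:
    """beta_hat_k = Lambda_k^-1 ybar_k, the GLS solution under the common
    within-condition design (ybar_k = per-gene sample mean in condition k)."""
    out: dict[str, np.ndarray] = {}
    for cond in data.conditions:
        X = data.matrix(cond)
        if X.shape[1] < 2:
            raise ValidationError(f"condition {cond!r} has fewer than 2 samples")
        ybar = X.mean(axis=1)
        L = infl[cond]
        out[cond] = np.linalg.solve(L, ybar)
    return out


def _structures(
    S: Mapping[str, np.ndarray],
    infl_or_G: Mapping[str, np.ndarray],
    n_k: Mapping[str, int],
    already_gram: bool = False,
) -> tuple[list[np.ndarray], list[np.ndarray], list[float]]:
    conds = list(S)
    Gs, Ss, ws = [], [], []
    for c in conds:
        L = np.asarray(infl_or_G[c], float)
        G = L if already_gram else L @ L.T
        Gs.append(G)
        Ss.append(np.asarray(S[c], float))
        ws.append(float(n_k[c] - 1))
    return Ss, Gs, ws


def _check_identifiable(Gs: Sequence[np.ndarray]) -> None:
    for G in Gs:
        p = G.shape[0]
        resid = G - (np.trace(G) / p) * np.eye(p)
        if np.linalg.norm(resid) > 1e-8 * max(1.0, np.linalg.norm(G)):
            return
    raise ValidationError(
        "variance components not identifiable: every Lambda Lambda' is "
        "proportional to the identity (network has no effective structure), "
        "only sigma2_g + sigma2_e is identified"
    )


def rehe_estimate(
    S: Mapping[str, np.ndarray],
    infl: InfluenceSet | Mapping[str, np.ndarray],
    n_k: Mapping[str, int],
) -> VarianceComponents:
    """Restricted Haseman-Elston estimate of (sigma2_g, sigma2_e).

    Minimizes sum_k (n_k - 1) ||S_k - a G_k - b I||_F^2 over the nonnegative
    quadrant, G_k = Lambda_k Lambda_k'. The 2x2 normal equations are solved
    in closed form; if the unconstrained minimizer leaves the quadrant, both
    single-component boundary problems (one component clamped at zero, the
    other re-minimized) are evaluated and the feasible minimizer returned.
    """
    matrices = infl.matrices if isinstance(infl, InfluenceSet) else infl
    Ss, Gs, ws = _structures(S, matrices, n_k)
    _check_identifiable(Gs)
    p = Gs[0].shape[0]
    m11 = sum(w * float((G * G).sum()) for w, G in zip(ws, Gs))
    m12 = sum(w * float(np.trace(G)) for w, G in zip(ws, Gs))
    m22 = sum(w * p for w in ws)
    v1 = sum(w * float((Sk * G).sum()) for w, Sk, G in zip(ws, Ss, Gs))
    v2 = sum(w * float(np.trace(Sk)) for w, Sk in zip(ws, Ss))
    M = np.array([[m11, m12], [m12, m22]])
    v = np.array([v1, v2])

    def objective(a: float, b: float) -> float:
        return sum(
            w * float(np.linalg.norm(Sk - a * G - b * np.eye(p)) ** 2)
            for w, Sk, G in zip(ws, Ss, Gs)
        )

    theta = np.linalg.solve(M, v)
    if theta[0] >= 0 and theta[1] >= 0:
        a, b = theta
    else:
        cand = [
            (0.0, max(v2 / m22, 0.0)),
            (max(v1 / m11, 0.0), 0.0),
        ]
        a, b = min(cand, key=lambda ab: objective(*ab))
    return VarianceComponents(float(a), float(b), method="REHE")


def restricted_loglik(
    a: float,
    b: float,
    S: Mapping[str, np.ndarray],
    infl: InfluenceSet | Mapping[str, np.ndarray],
    n_k: Mapping[str, int],
) -> float:
    """Restricted Gaussian log-likelihood (up to an additive constant) of the
    variance components, profiled over the saturated per-condition means."""
    matrices = infl.matrices if isinstance(infl, InfluenceSet) else infl
    Ss, Gs, ws = _structures(S, matrices, n_k)
    total = 0.0
    for w, Sk, G in zip(ws, Ss, Gs):
        d, U = np.linalg.eigh(G)
        s = np.einsum("ij,ij->j", U, Sk @ U)  # diag(U' S U)
        v = a * d + b
        if np.any(v <= 0):
            return -np.inf
        total += -0.5 * w * float(np.sum(np.log(v) + s / v))
    return total


def reml_estimate(
    S: Mapping[str, np.ndarray],
    infl: InfluenceSet | Mapping[str, np.ndarray],
    n_k: Mapping[str, int],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> VarianceComponents:
    """REML estimate of (sigma2_g, sigma2_e) by damped Newton iterations.

    The restricted log-likelihood (means profiled out; the n_k - 1 residual
    contrasts per condition) is maximized in log-parameters, which enforces
    nonnegativity; analytic gradient and Hessian come from the eigenvalue
    decomposition of each G_k = Lambda_k Lambda_k'. Convergence when the
    relative parameter change drops below ``tol``.
    """
    matrices = infl.matrices if isinstance(infl, InfluenceSet) else infl
    Ss, Gs, ws = _structures(S, matrices, n_k)
    _check_identifiable(Gs)
    eigs = []
    for Sk, G in zip(Ss, Gs):
        d, U = np.linalg.eigh(G)
        s = np.einsum("ij,ij->j", U, Sk @ U)
        eigs.append((d, s))

    def negloglik_grad_hess(a: float, b: float):
        f = 0.0
        g = np.zeros(2)
        H = np.zeros((2, 2))
        for w, (d, s) in zip(ws, eigs):
            v = a * d + b
            f += 0.5 * w * float(np.sum(np.log(v) + s / v))
            dv = [d, np.ones_like(d)]
            for i in range(2):
                g[i] += 0.5 * w * float(np.sum(dv[i] / v - s * dv[i] / v**2))
                for j in range(2):
                    H[i, j] += 0.5 * w * float(
                        np.sum(-dv[i] * dv[j] / v**2 + 2 * s * dv[i] * dv[j] / v**3)
                    )
        return f, g, H

    start = rehe_estimate(S, matrices, n_k)
    theta = np.log(np.maximum([start.sigma2_g, start.sigma2_e], 1e-4))
    f, g, H = negloglik_grad_hess(*np.exp(theta))
    for _ in range(max_iter):
        sig = np.exp(theta)
        # chain rule to log-parameters
        g_t = g * sig
        H_t = np.outer(sig, sig) * H + np.diag(g * sig)
        try:
            evals = np.linalg.eigvalsh(H_t)
            if evals.min() <= 1e-12:
                H_t = H_t + (abs(evals.min()) + 1e-6) * np.eye(2)
            step = -np.linalg.solve(H_t, g_t)
        except np.linalg.LinAlgError:
            step = -g_t
        step = np.clip(step, -5.0, 5.0)  # keep exp() in range during search
        # damped line search on the negative log-likelihood
        lam = 1.0
        for _ in range(40):
            cand = theta + lam * step
            f_new, g_new, H_new = negloglik_grad_hess(*np.exp(cand))
            if f_new < f + 1e-12:
                break
            lam *= 0.5
        else:
            cand, f_new, g_new, H_new = theta, f, g, H
        rel = np.max(np.abs(np.exp(cand) - np.exp(theta)) / (np.exp(theta) + 1e-12))
        theta, f, g, H = cand, f_new, g_new, H_new
        if rel < tol or np.linalg.norm(g * np.exp(theta)) < 1e-12:
            a, b = np.exp(theta)
            return VarianceComponents(float(a), float(b), method="REML")
    raise ValidationError(
        f"REML did not converge in {max_iter} iterations; last iterate "
        f"(sigma2_g, sigma2_e) = {tuple(np.exp(theta))}, gradient norm "
        f"{np.linalg.norm(g * np.exp(theta)):.3e}"
    )


def _sample_covariances(data: ExpressionDataset) -> dict[str, np.ndarray]:
    return {
        cond: np.cov(data.matrix(cond), ddof=1) for cond in data.conditions
    }


def fit_model(
    data: ExpressionDataset,
    infl: InfluenceSet,
    estimator: str = "rehe",
) -> ModelFit:
    """Estimate means and variance components for the full model."""
    beta = fit_means(data, infl)
    S = _sample_covariances(data)
    n_k = data.n_k
    if estimator == "rehe":
        vc = rehe_estimate(S, infl, n_k)
    elif estimator == "reml":
        vc = reml_estimate(S, infl, n_k)
    else:
        raise ValueError(f"estimator must be 'rehe' or 'reml', got {estimator!r}")
    cov_beta: dict[str, np.ndarray] = {}
    p = len(data.genes)
    for cond in data.conditions:
        L = infl[cond]
        Linv = np.linalg.solve(L, np.eye(p))
        Sigma = vc.sigma2_g * (L @ L.T) + vc.sigma2_e * np.eye(p)
        cov_beta[cond] = Linv @ Sigma @ Linv.T / n_k[cond]
    return ModelFit(beta, vc, cov_beta, n_k, data.genes)


# ---------------------------------------------------------------------------
# Pathway testing
# ---------------------------------------------------------------------------

def pathway_test(
    fit: ModelFit,
    infl: InfluenceSet,
    b: np.ndarray,
    conditions: tuple[str, str],
    name: str = "",
    normal_approx: bool = False,
) -> PathwayTestResult:
    """Two-sided test of the pathway contrast between two conditions.

    The contrast l = (-b'Lambda_1, b'Lambda_2) applied to the stacked means
    compares the network-propagated pathway activity; its variance under the
    fitted model is sum_k b'(sigma2_g G_k + sigma2_e I) b / n_k.
    """
    k1, k2 = conditions
    b = np.asarray(b, float)
    if b.sum() == 0:
        raise ValidationError("pathway indicator is empty")
    vc = fit.var_components
    num = float(b @ (infl[k2] @ fit.beta_hat[k2]) - b @ (infl[k1] @ fit.beta_hat[k1]))
    var = 0.0
    for k in (k1, k2):
        Ltb = infl[k].T @ b
        var += (vc.sigma2_g * float(Ltb @ Ltb) + vc.sigma2_e * float(b @ b)) / fit.n_k[k]
    if var <= 0:
        raise ValidationError(f"non-positive contrast variance for pathway {name!r}")
    stat = num / np.sqrt(var)
    df = float(fit.n_k[k1] + fit.n_k[k2] - 2)
    if normal_approx:
        pval = 2.0 * stats.norm.sf(abs(stat))
    else:
        pval = 2.0 * stats.t.sf(abs(stat), df)
    return PathwayTestResult(name, int(b.sum()), float(stat), df, float(pval))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------

def _neighbors_subset(
    adj: BinaryAdjacency, members: Sequence[str]
) -> list[str]:
    u = adj.undirected_view()
    pos = {g: i for i, g in enumerate(adj.genes)}
    keep = set(members)
    for g in members:
        for j in np.nonzero(u[pos[g]])[0]:
            keep.add(adj.genes[j])
    return [g for g in adj.genes if g in keep]


def run_netgsa(
    data: ExpressionDataset,
    pathways: PathwaySet,
    edges: EdgeList | BinaryAdjacency | None = None,
    estimator: str = "rehe",
    cluster: bool = True,
    max_size: int = 1000,
    penalty: float | str = "auto",
    nonedge_weight: float = np.inf,
    fdr: float = 0.05,
    seed: int = 0,
    conditions: tuple[str, str] | None = None,
    normal_approx: bool = False,
) -> pd.DataFrame:
    """Full pipeline: clustering, adjacency estimation, variance components,
    per-pathway tests, BH adjustment.

    ``estimator="rehe"`` (default) fits the variance components once on the
    entire network; ``estimator="reml"`` refits per pathway on the subnetwork
    of members plus their direct neighbors, mirroring the per-pathway REML
    protocol. With no edge list the network is learned from the data (the
    non-edge penalty weight defaults to 1 in that case).

    Returns a DataFrame with columns pathway, size, stat, df, pvalue, qvalue.
    """
    learned = False
    if isinstance(edges, BinaryAdjacency):
        if not edges.genes.equals(data.genes):
            raise ValidationError("adjacency and expression gene orders differ")
        known = edges
        data, _, pathways = harmonize(data, None, pathways)
    else:
        if edges is None:
            learned = True
            if not np.isfinite(nonedge_weight):
                logger.info(
                    "no edge list supplied: learning the network from "
                    "expression data (non-edge penalty weight set to 1)"
                )
                nonedge_weight = 1.0
        data, edges, pathways = harmonize(data, edges, pathways)
        known = build_binary_adjacency(edges or EdgeList(), data.genes)

    if conditions is None:
        if data.n_conditions != 2:
            raise ValidationError(
                "data has more than 2 conditions; pass an explicit pair"
            )
        conditions = tuple(data.conditions)  # type: ignore[assignment]

    if learned:
        # no known structure: the candidate support is the complete graph,
        # so estimation runs on a single all-genes cluster
        from .clustering import block_order

        partition = block_order(known, [({g: 0 for g in data.genes}, "none")])
    elif cluster:
        partition = cluster_network(known, max_size=max_size, seed=seed)
    else:
        partition = component_partition(known)
    adjset = estimate_adjacency(
        data, known, partition, penalty=penalty, nonedge_weight=nonedge_weight
    )
    infl = influence_set(adjset, partition)

    memb = pathways.membership.reindex(columns=data.genes, fill_value=0)
    results: list[PathwayTestResult] = []
    if estimator == "rehe":
        fit = fit_model(data, infl, estimator="rehe")
        for pname in pathways.names:
            b = memb.loc[pname].to_numpy(float)
            results.append(
                pathway_test(fit, infl, b, conditions, name=pname,
                             normal_approx=normal_approx)
            )
    elif estimator == "reml":
        for pname in pathways.names:
            members = pathways.members(pname)
            sub_genes = _neighbors_subset(known, members)
            idx = [data.genes.get_loc(g) for g in sub_genes]
            sub_data = data.restrict_genes(sub_genes)
            sub_infl = InfluenceSet(
                {
                    c: influence_matrix(adjset[c][np.ix_(idx, idx)])
                    for c in adjset.conditions
                },
                pd.Index(sub_genes),
            )
            sub_fit = fit_model(sub_data, sub_infl, estimator="reml")
            b = memb.loc[pname].reindex(sub_genes).to_numpy(float)
            results.append(
                pathway_test(sub_fit, sub_infl, b, conditions, name=pname,
                             normal_approx=normal_approx)
            )
    else:
        raise ValueError(f"estimator must be 'rehe' or 'reml', got {estimator!r}")

    qvals = bh_adjust(np.array([r.pvalue for r in results]))
    results = [replace(r, qvalue=float(q)) for r, q in zip(results, qvals)]
    out = pd.DataFrame(
        [
            {
                "pathway": r.pathway, "size": r.size, "stat": r.stat,
                "df": r.df, "pvalue": r.pvalue, "qvalue": r.qvalue,
            }
            for r in results
        ]
    )
    logger.info(
        "tested %d pathways (%s, clustering %s): %d significant at FDR %g",
        len(out), estimator, "on" if cluster else "off",
        int((out["qvalue"] <= fdr).sum()), fdr,
    )
    return out
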