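# Methods

## Model

`pynetgsa` tests pathway enrichment between experimental conditions while
accounting for the interaction network among genes (or proteins,
metabolites). For a sample `i` in condition `k` the gene vector is modeled
as

    y_i = Λ_k β_k + Λ_k γ_i + ε_i,
    γ_i ~ N(0, σ²_g I),   ε_i ~ N(0, σ²_ε I),

where `Λ_k = (I − A_k)⁻¹` is the influence matrix of the condition-specific
weighted adjacency `A_k`: it propagates each gene's baseline effect `β`
through the network, so `Cov(y) = σ²_g Λ_k Λ_kᵀ + σ²_ε I`. A pathway with
0/1 indicator `b` is tested with the contrast `ℓ = (−bᵀΛ_1, bᵀΛ_2)` on the
stacked means,

    T = ℓ β̂ / sqrt(ℓ C ℓᵀ),
    Cov(β̂_k) = Λ_k⁻¹ (σ̂²_g Λ_kΛ_kᵀ + σ̂²_ε I) Λ_k⁻ᵀ / n_k,

referred to a t distribution, with Benjamini–Hochberg adjustment across
pathways. Because `β̂_k = Λ_k⁻¹ ȳ_k`, the numerator reduces to
`bᵀ(ȳ_2 − ȳ_1)`; the network enters through the variance, which is what
gives the method power when signal spreads along edges.

Key assumptions: Gaussian data on a common scale per gene (standardize
first if not), the same gene universe and ordering across all matrices, two
conditions per test (pick a pair explicitly for multi-condition data), and
variance components shared across conditions (the joint moment objective
below implies this choice).

## Weighted adjacency estimation

The 0/1 interaction structure is external knowledge; the *weights* are
estimated per condition from the data. For undirected networks each gene is
regressed on the other genes of its cluster with an L1 penalty whose
per-coefficient factor is 0 for known-edge partners and `nonedge_weight`
for non-partners:

- **external mode** (default, `nonedge_weight = ∞`): non-edges are excluded,
  so each neighborhood regression is ordinary least squares on the known
  neighbors;
- **discovery mode** (finite `nonedge_weight`, automatic when no edge list
  is given): non-edges enter with penalty `λ·w`, `λ = c·sqrt(log p / n)`
  (`c = 1` by default), solved by cyclic coordinate descent. This is what
  makes the method robust to missing edges in curated databases: a strong
  data-supported edge can survive the penalty.

The two coefficients of a pair are symmetrized by the signed geometric mean
`sign·sqrt(|b_ij b_ji|)` when their signs agree (0 otherwise), which equals
the partial correlation when the regressions are exact. Genes are centered
within condition and (for the undirected estimator) scaled to unit
variance; partial-correlation weights are scale-invariant, so scaling only
stabilizes the numerics. For known *directed acyclic* structures each gene
is regressed by OLS on its parents (centered, unscaled, so coefficients
stay on the data scale), and `A[child, parent]` holds the coefficient.

Invertibility of `I − A_k` is checked (condition number < 1e12) rather than
enforced by rescaling; in practice the estimated partial correlations keep
the spectrum well inside the unit disc.

## Clustering and block diagonalization

Estimating `A_k` is the expensive step, and it decomposes exactly over sets
of genes that share no allowed edges. Connected components of the 0/1
structure are found first; any component larger than `max_size` (default
1000 genes) is split by six community-detection algorithms (walktrap,
leading eigenvector, fast greedy, label propagation, infomap, louvain, via
python-igraph on the undirected view). Candidates whose largest cluster
still exceeds `max_size` are discarded; among survivors the partition with
the smallest **edge loss** — the count of distinct 0/1 edges crossing
clusters — is chosen, with ties broken by the fixed algorithm order above.
If every candidate is oversized, the minimum-loss candidate is re-clustered
recursively (up to 3 rounds); if that still fails the component is kept
whole with a warning. Stochastic algorithms are seeded, so partitions are
reproducible. `A_k` is then estimated per cluster and reassembled
block-diagonally; within-cluster results are *identical* to whole-network
estimation (verified elementwise in the tests), the only approximation
being the dropped cross-cluster edges. Clustering runs once on the shared
0/1 structure, not per condition. In discovery mode without an edge list
there is no structure to cluster, so estimation runs on a single all-genes
cluster.

## Variance components: REHE and REML

Let `S_k` be the within-condition sample covariance and
`G_k = Λ_k Λ_kᵀ`.

**REHE** (restricted Haseman–Elston; the default) solves

    min_{σ²_g, σ²_ε ≥ 0}  Σ_k (n_k − 1) ‖S_k − σ²_g G_k − σ²_ε I‖²_F

via the closed-form 2×2 normal equations; if the unconstrained solution
leaves the quadrant, both single-component boundary problems are
re-minimized and the feasible minimizer kept. This is a method-of-moments
fit — no iteration, no likelihood — which is why it is fast.

**REML** maximizes the restricted Gaussian log-likelihood of the
`n_k − 1` residual contrasts per condition, which after eigendecomposition
`G_k = U D Uᵀ` separates into scalar terms `log(σ²_g d + σ²_ε) +
s/(σ²_g d + σ²_ε)`. Damped Newton iterations run in log-parameters
(enforcing nonnegativity) with analytic gradient and Hessian, starting from
the REHE estimate; convergence at relative change < 1e-8, at most 100
iterations, steps clipped to ±5 in log-space. Mirroring the reference
protocol, `run_netgsa(estimator="reml")` refits per pathway on the
subnetwork of members plus their direct neighbors (the restriction is
applied to the already estimated `A_k` blocks), while REHE runs once on the
whole network.

If every `G_k` is proportional to the identity (no effective network
structure) only the sum `σ²_g + σ²_ε` is identified and both estimators
raise an explicit error rather than returning an arbitrary split.

**Degrees of freedom.** The t reference uses `df = n_1 + n_2 − 2` under
both estimators, with a `normal_approx` switch for large samples. At the
sample sizes this package targets (tens of samples per condition) the t and
normal references are nearly indistinguishable, and the null-calibration
property test (KS distance of pooled null p-values from uniform < 0.1)
guards the choice.

## Synthetic data and the power study

The generator emulates a two-condition expression study:

- **network**: genes split evenly into `n_components` components (default 3
  for p = 150), Erdős–Rényi edges within components at density 0.05 (mean
  degree ≈ 2.5 at the default sizes — sparse, like curated interaction
  networks); weights uniform on ±[0.2, 0.6], shared between conditions
  (optionally perturbed), rescaled so the spectral radius of each `A_k` is
  at most 0.9 so `Λ_k` always exists;
- **expression**: draws from the model itself with `σ²_g = 0.3`,
  `σ²_ε = 0.7` — a unit-scale total variance with a meaningful but not
  dominant network-propagated share;
- **signal injection**: every gene is standardized to zero mean and unit
  variance across *all* samples first, then the mean signal `mu`
  (0.2 / 0.3 / 0.4 in the reference design) is added to the dysregulated
  genes in the target condition only;
- **dysregulation frameworks**: three seedable stand-ins —
  `uniform-random` (default), `betweenness-ranked` (top fraction by
  betweenness centrality) and `neighborhood-seeded` (sets grown along edges
  from random seeds, concentrating signal topologically). Default fraction
  0.3 of the genes.

`run_power_study` repeats generate → dysregulate → full pipeline with
common random numbers across `mu` values, bins pathways by their number of
dysregulated members (None, (0,5], (5,10], >10) and reports the mean and
standard error of the FDR-0.05 rejection indicator per (group, mu) cell.
The None group estimates type-I error, the rest power.

The desk-scale default design (p = 150 genes, 15 pathways, 40 + 40 samples,
50 replicates in the acceptance run) keeps a full study under a minute on
one core; all sizes are plain fields of `SimulationDesign`, so larger
studies are configuration, not code. What the generator does **not**
emulate: heavy-tailed or count-distributed expression, batch effects,
condition-specific topology differences beyond weight perturbation,
identifier noise, or correlated pathway collections curated from real
databases — passing tests show the statistical machinery is correct under
its own model, not that real data meet the model.

## Numerical choices and degenerate inputs

- Coordinate descent: tolerance 1e-8 on the largest coefficient update,
  at most 2000 sweeps, deterministic cyclic order.
- Influence matrices: solved (never explicitly inverted except for
  `Λ⁻¹` in `Cov(β̂)`), blockwise under clustering; residual check
  `(I − A)Λ − I` within 1e-8 in the tests.
- Constant genes (zero variance) raise errors naming the gene; empty
  pathways and empty contrasts are rejected rather than silently skipped.
- Pathways whose members are all isolated still get a statistic through
  the `σ̂²_ε` term — no special-casing.
- Edge loss on directed graphs counts distinct unordered pairs (the
  undirected view used by the community algorithms).
- All randomness lives in data generation and the seeded clustering
  algorithms; estimation and testing are deterministic given data.

## Known limitations

- No covariate adjustment and no joint K-condition tests; multi-condition
  data are analyzed pairwise.
- The per-pathway REML restriction truncates network influence at direct
  neighbors; pathways embedded in long dependency chains lose some
  propagated variance.
- Discovery mode on thousands of genes is quadratic per gene in the
  candidate set and is meant for moderate universes.
- The t-reference df is a pragmatic choice, not a Satterthwaite
  approximation; for very small samples (n_k near the minimum of 3) the
  test may be mildly miscalibrated.
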