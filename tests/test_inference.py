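import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats, optimize

import pynetgsa as pg
from pynetgsa.inference import _sample_covariances
from pynetgsa.io import ValidationError


def make_infl(p=6, seed=0, scale=0.3):
    rng = np.random.default_rng(seed)
    A = rng.normal(scale=scale, size=(p, p))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    rho = np.max(np.abs(np.linalg.eigvalsh(A)))
    if rho > 0.8:
        A *= 0.8 / rho
    return np.linalg.inv(np.eye(p) - A)


def simulate_model(L, s2g, s2e, n, seed):
    """Samples from y = L(beta + gamma) + eps with beta = 0."""
    rng = np.random.default_rng(seed)
    p = L.shape[0]
    return L @ rng.normal(0, np.sqrt(s2g), (p, n)) + rng.normal(0, np.sqrt(s2e), (p, n))


class TestFitMeans:
    def test_identity_influence_returns_sample_mean(self, fixture_50):
        _, _, _, _, data = fixture_50
        p = len(data.genes)
        infl = pg.InfluenceSet({c: np.eye(p) for c in data.conditions}, data.genes)
        beta = pg.fit_means(data, infl)
        for c in data.conditions:
            assert np.allclose(beta[c], data.matrix(c).mean(axis=1))

    def test_triangular_two_gene_system(self):
        vals = pd.DataFrame(
            np.column_stack([[1.0, 1.5]] * 6),
            index=["a", "b"], columns=[f"s{i}" for i in range(6)],
        )
        vals += 0.0  # exact means (1, 1.5) in both conditions
        cond = pd.Series(["x"] * 3 + ["y"] * 3, index=vals.columns)
        data = pg.ExpressionDataset(vals, cond)
        L = np.array([[1.0, 0.0], [0.5, 1.0]])
        infl = pg.InfluenceSet({"x": L, "y": L}, data.genes)
        beta = pg.fit_means(data, infl)
        assert np.allclose(beta["x"], [1.0, 1.0])

    def test_duplicating_samples_leaves_estimate_unchanged(self, fixture_50):
        _, _, _, _, data = fixture_50
        doubled = pg.ExpressionDataset(
            pd.concat(
                [data.values, data.values.add_suffix("_dup", axis=1)], axis=1
            ),
            pd.concat([data.condition_of,
                       data.condition_of.set_axis(
                           data.condition_of.index + "_dup")]),
        )
        p = len(data.genes)
        infl = pg.InfluenceSet({c: np.eye(p) for c in data.conditions}, data.genes)
        b1, b2 = pg.fit_means(data, infl), pg.fit_means(doubled, infl)
        for c in data.conditions:
            assert np.allclose(b1[c], b2[c])


class TestREHE:
    def test_exact_recovery_from_constructed_covariance(self):
        L = make_infl(p=8, seed=1)
        S = {"x": 0.3 * L @ L.T + 0.7 * np.eye(8)}
        vc = pg.rehe_estimate(S, {"x": L}, {"x": 20})
        assert abs(vc.sigma2_g - 0.3) < 1e-8
        assert abs(vc.sigma2_e - 0.7) < 1e-8

    def test_zero_covariance_gives_origin(self):
        L = make_infl(p=5, seed=2)
        vc = pg.rehe_estimate({"x": np.zeros((5, 5))}, {"x": L}, {"x": 10})
        assert vc.sigma2_g == 0 and vc.sigma2_e == 0

    def test_boundary_projection_clamps_negative_component(self):
        L = make_infl(p=6, seed=3)
        G = L @ L.T
        S = {"x": -0.05 * G + 1.0 * np.eye(6)}
        vc = pg.rehe_estimate(S, {"x": L}, {"x": 10})
        assert vc.sigma2_g == 0.0
        # re-minimized second component: tr(S)/p
        assert abs(vc.sigma2_e - np.trace(S["x"]) / 6) < 1e-10

    def test_identity_influence_not_identifiable(self):
        with pytest.raises(ValidationError, match="identifiab"):
            pg.rehe_estimate({"x": np.eye(4)}, {"x": np.eye(4)}, {"x": 10})

    def test_monte_carlo_consistency(self):
        # mean estimate over 200 replicates near the generating components
        L = make_infl(p=30, seed=4)
        est = []
        for r in range(200):
            Y = simulate_model(L, 0.5, 1.0, 200, seed=1000 + r)
            S = {"x": np.cov(Y, ddof=1)}
            vc = pg.rehe_estimate(S, {"x": L}, {"x": 200})
            est.append([vc.sigma2_g, vc.sigma2_e])
        mean = np.mean(est, axis=0)
        assert abs(mean[0] - 0.5) < 0.05
        assert abs(mean[1] - 1.0) < 0.05

    def test_global_optimum_on_grid(self):
        # returned point beats a 50x50 grid over [0, 2]^2
        for seed in range(10):
            L = make_infl(p=6, seed=seed)
            Y = simulate_model(L, 0.6, 0.9, 50, seed=seed)
            S = np.cov(Y, ddof=1)
            vc = pg.rehe_estimate({"x": S}, {"x": L}, {"x": 50})
            G = L @ L.T

            def obj(a, b):
                return np.linalg.norm(S - a * G - b * np.eye(6)) ** 2

            best = vc and obj(vc.sigma2_g, vc.sigma2_e)
            grid = np.linspace(0, 2, 50)
            assert best <= min(obj(a, b) for a in grid for b in grid) + 1e-9

    def test_bias_shrinks_with_sample_size(self):
        L = make_infl(p=20, seed=5)
        bias = []
        for n in (50, 200, 800):
            est = []
            for r in range(60):
                Y = simulate_model(L, 0.5, 1.0, n, seed=r * 7 + n)
                vc = pg.rehe_estimate(
                    {"x": np.cov(Y, ddof=1)}, {"x": L}, {"x": n})
                est.append([vc.sigma2_g, vc.sigma2_e])
            m = np.mean(est, axis=0)
            bias.append(abs(m[0] - 0.5) + abs(m[1] - 1.0))
        assert bias[0] >= bias[1] >= bias[2] or bias[2] < 0.02


class TestREML:
    def test_agrees_with_rehe_at_moderate_n(self):
        L = make_infl(p=20, seed=6)
        Y = simulate_model(L, 0.5, 1.0, 300, seed=11)
        S = {"x": np.cov(Y, ddof=1)}
        rehe = pg.rehe_estimate(S, {"x": L}, {"x": 300})
        reml = pg.reml_estimate(S, {"x": L}, {"x": 300})
        assert abs(reml.sigma2_g - rehe.sigma2_g) < 0.05
        assert abs(reml.sigma2_e - rehe.sigma2_e) < 0.05

    def test_identity_influence_not_identifiable(self):
        with pytest.raises(ValidationError, match="identifiab"):
            pg.reml_estimate({"x": 2 * np.eye(4)}, {"x": np.eye(4)}, {"x": 10})

    def test_likelihood_at_reml_beats_rehe(self):
        L = make_infl(p=10, seed=7)
        Y = simulate_model(L, 0.4, 0.8, 60, seed=12)
        S = {"x": np.cov(Y, ddof=1)}
        infl = {"x": L}
        n = {"x": 60}
        rehe = pg.rehe_estimate(S, infl, n)
        reml = pg.reml_estimate(S, infl, n)
        ll_reml = pg.restricted_loglik(reml.sigma2_g, reml.sigma2_e, S, infl, n)
        ll_rehe = pg.restricted_loglik(
            max(rehe.sigma2_g, 1e-8), max(rehe.sigma2_e, 1e-8), S, infl, n)
        assert ll_reml >= ll_rehe - 1e-8

    def test_newton_matches_derivative_free_optimizer(self):
        for seed in range(10):
            L = make_infl(p=8, seed=20 + seed)
            Y = simulate_model(L, 0.5, 1.0, 80, seed=30 + seed)
            S = {"x": np.cov(Y, ddof=1)}
            infl, n = {"x": L}, {"x": 80}
            reml = pg.reml_estimate(S, infl, n)
            res = optimize.minimize(
                lambda t: -pg.restricted_loglik(np.exp(t[0]), np.exp(t[1]),
                                                S, infl, n),
                x0=np.log([0.5, 1.0]), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            a, b = np.exp(res.x)
            assert abs(reml.sigma2_g - a) < 1e-4
            assert abs(reml.sigma2_e - b) < 1e-4

    def test_two_conditions_pooled(self):
        L1, L2 = make_infl(p=12, seed=8), make_infl(p=12, seed=9)
        Y1 = simulate_model(L1, 0.5, 1.0, 400, seed=13)
        Y2 = simulate_model(L2, 0.5, 1.0, 400, seed=14)
        S = {"x": np.cov(Y1, ddof=1), "y": np.cov(Y2, ddof=1)}
        infl = {"x": L1, "y": L2}
        n = {"x": 400, "y": 400}
        reml = pg.reml_estimate(S, infl, n)
        assert abs(reml.sigma2_g - 0.5) < 0.1
        assert abs(reml.sigma2_e - 1.0) < 0.1


class TestPathwayTest:
    def _fit(self, beta, L, s2g, s2e, n=10):
        p = L.shape[0]
        vc = pg.VarianceComponents(s2g, s2e, "REHE")
        conds = list(beta)
        cov = {}
        for c in conds:
            Linv = np.linalg.inv(L)
            cov[c] = Linv @ (s2g * L @ L.T + s2e * np.eye(p)) @ Linv.T / n
        return pg.ModelFit(beta, vc, cov, {c: n for c in conds},
                           pd.Index([f"g{i}" for i in range(p)]))

    def test_null_contrast_gives_zero_statistic(self):
        L = make_infl(p=4, seed=10)
        beta = {"x": np.ones(4), "y": np.ones(4)}
        fit = self._fit(beta, L, 0.3, 0.7)
        infl = pg.InfluenceSet({"x": L, "y": L}, fit.genes)
        res = pg.pathway_test(fit, infl, np.ones(4), ("x", "y"))
        assert res.stat == 0.0
        assert res.pvalue == 1.0

    def test_hand_computed_two_gene_case(self):
        # b = (1,1), Lambda = I, beta diff = (1,1): numerator b'(beta2-beta1)=2;
        # variance per condition (s2g+s2e)|b|^2/n = 1*2/4 = 0.5, total 1 -> T=2
        L = np.eye(2)
        beta = {"x": np.zeros(2), "y": np.ones(2)}
        vc = pg.VarianceComponents(0.5, 0.5, "REHE")
        fit = pg.ModelFit(beta, vc, {}, {"x": 4, "y": 4}, pd.Index(["a", "b"]))
        infl = pg.InfluenceSet({"x": L, "y": L}, fit.genes)
        res = pg.pathway_test(fit, infl, np.ones(2), ("x", "y"))
        assert res.stat == pytest.approx(2.0)
        assert res.df == 6
        assert res.size == 2

    def test_scale_equivariance(self):
        L = make_infl(p=5, seed=11)
        rng = np.random.default_rng(12)
        beta = {"x": rng.normal(size=5), "y": rng.normal(size=5)}
        b = np.array([1, 0, 1, 1, 0], float)
        infl = pg.InfluenceSet({"x": L, "y": L}, pd.Index(list("abcde")))
        fit1 = self._fit(beta, L, 0.3, 0.7)
        c = 3.7
        fit2 = self._fit({k: c * v for k, v in beta.items()}, L,
                         c**2 * 0.3, c**2 * 0.7)
        r1 = pg.pathway_test(fit1, infl, b, ("x", "y"))
        r2 = pg.pathway_test(fit2, infl, b, ("x", "y"))
        assert r1.stat == pytest.approx(r2.stat)

    def test_empty_pathway_rejected(self):
        L = np.eye(2)
        fit = self._fit({"x": np.zeros(2), "y": np.zeros(2)}, L, 0.3, 0.7)
        infl = pg.InfluenceSet({"x": L, "y": L}, fit.genes)
        with pytest.raises(ValidationError, match="empty"):
            pg.pathway_test(fit, infl, np.zeros(2), ("x", "y"))


def brute_force_bh(p):
    """Step-up rule applied literally: q_(i) = min_{j>=i} p_(j) m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestBH:
    def test_step_up_example(self):
        q = pg.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_all_ones_and_singleton(self):
        assert np.allclose(pg.bh_adjust(np.ones(5)), 1.0)
        assert pg.bh_adjust(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            pg.bh_adjust(np.array([0.5, 1.2]))

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = rng.random(size=rng.integers(1, 40))
            assert np.allclose(pg.bh_adjust(p), brute_force_bh(p))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_qvalues_dominate_pvalues(self, pvals):
        p = np.array(pvals)
        q = pg.bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        # monotone in p-rank
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestRunNetgsa:
    def test_clustering_noop_below_threshold(self, fixture_50):
        _, adj, _, pathways, data = fixture_50
        on = pg.run_netgsa(data, pathways, edges=adj, cluster=True, seed=1)
        off = pg.run_netgsa(data, pathways, edges=adj, cluster=False, seed=1)
        pd.testing.assert_frame_equal(on, off)

    def test_rehe_whole_network_and_reml_per_pathway_complete(self, fixture_50):
        _, adj, _, pathways, data = fixture_50
        rehe = pg.run_netgsa(data, pathways, edges=adj, estimator="rehe", seed=1)
        reml = pg.run_netgsa(data, pathways, edges=adj, estimator="reml", seed=1)
        for res in (rehe, reml):
            assert list(res.columns) == [
                "pathway", "size", "stat", "df", "pvalue", "qvalue"]
            assert res["pvalue"].between(0, 1).all()
            assert res["qvalue"].between(0, 1).all()
            assert (res["qvalue"] >= res["pvalue"] - 1e-12).all()

    def test_sizes_match_membership(self, fixture_50):
        _, adj, _, pathways, data = fixture_50
        res = pg.run_netgsa(data, pathways, edges=adj, seed=1)
        expected = pathways.sizes()
        for _, row in res.iterrows():
            assert row["size"] == expected[row["pathway"]]

    def test_learned_network_without_edges(self, fixture_50):
        # with no edge list the network is learned from the data
        _, _, _, pathways, data = fixture_50
        res = pg.run_netgsa(data, pathways, edges=None, seed=1)
        assert len(res) == len(pathways)

    def test_deterministic_given_seed(self, fixture_50):
        _, adj, _, pathways, data = fixture_50
        r1 = pg.run_netgsa(data, pathways, edges=adj, seed=5)
        r2 = pg.run_netgsa(data, pathways, edges=adj, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_cov_beta_symmetric_psd(self, fixture_50):
        _, adj, _, _, data = fixture_50
        part = pg.component_partition(adj)
        est = pg.estimate_adjacency(data, adj, part)
        infl = pg.influence_set(est, part)
        fit = pg.fit_model(data, infl)
        for c in data.conditions:
            C = fit.cov_beta[c]
            assert np.allclose(C, C.T, atol=1e-10)
            assert np.linalg.eigvalsh(C).min() > -1e-10
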