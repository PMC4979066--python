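"""OU likelihoods against brute-force oracles; fitting, scanning, LRT, FDR."""

import numpy as np
import pandas as pd
import pytest

import exprshift as es
from exprshift.ou_shift import (OUSolver, RegimePainting, admissible_nodes,
                                fit_ou1, fit_ou2, lrt_and_fdr,
                                node_shift_outliers, ou_loglik, scan_shifts)

import oracles
from conftest import random_tree


def _series(tree, values):
    return pd.Series(values, index=tree.tip_labels, dtype=float)


class TestOULoglik:
    def test_two_tip_closed_form(self):
        """Depth-1 cherry joined at the root: V = sigma2/(2a)(1-e^{-2a}) I."""
        t = es.parse_newick("(A:1,B:1):0;")
        x = _series(t, [0.0, 0.0])
        alpha, sigma2 = 1.0, 2.0
        got = ou_loglik(t, x, None, alpha, sigma2, 0.0)
        v = sigma2 / (2 * alpha) * (1 - np.exp(-2 * alpha))
        expect = 2 * (-0.5 * np.log(2 * np.pi * v))
        assert got == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("alpha", [0.3, 1.0, 5.0])
    def test_ou1_matches_quadrature_oracle(self, seed, alpha):
        t = random_tree(3 + seed, seed, clock=True)
        rng = np.random.default_rng(seed)
        x = _series(t, rng.normal(1.0, 1.0, t.n_tips))
        sigma2, theta = 1.3, 0.7
        got = ou_loglik(t, x, None, alpha, sigma2, theta)
        m, V, labs = oracles.ou_mean_cov_quad(t, alpha, sigma2,
                                              np.array([theta]))
        expect = oracles.mvn_loglik(x.loc[labs].to_numpy(), m, V)
        assert got == pytest.approx(expect, abs=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_ou2_painting_matches_quadrature_oracle(self, seed):
        t = random_tree(6, seed, clock=True)
        nodes = admissible_nodes(t, 2)
        if not nodes:
            pytest.skip("no admissible painting on this draw")
        node = nodes[0]
        rng = np.random.default_rng(seed + 50)
        x = _series(t, rng.normal(0.0, 1.0, t.n_tips))
        painting = RegimePainting.at_node(t, node, min_species=2)
        for alpha, sigma2, theta in [(0.5, 1.0, (0.0, 2.0)),
                                     (3.0, 0.5, (1.0, -1.0))]:
            got = ou_loglik(t, x, painting, alpha, sigma2, np.array(theta))
            v = t.index(node)
            m, V, labs = oracles.ou_mean_cov_quad(
                t, alpha, sigma2, np.array(theta),
                derived_tips=frozenset(t.tips_below(v)),
                shift_depth=float(t.depths()[t.parent[v]]))
            expect = oracles.mvn_loglik(x.loc[labs].to_numpy(), m, V)
            assert got == pytest.approx(expect, abs=1e-8)

    def test_regime_weights_sum_to_one(self):
        t = random_tree(8, 1, clock=True)
        solver = OUSolver(t)
        node = admissible_nodes(t, 3)[0]
        painting = RegimePainting.at_node(t, node)
        for alpha in [1e-6, 0.5, 10.0]:
            W = solver.weights(alpha, painting)
            np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bm_limit_at_tiny_alpha(self, seed):
        """OU1 loglik at alpha = 1e-6 is within 1e-3 of the BM loglik."""
        t = random_tree(6 + seed, seed, clock=True)
        rng = np.random.default_rng(seed + 10)
        x = _series(t, rng.normal(2.0, 1.0, t.n_tips))
        sigma2, theta = 0.8, 2.0
        ll_ou = ou_loglik(t, x, None, 1e-6, sigma2, theta)
        C, labs = es.tree_covariance(t)
        ll_bm = oracles.mvn_loglik(x.loc[labs].to_numpy(),
                                   np.full(t.n_tips, theta), sigma2 * C)
        assert abs(ll_ou - ll_bm) < 1e-3
        # and alpha=0 dispatches exactly to BM
        assert ou_loglik(t, x, None, 0.0, sigma2, theta) == \
            pytest.approx(ll_bm, abs=1e-10)

    def test_non_ultrametric_tree_rejected(self):
        t = random_tree(6, 0, clock=False)
        x = _series(t, np.arange(t.n_tips, dtype=float))
        with pytest.raises(ValueError, match="ultrametric"):
            ou_loglik(t, x, None, 1.0, 1.0, 0.0)


class TestFitOU1:
    def test_recovers_optimum_under_strong_selection(self):
        """With alpha*depth = 5 the fitted optimum tracks the truth."""
        tree = es.gen_yule_tree(64, seed=3, normalize_depth=True)
        cfg = es.ScenarioConfig(n_species=64, n_genes=200, generator="ou1",
                                seed=3, alpha=5.0, missing_fraction=0.0,
                                mu_mean=10.0, mu_sd=0.0,
                                log_sigma2_mean=float(np.log(0.5)),
                                log_sigma2_sd=0.0)
        X, smap, truth = es.gen_expression(cfg, tree)
        sv = float(np.sqrt(0.5 / (2 * 5.0)))
        thetas = []
        for g in X.gene_ids[:60]:
            fit = fit_ou1(tree, X.data.loc[g])
            assert fit.converged
            assert abs(fit.theta[0] - 10.0) < 3 * sv
            thetas.append(fit.theta[0])
        assert np.mean(thetas) == pytest.approx(10.0, abs=0.05 * max(sv, 1.0))

    def test_large_alpha_theta_approaches_tip_mean(self):
        tree = es.gen_yule_tree(16, seed=4, normalize_depth=True)
        rng = np.random.default_rng(4)
        x = _series(tree, rng.normal(3.0, 0.1, 16))
        solver = OUSolver(tree)
        _, theta, _ = solver.profile(x.loc[solver.labels].to_numpy(),
                                     solver.alpha_max, None)
        assert theta[0] == pytest.approx(float(x.mean()), abs=1e-3)

    def test_constant_gene_flagged_degenerate(self):
        t = random_tree(6, 1, clock=True)
        fit = fit_ou1(t, _series(t, np.full(t.n_tips, 2.0)))
        assert not fit.converged


class TestScanShifts:
    def test_admissible_nodes_on_balanced_six_tip_tree(self):
        t = es.parse_newick(
            "(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1):0;")
        got = admissible_nodes(t, 3)
        # both root children split 3|3; deeper nodes leave < 3 on one side
        assert len(got) == 2
        assert {frozenset(t.tips_below(t.index(n))) for n in got} == \
            {frozenset("ABC"), frozenset("DEF")}

    def test_planted_shift_recovered(self):
        cfg = es.ScenarioConfig(n_species=24, n_genes=40,
                                generator="ou2_shift", seed=8,
                                missing_fraction=0.0)
        tree = es.gen_yule_tree(24, seed=8, normalize_depth=True)
        X, smap, truth = es.gen_expression(cfg, tree)
        planted = truth["per_gene"]["shift_node"].iloc[0]
        v = tree.index(planted)
        neighborhood = {planted, tree.names[tree.parent[v]]} | \
            {tree.names[c] for c in tree.children[v]}
        hits = 0
        for g in X.gene_ids:
            ou1, ou2 = scan_shifts(tree, X.data.loc[g])
            assert ou2.loglik >= ou1.loglik - 1e-6
            hits += ou2.focal_node in neighborhood
        assert hits / len(X.gene_ids) >= 0.8

    def test_lambda_nonnegative_on_null_data(self):
        cfg = es.ScenarioConfig(n_species=16, n_genes=30, generator="ou1",
                                seed=9, missing_fraction=0.1)
        tree = es.gen_yule_tree(16, seed=9, normalize_depth=True)
        X, smap, _ = es.gen_expression(cfg, tree)
        Xs = es.collapse_conspecifics(X, smap)
        for g in Xs.gene_ids:
            ou1, ou2 = scan_shifts(tree, Xs.data.loc[g])
            assert 2 * (ou2.loglik - ou1.loglik) >= -1e-6

    def test_fixture_scan_reproduces_expected(self, toy6):
        tree = toy6["tree"]
        X = toy6["expression"]
        Xs = es.collapse_conspecifics(X, toy6["sample_map"])
        expect = toy6["expected_ou"]
        for g in expect.index:
            if expect.loc[g, "best_node"] == "none":
                with pytest.raises(ValueError):
                    scan_shifts(tree, Xs.data.loc[g])
                continue
            ou1, ou2 = scan_shifts(tree, Xs.data.loc[g])
            assert ou2.focal_node == expect.loc[g, "best_node"]
            assert ou1.loglik == pytest.approx(expect.loc[g, "loglik_ou1"],
                                               abs=1e-6)
            assert ou2.loglik == pytest.approx(expect.loc[g, "loglik_ou2"],
                                               abs=1e-6)


class TestLRTAndFDR:
    def _scan_frame(self, lams):
        return pd.DataFrame({
            "status": ["ok"] * len(lams),
            "loglik_ou1": np.zeros(len(lams)),
            "loglik_ou2": np.asarray(lams) / 2.0,
            "best_node": ["N2"] * len(lams),
        }, index=[f"g{i}" for i in range(len(lams))])

    def test_zero_lambda_gives_p_one(self):
        out, _ = lrt_and_fdr(self._scan_frame([0.0, 1.0]))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_chi2_quantile(self):
        out, _ = lrt_and_fdr(self._scan_frame([3.841, 0.5]))
        assert out["p"].iloc[0] == pytest.approx(0.050, abs=5e-4)

    def test_bh_with_equal_pvalues_calls_all(self):
        lam = 2 * 5.414  # p ~ 0.001
        out, counts = lrt_and_fdr(self._scan_frame([lam] * 100))
        assert out["called"].all()
        np.testing.assert_allclose(out["q"], out["p"], rtol=1e-9)
        assert counts["N2"] == 100

    def test_candidate_correction_controls_null_calls(self):
        """With the candidate-count Bonferroni option, single-optimum data
        yield few shift calls despite the best-node selection."""
        cfg = es.ScenarioConfig(n_species=16, n_genes=60, generator="ou1",
                                seed=21, missing_fraction=0.0)
        tree = es.gen_yule_tree(16, seed=21, normalize_depth=True)
        X, _, _ = es.gen_expression(cfg, tree)
        from exprshift.ou_shift import scan_dataset
        scan = scan_dataset(tree, X)
        naive, _ = lrt_and_fdr(scan, alpha_fdr=0.05)
        corrected, _ = lrt_and_fdr(scan, alpha_fdr=0.05,
                                   correction="candidates")
        assert corrected["called"].mean() <= 0.10
        assert corrected["called"].sum() <= naive["called"].sum()

    def test_counts_sum_to_called(self):
        rng = np.random.default_rng(0)
        lams = rng.chisquare(1, 50)
        lams[:10] += 30
        frame = self._scan_frame(lams)
        frame.loc[frame.index[:25], "best_node"] = "N5"
        out, counts = lrt_and_fdr(frame)
        assert counts.sum() == out["called"].sum()


class TestNodeShiftOutliers:
    def test_single_hotspot_flagged(self):
        counts = pd.Series([0, 0, 0, 0, 100],
                           index=[f"n{i}" for i in range(5)])
        out = node_shift_outliers(counts)
        assert list(out.index[out["outlier"]]) == ["n4"]

    def test_uniform_counts_flag_nothing(self):
        counts = pd.Series([7] * 8, index=[f"n{i}" for i in range(8)])
        out = node_shift_outliers(counts)
        assert not out["outlier"].any()

    def test_two_hotspots_flagged_exactly(self):
        counts = pd.Series([1, 0, 2, 60, 1, 0, 55, 2],
                           index=[f"n{i}" for i in range(8)])
        out = node_shift_outliers(counts)
        assert set(out.index[out["outlier"]]) == {"n3", "n6"}

    def test_needs_five_nodes(self):
        with pytest.raises(ValueError):
            node_shift_outliers(pd.Series([1, 2, 3]))
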