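"""Continuous-trait model fitting, selection, and ancestral reconstruction."""

import numpy as np
import pytest

import phylopower as pp
from phylopower.asr_continuous import (EvolutionModelFit, bm_profile_loglik,
                                       fit_evolution_models,
                                       reconstruct_continuous,
                                       select_and_rescale)
from phylopower.treeio import vcv_matrix


def dense_gls_oracle(tree, x):
    """Independent conditional-mean/variance computation on the full
    node-tip covariance (textbook GLS with estimated root)."""
    labels, V = vcv_matrix(tree)
    Vi = np.linalg.inv(V)
    one = np.ones(len(x))
    mu = (one @ Vi @ x) / (one @ Vi @ one)
    r = x - mu
    s2 = (r @ Vi @ r) / len(x)
    depths = tree.depths()
    tips = tree.tip_indices()
    anc = {int(i): set(tree.ancestors(int(i))) | {int(i)} for i in tips}
    out = {}
    for v in range(tree.n_nodes):
        if v in set(tips.tolist()):
            continue
        vanc = set(tree.ancestors(v)) | {v}
        c = np.array([max(depths[j] for j in (anc[int(i)] & vanc))
                      if (anc[int(i)] & vanc) else 0.0 for i in tips])
        mean = mu + c @ Vi @ r
        var = s2 * ((depths[v] - c @ Vi @ c)
                    + (1 - one @ Vi @ c) ** 2 / (one @ Vi @ one))
        out[v] = (mean, max(var, 0.0))
    return out, s2


class TestReconstruction:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_gls_oracle(self, seed):
        tree = pp.simulate_yule_tree(8, 0.5, seed=seed)
        x = pp.simulate_bm_trait(tree, 0.0, 0.5, seed=seed + 50)
        est = reconstruct_continuous(tree, x)
        oracle, s2 = dense_gls_oracle(tree, x)
        for v, (mean, var) in oracle.items():
            assert est.node_mle[v] == pytest.approx(mean, abs=1e-8)
            width = est.node_ci[v][1] - est.node_ci[v][0]
            assert width == pytest.approx(2 * 1.959964 * np.sqrt(var), abs=1e-6)

    def test_two_tip_closed_form(self):
        tree = pp.parse_newick("(A:1,B:3);")
        est = reconstruct_continuous(tree, np.array([0.0, 4.0]))
        assert est.node_mle[0] == pytest.approx(1.0)

    def test_constant_trait(self):
        tree = pp.simulate_yule_tree(6, 0.5, seed=2)
        est = reconstruct_continuous(tree, np.full(6, 2.5))
        for v in est.nodes():
            assert est.node_mle[v] == pytest.approx(2.5)
            lo, hi = est.node_ci[v]
            assert hi > lo  # degenerate input still yields a defined interval

    def test_root_is_convex_combination_of_tips(self):
        tree = pp.simulate_yule_tree(10, 0.5, seed=3)
        x = pp.simulate_bm_trait(tree, 1.0, 0.3, seed=8)
        est = reconstruct_continuous(tree, x)
        assert x.min() - 1e-9 <= est.node_mle[0] <= x.max() + 1e-9
        # shifting all tips shifts every node identically (affine equivariance)
        est2 = reconstruct_continuous(tree, x + 5.0)
        for v in est.nodes():
            assert est2.node_mle[v] == pytest.approx(est.node_mle[v] + 5.0)

    def test_branch_rescaling_leaves_mles_scales_rate(self):
        tree = pp.simulate_yule_tree(9, 0.5, seed=4)
        x = pp.simulate_bm_trait(tree, 0.0, 0.4, seed=9)
        est = reconstruct_continuous(tree, x)
        c = 2.5
        scaled = pp.PhyloTree(tree.parent.copy(), tree.blen * c, list(tree.label))
        est2 = reconstruct_continuous(scaled, x)
        for v in est.nodes():
            assert est2.node_mle[v] == pytest.approx(est.node_mle[v], abs=1e-9)
        assert est2.sigma2 == pytest.approx(est.sigma2 / c, rel=1e-9)

    def test_back_transform_is_monotone(self):
        tree = pp.simulate_yule_tree(7, 0.5, seed=6)
        x = pp.simulate_bm_trait(tree, 0.1, 0.2, seed=12)
        est = reconstruct_continuous(tree, x)
        nodes = est.nodes()
        order_log = np.argsort([est.node_mle[v] for v in nodes])
        order_ratio = np.argsort([est.ratio_mle(v) for v in nodes])
        assert np.array_equal(order_log, order_ratio)


class TestModelFitting:
    def test_bm_aic_formula(self, default_fixture):
        tree, table, _ = default_fixture
        x = np.log10(table.frame["bmr"].to_numpy())
        fits = fit_evolution_models(tree, x, models=("BM", "lambda"))
        bm = next(f for f in fits if f.model == "BM")
        assert bm.aic == pytest.approx(2 * 2 - 2 * bm.lnL)
        lam = next(f for f in fits if f.model == "lambda")
        assert lam.k == 3 and lam.lrt_p is not None

    def test_ou_limit_reproduces_bm(self, default_fixture):
        tree, table, _ = default_fixture
        x = np.log10(table.frame["bmr"].to_numpy())
        labels, V = vcv_matrix(tree)
        lnL_bm, _, _ = bm_profile_loglik(V, x)
        _, Vou = pp.transform_branch_lengths((labels, V), "OU", 1e-9)
        lnL_ou, _, _ = bm_profile_loglik(Vou, x)
        assert lnL_ou == pytest.approx(lnL_bm, abs=1e-4)

    def test_bm_data_keeps_lambda_high_and_lrt_quiet(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            tree = pp.simulate_yule_tree(40, 0.4, seed=rep)
            x = pp.simulate_bm_trait(tree, 0.0, 0.05, seed=10_000 + rep)
            fits = fit_evolution_models(tree, x, models=("BM", "lambda"))
            lam = next((f for f in fits if f.model == "lambda"), None)
            if lam is not None and lam.lrt_p >= 0.05:
                hits += 1
        assert hits >= 90

    def test_nonconverging_models_are_excluded_not_fatal(self, default_fixture):
        tree, table, _ = default_fixture
        x = np.log10(table.frame["bmr"].to_numpy())
        fits = fit_evolution_models(tree, x)
        assert any(f.model == "BM" for f in fits)
        assert {f.model for f in fits} <= set(pp.asr_continuous.MODELS)


class TestSelection:
    def _fits(self, lnl_bm=-10.0):
        return [EvolutionModelFit("BM", 1.0, 0.0, None, lnl_bm, 2)]

    def test_no_significant_model_returns_tree_unchanged(self):
        tree = pp.simulate_yule_tree(6, 0.5, seed=1)
        fits = self._fits() + [
            EvolutionModelFit("lambda", 1.0, 0.0, 0.7, -9.9, 3, lrt_p=0.6)]
        out = select_and_rescale(fits, tree)
        assert np.array_equal(out.blen[1:], tree.blen[1:])

    def test_winning_neutral_lambda_is_identity(self):
        tree = pp.simulate_yule_tree(6, 0.5, seed=1)
        fits = self._fits() + [
            EvolutionModelFit("lambda", 1.0, 0.0, 1.0, -4.0, 3, lrt_p=0.001)]
        out = select_and_rescale(fits, tree)
        assert np.allclose(out.blen[1:], tree.blen[1:])

    def test_winning_half_lambda_halves_off_diagonals(self):
        tree = pp.simulate_yule_tree(6, 0.5, seed=1)
        fits = self._fits() + [
            EvolutionModelFit("lambda", 1.0, 0.0, 0.5, -4.0, 3, lrt_p=0.001)]
        out = select_and_rescale(fits, tree)
        labels, V = vcv_matrix(tree)
        _, W = vcv_matrix(out, order=labels)
        off = ~np.eye(len(labels), dtype=bool)
        assert np.allclose(W[off], 0.5 * V[off], atol=1e-9)
        assert np.allclose(np.diag(W), np.diag(V), atol=1e-9)

    def test_best_aic_among_significant_wins(self):
        tree = pp.simulate_yule_tree(6, 0.5, seed=1)
        fits = self._fits() + [
            EvolutionModelFit("lambda", 1.0, 0.0, 0.5, -5.0, 3, lrt_p=0.01),
            EvolutionModelFit("delta", 1.0, 0.0, 2.0, -3.0, 3, lrt_p=0.001),
        ]
        out = select_and_rescale(fits, tree)
        expected = pp.transform_branch_lengths(tree, "delta", 2.0)
        assert np.allclose(out.blen[1:], expected.blen[1:])
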