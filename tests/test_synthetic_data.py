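"""Generators: Yule trees, Brownian traits, phylogenetic binary labels."""

import numpy as np
import pytest
from scipy.special import expit

import phylopower as pp
from phylopower.synthetic_data import (SimulationConfig,
                                       implied_label_correlation,
                                       make_fixture, simulate_binary_power,
                                       simulate_bm_trait, simulate_yule_tree)


class TestYule:
    def test_tip_count_and_ultrametricity(self):
        t = simulate_yule_tree(79, 0.2, seed=0)
        assert t.n_tips == 79
        assert t.is_ultrametric(1e-9)

    def test_same_seed_same_newick(self):
        a = pp.write_newick(simulate_yule_tree(20, 0.3, seed=5))
        b = pp.write_newick(simulate_yule_tree(20, 0.3, seed=5))
        assert a == b
        c = pp.write_newick(simulate_yule_tree(20, 0.3, seed=6))
        assert a != c

    def test_faster_birth_means_shallower_trees(self):
        # with n fixed, the expected tree height shrinks as the rate grows
        h_slow = np.mean([simulate_yule_tree(12, 0.2, seed=s).height()
                          for s in range(200)])
        h_fast = np.mean([simulate_yule_tree(12, 0.8, seed=s).height()
                          for s in range(200)])
        assert h_fast < h_slow


class TestBrownian:
    def test_zero_rate_returns_root_value(self):
        t = simulate_yule_tree(8, 0.5, seed=1)
        x = simulate_bm_trait(t, 3.14, 0.0, seed=2)
        assert np.allclose(x, 3.14)

    def test_tip_covariance_matches_shared_path(self):
        t = pp.parse_newick("((A:1,B:1):2,C:3);")
        sims = np.array([simulate_bm_trait(t, 0.0, 1.0, seed=s)
                         for s in range(2000)])
        cov_ab = np.cov(sims[:, 0], sims[:, 1])[0, 1]
        # Var of a normal sample covariance: (var_a var_b + cov^2) / n
        se_ab = np.sqrt((3.0 * 3.0 + 2.0 ** 2) / 2000)
        assert abs(cov_ab - 2.0) < 3 * se_ab
        cov_ac = np.cov(sims[:, 0], sims[:, 2])[0, 1]
        se_ac = np.sqrt(3.0 * 3.0 / 2000)
        assert abs(cov_ac) < 3 * se_ac

    def test_clade_offset_raises_clade_mean(self):
        t = simulate_yule_tree(12, 0.5, seed=3)
        clade = tuple(t.tip_labels[:4])
        node = t.mrca(list(clade))
        members = [lab for i, lab in zip(t.tip_indices(), t.tip_labels)
                   if node in (t.ancestors(int(i)) + [int(i)])]
        sims = np.array([simulate_bm_trait(t, 0.0, 0.01, seed=s,
                                           shifts={clade: 0.3})
                         for s in range(400)])
        idx = [t.tip_labels.index(m) for m in members]
        rest = [i for i in range(12) if i not in idx]
        gap = sims[:, idx].mean() - sims[:, rest].mean()
        assert gap == pytest.approx(0.3, abs=0.06)


class TestBinaryLabels:
    def test_iid_limit_on_star_tree(self):
        n = 5000
        star = pp.parse_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")
        y = simulate_binary_power(star, np.zeros(n), b0=0.4, b1=0.0,
                                  signal=0.0, seed=9)
        p = expit(0.4)
        assert abs(y.mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_balanced_null_near_half(self):
        n = 4000
        star = pp.parse_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")
        y = simulate_binary_power(star, np.zeros(n), 0.0, 0.0, 0.0, seed=3)
        assert abs(y.mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_sister_concordance_increases_with_signal(self):
        t = simulate_yule_tree(30, 0.5, seed=7)
        x = simulate_bm_trait(t, 0.0, 0.05, seed=8)
        conc = []
        for signal in (0.0, 0.5, 0.95):
            agree = total = 0
            for s in range(300):
                y = simulate_binary_power(t, x, 0.0, 1.0, signal, seed=1000 + s)
                lab = dict(zip(t.tip_labels, y))
                for i in t.tip_indices():
                    sibs = t.children(t.parent[i])
                    for j in sibs:
                        if j != i and j in set(t.tip_indices().tolist()):
                            agree += lab[t.label[i]] == lab[t.label[j]]
                            total += 1
            conc.append(agree / total)
        assert conc[0] < conc[1] < conc[2]

    def test_marginals_follow_logistic_mean(self):
        t = simulate_yule_tree(25, 0.4, seed=11)
        x = np.linspace(-2, 2, 25)
        sims = np.array([simulate_binary_power(t, x, 0.3, 1.2, 0.6, seed=s)
                         for s in range(3000)])
        freq = sims.mean(axis=0)
        p = expit(0.3 + 1.2 * x)
        se = np.sqrt(p * (1 - p) / 3000)
        assert np.all(np.abs(freq - p) < 4 * se)

    def test_implied_correlation_matches_simulation(self):
        t = simulate_yule_tree(10, 0.5, seed=13)
        x = simulate_bm_trait(t, 0.0, 0.03, seed=14)
        C = implied_label_correlation(t, x, 0.2, 1.0, signal=0.7)
        sims = np.array([simulate_binary_power(t, x, 0.2, 1.0, 0.7, seed=s)
                         for s in range(4000)])
        emp = np.corrcoef(sims.T)
        iu = np.triu_indices(10, 1)
        assert np.abs(C[iu] - emp[iu]).max() < 0.08


class TestFixture:
    def test_fixture_structure(self, default_fixture):
        tree, table, clades = default_fixture
        assert tree.n_tips == 79 and len(table) == 79
        assert table.frame["bmr"].notna().all()
        tars = table.frame["species"].str.startswith("Tarsius_")
        assert table.frame.loc[tars, ["cr", "sr"]].isna().all().all()
        assert table.frame.loc[~tars, ["cr", "sr"]].notna().all().all()
        for name, members in clades.items():
            assert set(members) <= set(tree.tip_labels), name
        assert len(clades) == 10

    def test_fixed_seed_byte_identical(self):
        a = make_fixture(SimulationConfig(seed=4))
        b = make_fixture(SimulationConfig(seed=4))
        assert pp.write_newick(a[0]) == pp.write_newick(b[0])
        assert a[1].frame.equals(b[1].frame)
        assert a[2] == b[2]

    def test_clade_backbone_ages(self, default_fixture):
        tree, _, clades = default_fixture
        ages = tree.node_ages()
        assert ages[tree.mrca(clades["Primates"])] == pytest.approx(74.0, abs=1e-6)
        assert ages[tree.mrca(clades["Catarrhini"])] == pytest.approx(29.0, abs=1e-6)

    def test_pipeline_recovers_slope_signs(self, default_fixture):
        # end-to-end: the generating dependence (labels rise with dimorphism,
        # fall with sex ratio) is recovered for all three ASR predictors
        tree, table, _ = default_fixture
        y = (table.frame["power"] == "MD").astype(float).to_numpy()
        signs = {}
        for pred, expected in [("bmr", 1), ("cr", 1), ("sr", -1)]:
            sub = table.predictor(pred)
            ptree = pp.prune_to_taxa(tree, list(sub["species"]))
            order = ptree.tip_labels
            sub = sub.set_index("species").loc[order].reset_index()
            yy = (sub["power"] == "MD").astype(float).to_numpy()
            z, _ = pp.log10_standardize(sub[pred].to_numpy())
            fit = pp.fit_phylogistic(yy, z, pp.vcv_matrix(ptree)[1])
            signs[pred] = np.sign(fit.b1) == expected
        assert all(signs.values()), signs
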