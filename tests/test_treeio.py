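"""Tree parsing, pruning, grafting, covariance, and transforms."""

import numpy as np
import pytest

import phylopower as pp
from phylopower.treeio import TreeError, _transform_vcv

from conftest import brute_force_patristic, random_tree


class TestNewick:
    def test_minimal_tree(self):
        t = pp.parse_newick("(A:1,B:1);")
        assert sorted(t.tip_labels) == ["A", "B"]
        tips = t.tip_indices()
        assert np.allclose(t.blen[tips], 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip(self, seed):
        t = random_tree(seed)
        assert pp.parse_newick(pp.write_newick(t)) == t

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError, match="[Dd]uplicate|[Mm]ultiple"):
            pp.parse_newick("(A:1,A:2);")

    def test_malformed_string_rejected(self):
        with pytest.raises(TreeError):
            pp.parse_newick("((A:1,B:1;")

    def test_zero_branch_warns(self):
        with pytest.warns(UserWarning, match="zero-length"):
            pp.parse_newick("(A:0,B:1);")


class TestPrune:
    def test_path_preserved_minimal(self, small_tree):
        p = pp.prune_to_taxa(small_tree, {"A", "C"})
        assert sorted(p.tip_labels) == ["A", "C"]
        assert p.patristic_distance("A", "C") == pytest.approx(4.0)
        assert p.depths()[p.tip_indices()].max() == pytest.approx(2.0)

    def test_keep_all_is_identity(self, small_tree):
        assert pp.prune_to_taxa(small_tree, set(small_tree.tip_labels)) == small_tree

    @pytest.mark.parametrize("seed", range(5))
    def test_patristic_distances_preserved(self, seed):
        t = random_tree(seed, n=10)
        rng = np.random.default_rng(seed)
        keep = list(rng.choice(t.tip_labels, size=6, replace=False))
        p = pp.prune_to_taxa(t, keep)
        before = brute_force_patristic(t)
        after = brute_force_patristic(p)
        for pair, d in after.items():
            assert d == pytest.approx(before[pair], abs=1e-9)

    def test_unknown_label_listed(self, small_tree):
        with pytest.raises(TreeError, match="ZZZ"):
            pp.prune_to_taxa(small_tree, {"A", "ZZZ"})


class TestGraft:
    HOST = "((A:60,B:60):10,C:70);"

    def test_younger_fossil_gets_buffered_branch(self):
        t = pp.parse_newick(self.HOST)
        g = pp.graft_taxon(t, pp.FossilRecord("F", "A", 47.0, 56.0))
        assert g.blen[g.index_of("F")] == pytest.approx(10.0)

    def test_older_fossil_gets_one_my_branch(self):
        t = pp.parse_newick(self.HOST)
        g = pp.graft_taxon(t, pp.FossilRecord("F", "A", 58.0, 56.0))
        assert g.blen[g.index_of("F")] == pytest.approx(1.0)

    def test_prune_round_trip(self):
        t = pp.parse_newick(self.HOST)
        g = pp.graft_taxon(t, pp.FossilRecord("F", "A", 47.0, 56.0))
        assert pp.prune_to_taxa(g, ["A", "B", "C"]) == t

    def test_original_paths_unchanged(self):
        t = pp.parse_newick(self.HOST)
        g = pp.graft_taxon(t, pp.FossilRecord("F", "B", 30.0, 40.0))
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert g.patristic_distance(a, b) == pytest.approx(
                t.patristic_distance(a, b))

    def test_divergence_off_edge_rejected(self):
        t = pp.parse_newick(self.HOST)
        with pytest.raises(TreeError, match="divergence age"):
            pp.graft_taxon(t, pp.FossilRecord("F", "A", 47.0, 65.0))


class TestVcv:
    def test_star_no_shared_path(self):
        labels, V = pp.vcv_matrix(pp.parse_newick("(A:2,B:2);"))
        assert np.allclose(V, 2 * np.eye(2))

    def test_three_tip(self, small_tree):
        labels, V = pp.vcv_matrix(small_tree, order=["A", "B", "C"])
        expected = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]], dtype=float)
        assert np.allclose(V, expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_shared_path_oracle(self, seed):
        t = random_tree(seed, n=8)
        labels, V = pp.vcv_matrix(t)
        depths = t.depths()
        tips = {lab: int(i) for i, lab in zip(t.tip_indices(), labels)}
        dists = brute_force_patristic(t)
        for a, la in enumerate(labels):
            assert V[a, a] == pytest.approx(depths[tips[la]])
            for b in range(a + 1, len(labels)):
                lb = labels[b]
                shared = 0.5 * (depths[tips[la]] + depths[tips[lb]]
                                - dists[frozenset((la, lb))])
                assert V[a, b] == pytest.approx(shared, abs=1e-9)

    def test_ultrametric_constant_diagonal(self):
        t = random_tree(3, n=12)
        _, V = pp.vcv_matrix(t)
        assert np.allclose(np.diag(V), t.height())


class TestTransforms:
    NEUTRAL = [("lambda", 1.0), ("kappa", 1.0), ("delta", 1.0),
               ("OU", 0.0), ("EB", 0.0)]

    @pytest.mark.parametrize("model,param", NEUTRAL)
    def test_neutral_is_identity_on_tree(self, model, param):
        t = random_tree(1, n=8)
        out = pp.transform_branch_lengths(t, model, param)
        assert np.array_equal(out.blen[1:], t.blen[1:])
        assert np.array_equal(out.parent, t.parent)

    @pytest.mark.parametrize("model,param",
                             [(m, p) for m, p in NEUTRAL if m != "kappa"])
    def test_neutral_is_identity_on_vcv(self, model, param):
        t = random_tree(1, n=8)
        labels, V = pp.vcv_matrix(t)
        _, W = pp.transform_branch_lengths((labels, V), model, param)
        assert np.array_equal(W, V)

    def test_lambda_zero_gives_star_covariance(self):
        t = random_tree(2, n=6)
        labels, V = pp.vcv_matrix(t)
        _, W = pp.transform_branch_lengths((labels, V), "lambda", 0.0)
        assert np.allclose(W - np.diag(np.diag(W)), 0.0)
        assert np.allclose(np.diag(W), np.diag(V))

    def test_ou_limit_recovers_bm(self):
        # unit-height tree so the O(alpha * T^2) deviation stays tiny
        t = pp.parse_newick("((A:0.5,B:0.5):0.5,(C:0.7,D:0.7):0.3);")
        labels, V = pp.vcv_matrix(t)
        _, W = pp.transform_branch_lengths((labels, V), "OU", 1e-8)
        assert np.abs(W - V).max() < 1e-6
        t2 = pp.transform_branch_lengths(t, "OU", 1e-8)
        assert np.abs(t2.blen[1:] - t.blen[1:]).max() < 1e-6

    def test_tree_and_vcv_transforms_agree(self):
        t = random_tree(4, n=7)
        labels, V = pp.vcv_matrix(t)
        for model, param in [("lambda", 0.4), ("delta", 1.7), ("EB", -0.5),
                             ("OU", 0.8)]:
            t2 = pp.transform_branch_lengths(t, model, param)
            _, Vt = pp.vcv_matrix(t2, order=labels)
            _, Vd = pp.transform_branch_lengths((labels, V), model, param)
            assert np.allclose(Vt, Vd, atol=1e-9), model

    def test_kappa_powers_branch_lengths(self):
        t = random_tree(5, n=6)
        t2 = pp.transform_branch_lengths(t, "kappa", 0.5)
        assert np.allclose(t2.blen[1:], np.sqrt(t.blen[1:]))

    @pytest.mark.parametrize("model,bad", [("lambda", 1.5), ("lambda", -0.1),
                                           ("kappa", -1.0), ("delta", 0.0),
                                           ("OU", -0.5), ("EB", 0.5)])
    def test_out_of_range_parameter_rejected(self, model, bad):
        t = random_tree(0, n=5)
        with pytest.raises(TreeError, match="range"):
            pp.transform_branch_lengths(t, model, bad)

    def test_kappa_on_vcv_rejected(self):
        t = random_tree(0, n=5)
        with pytest.raises(TreeError, match="kappa"):
            pp.transform_branch_lengths(pp.vcv_matrix(t), "kappa", 0.5)
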