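import dendropy
import numpy as np
import pytest

from oracles import clade_frequencies_brute
from parabias.synthetic_data import SimConfig, simulate_tree
from parabias.tree_tools import (
    VCVMatrix,
    add_sister_tips,
    lambda_scale,
    majority_consensus,
    prune_and_align,
    resolve_polytomies,
    vcv_from_tree,
)


def newick(s):
    t = dendropy.Tree.get(data=s, schema="newick")
    t.is_rooted = True
    return t


class TestConsensus:
    def test_unanimous_trees_reproduce_topology_and_lengths(self, three_tip_tree):
        cons = majority_consensus([three_tip_tree.clone(depth=1) for _ in range(3)])
        v0 = vcv_from_tree(three_tip_tree)
        vc = vcv_from_tree(cons).submatrix(v0.labels)
        assert np.abs(vc.C - v0.C).max() < 1e-12

    def test_majority_clade_retained_minority_collapsed(self):
        # clade (A,B) in 6/10 trees, (B,C) in 4/10
        t_ab = "(((A:1,B:1):1,C:2):1,D:3);"
        t_bc = "(((B:1,C:1):1,A:2):1,D:3);"
        trees = [newick(t_ab) for _ in range(6)] + [newick(t_bc) for _ in range(4)]
        cons = majority_consensus(trees)
        clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in cons.preorder_internal_node_iter()
        }
        assert frozenset("AB") in clades
        assert frozenset("BC") not in clades

    def test_exactly_half_not_retained(self):
        trees = [newick("(((A:1,B:1):1,C:2):1,D:3);") for _ in range(2)]
        trees += [newick("(((B:1,C:1):1,A:2):1,D:3);") for _ in range(2)]
        cons = majority_consensus(trees, threshold=0.5)
        clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in cons.preorder_internal_node_iter()
        }
        # each 3-tip resolution appears in exactly half the trees: star result
        assert frozenset("AB") not in clades and frozenset("BC") not in clades

    def test_three_incompatible_resolutions_give_star(self):
        trees = [
            newick("((A:1,B:1):1,C:2);"),
            newick("((A:1,C:1):1,B:2);"),
            newick("((B:1,C:1):1,A:2);"),
        ]
        cons = majority_consensus(trees)
        assert len(cons.seed_node.child_nodes()) == 3

    def test_consensus_branch_length_is_mean_over_supporting_trees(self):
        trees = [
            newick("((A:1,B:1):1,C:2);"),
            newick("((A:1,B:1):2,C:3);"),
            newick("((A:1,B:1):3,C:4);"),
        ]
        cons = majority_consensus(trees)
        ab = next(
            n for n in cons.preorder_internal_node_iter()
            if {l.taxon.label for l in n.leaf_iter()} == {"A", "B"}
        )
        assert ab.edge.length == pytest.approx(2.0)
        c_tip = next(l for l in cons.leaf_node_iter() if l.taxon.label == "C")
        assert c_tip.edge.length == pytest.approx(3.0)

    def test_all_consensus_clades_are_majority_by_brute_force(self):
        # random 6-tip tree sets; every consensus clade must occur in > 50%
        rng = np.random.default_rng(3)
        for rep in range(3):
            trees = [
                simulate_tree(SimConfig(seed=int(rng.integers(1e6)), n_species=6))
                for _ in range(5)
            ]
            cons = majority_consensus(trees)
            freqs = clade_frequencies_brute(trees)
            tips = {l.taxon.label for l in cons.leaf_node_iter()}
            for node in cons.preorder_internal_node_iter():
                clade = frozenset(l.taxon.label for l in node.leaf_iter())
                if clade == tips:
                    continue
                assert freqs[clade] > 0.5
            # and conversely every majority clade is in the consensus
            cons_clades = {
                frozenset(l.taxon.label for l in n.leaf_iter())
                for n in cons.preorder_internal_node_iter()
            }
            for clade, f in freqs.items():
                if f > 0.5:
                    assert clade in cons_clades

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus([])


class TestResolvePolytomies:
    def test_binary_tree_unchanged(self, three_tip_tree):
        out = resolve_polytomies(three_tip_tree, seed=1)
        v0 = vcv_from_tree(three_tip_tree)
        v1 = vcv_from_tree(out).submatrix(v0.labels)
        assert np.abs(v1.C - v0.C).max() == 0.0

    def test_trifurcation_resolved_with_epsilon_branch(self):
        t = newick("(A:1,B:1,C:1);")
        out = resolve_polytomies(t, seed=1)
        assert all(len(n.child_nodes()) <= 2 for n in out.preorder_internal_node_iter())
        v = vcv_from_tree(out)
        assert np.abs(np.diag(v.C) - 1.0).max() <= 1e-8 + 1e-15

    def test_determinism_and_seed_sensitivity(self):
        t = newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        s1 = resolve_polytomies(t, seed=7).as_string(schema="newick")
        s2 = resolve_polytomies(t, seed=7).as_string(schema="newick")
        assert s1 == s2

    def test_path_length_perturbation_bound(self):
        t = newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")
        out = resolve_polytomies(t, seed=3, epsilon=1e-8)
        n_new = sum(1 for _ in out.preorder_internal_node_iter()) - sum(
            1 for _ in t.preorder_internal_node_iter()
        )
        v = vcv_from_tree(out)
        assert np.abs(np.diag(v.C) - 1.0).max() <= n_new * 1e-8 + 1e-15
        assert sorted(v.labels) == list("ABCDEFGH")


class TestSisterTips:
    def test_vcv_of_edited_tree(self):
        t = newick("((A:1,B:1):1,C:2);")
        out = add_sister_tips(t, "A", k=2, seed=1)
        v = vcv_from_tree(out)
        i, j = v.index_of("A#1"), v.index_of("A#2")
        assert v.C[i, i] == pytest.approx(2.0, abs=1e-7)
        assert v.C[i, j] == pytest.approx(1.0, abs=1e-7)

    def test_original_label_replaced_by_k_new(self):
        t = newick("((A:1,B:1):1,C:2);")
        out = add_sister_tips(t, "A", k=3, seed=1)
        labels = {l.taxon.label for l in out.leaf_node_iter()}
        assert labels == {"A#1", "A#2", "A#3", "B", "C"}
        assert all(len(n.child_nodes()) <= 2 for n in out.preorder_internal_node_iter())

    def test_unknown_species_rejected(self, three_tip_tree):
        with pytest.raises(KeyError):
            add_sister_tips(three_tip_tree, "Z", k=2)


class TestVCV:
    def test_hand_computed_shared_paths(self, three_tip_tree):
        v = vcv_from_tree(three_tip_tree)
        a, b, c = v.index_of("A"), v.index_of("B"), v.index_of("C")
        assert v.C[a, a] == 2 and v.C[a, b] == 1 and v.C[a, c] == 0 and v.C[c, c] == 2

    def test_correlation_scale(self, three_tip_tree):
        v = vcv_from_tree(three_tip_tree, scale="correlation")
        a, b = v.index_of("A"), v.index_of("B")
        assert np.allclose(np.diag(v.C), 1.0)
        assert v.C[a, b] == pytest.approx(0.5)

    def test_star_tree_identity_under_correlation(self):
        v = vcv_from_tree(newick("(A:1,B:1,C:1,D:1);"), scale="correlation")
        assert np.abs(v.C - np.eye(4)).max() == 0.0

    def test_symmetric_psd_ultrametric_diag(self, tree20):
        v = vcv_from_tree(tree20)
        assert np.allclose(v.C, v.C.T)
        assert np.allclose(np.diag(v.C), 1.0)  # depth normalized to 1
        assert np.linalg.eigvalsh(v.C).min() > -1e-10
        assert (np.diag(v.C)[:, None] >= v.C - 1e-12).all()

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            vcv_from_tree(newick("((A:1,B:-0.5):1,C:2);"))


class TestLambdaScale:
    def test_identity_and_star_limits(self, tree20):
        C = vcv_from_tree(tree20).C
        assert np.abs(lambda_scale(C, 1.0) - C).max() == 0.0
        assert np.abs(lambda_scale(C, 0.0) - np.diag(np.diag(C))).max() == 0.0

    def test_halving_off_diagonal(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = lambda_scale(C, 0.5)
        assert out[0, 1] == 0.25 and out[0, 0] == 1.0

    def test_composition_multiplies(self, tree20):
        C = vcv_from_tree(tree20).C
        ab = lambda_scale(lambda_scale(C, 0.6), 0.5)
        direct = lambda_scale(C, 0.3)
        assert np.abs(ab - direct).max() < 1e-14

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lambda_scale(np.eye(2), 1.5)


class TestPrune:
    def test_submatrix_identity(self, tree20):
        full = vcv_from_tree(tree20)
        subset = full.labels[2:9]
        pruned, imap = prune_and_align(tree20, subset)
        sub = vcv_from_tree(pruned)
        order = [imap[s.casefold()] for s in subset]
        assert np.abs(sub.C[np.ix_(order, order)] - full.submatrix(subset).C).max() < 1e-10

    def test_prune_to_all_tips_is_noop(self, tree20):
        full = vcv_from_tree(tree20)
        pruned, _ = prune_and_align(tree20, full.labels)
        assert np.abs(vcv_from_tree(pruned).submatrix(full.labels).C - full.C).max() < 1e-12

    def test_two_tip_prune_preserves_root_to_tip(self, three_tip_tree):
        pruned, _ = prune_and_align(three_tip_tree, ["A", "B"])
        v = vcv_from_tree(pruned)
        assert np.allclose(np.diag(v.C), 2.0)

    def test_missing_species_listed(self, three_tip_tree):
        with pytest.raises(KeyError, match="Z"):
            prune_and_align(three_tip_tree, ["A", "Z"])
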