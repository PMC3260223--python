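import itertools

import numpy as np
import pandas as pd
import pytest

import epiforest as ef
from epiforest.interaction import InteractionConfig


def brute_force_pair_counts(forest, count_scope="branch"):
    """Independent oracle: recount pair co-occurrences by walking the
    serialized forest node by node in pure Python."""
    counts = {}
    d = forest.to_json()
    for tree in d["trees"]:
        la, lb = tree["feature_a"], tree["feature_b"]
        cl, cr, leafc = tree["children_left"], tree["children_right"], tree["leaf_class"]
        tree_combos = set()

        def walk(node, path):
            if leafc[node] >= 0:
                for pair in itertools.combinations(sorted(set(path)), 2):
                    if count_scope == "tree":
                        tree_combos.add(pair)
                    else:
                        counts[pair] = counts.get(pair, 0) + 1
                return
            snps = [la[node]] + ([lb[node]] if lb[node] >= 0 else [])
            walk(cl[node], path + snps)
            walk(cr[node], path + snps)

        walk(0, [])
        for pair in tree_combos:
            counts[pair] = counts.get(pair, 0) + 1
    return counts


class TestBranchSets:
    def test_depth1_pair_tree(self, xor_data):
        X, y = xor_data
        est = ef.EpistasisForest(n_trees=1, mtry=6, min_node_size=2,
                                 random_state=0).fit(X, y)
        # replace rng-built forest with a deterministic XOR tree
        est.trees_ = [ef.grow_tree(np.random.default_rng(0), X, y,
                                   mtry=ef.n_candidate_variables(3), min_node_size=2)]
        branches = ef.branch_snp_sets(est)
        assert len(branches[0]) == 2
        for b in branches[0]:
            assert b.tolist() == [0, 1]

    def test_leaf_only_tree_contributes_nothing(self):
        X = np.random.default_rng(0).integers(0, 3, (10, 4)).astype(np.int8)
        y = np.zeros(10, dtype=np.int8)
        y[0] = 1
        est = ef.EpistasisForest(n_trees=1, mtry=1, min_node_size=100,
                                 random_state=0).fit(X, y)
        branches = ef.branch_snp_sets(est)
        assert [b.size for b in branches[0]] == [0]
        assert ef.raw_interaction_scores(est, 2) == {}

    def test_repeated_snp_counted_once_per_branch(self, small_forest):
        """A SNP in several nodes of one path enters the branch set once."""
        for tree_branches in ef.branch_snp_sets(small_forest):
            for b in tree_branches:
                assert len(set(b.tolist())) == b.size


class TestRawScores:
    @pytest.mark.parametrize("count_scope", ["tree", "branch"])
    def test_matches_bruteforce_recount(self, small_forest, count_scope):
        ours = ef.raw_interaction_scores(small_forest, 2, count_scope=count_scope)
        oracle = brute_force_pair_counts(small_forest, count_scope=count_scope)
        assert ours == oracle

    def test_conservation_of_pair_mass(self, small_forest):
        """Per-branch counting: sum_G inter(G) over pairs equals the sum over
        branches of C(|set|, 2), exactly."""
        total = sum(
            ef.raw_interaction_scores(small_forest, 2, count_scope="branch").values()
        )
        expected = sum(
            b.size * (b.size - 1) // 2
            for tree in ef.branch_snp_sets(small_forest)
            for b in tree
        )
        assert total == expected

    def test_tree_counts_bounded_by_branch_counts(self, small_forest):
        """Per-tree counts never exceed per-branch counts or the tree count."""
        per_tree = ef.raw_interaction_scores(small_forest, 2, count_scope="tree")
        per_branch = ef.raw_interaction_scores(small_forest, 2, count_scope="branch")
        assert set(per_tree) == set(per_branch)
        for combo, c in per_tree.items():
            assert c <= per_branch[combo]
            assert c <= len(small_forest.trees_)

    def test_triples_counted(self, small_forest):
        triples = ef.raw_interaction_scores(small_forest, 3)
        for combo, count in triples.items():
            assert len(combo) == 3 and count >= 1


class TestRandomization:
    def test_label_multiset_and_topology_preserved(self, small_forest):
        before = []
        for t in small_forest.trees_:
            internal = t.leaf_class < 0
            before.append((t.children_left.copy(), t.children_right.copy(),
                           t.left_mask.copy()))
        all_before = np.concatenate([
            np.concatenate([t.feature_a[t.leaf_class < 0],
                            t.feature_b[(t.leaf_class < 0) & (t.feature_b >= 0)]])
            for t in small_forest.trees_
        ])
        labels = ef.randomize_forest_labels(small_forest, np.random.default_rng(0))
        all_after = np.concatenate([
            np.concatenate([la[t.leaf_class < 0],
                            lb[(t.leaf_class < 0) & (t.feature_b >= 0)]])
            for t, (la, lb) in zip(small_forest.trees_, labels)
        ])
        assert sorted(all_before.tolist()) == sorted(all_after.tolist())
        for t, (cl, cr, mask) in zip(small_forest.trees_, before):
            np.testing.assert_array_equal(t.children_left, cl)
            np.testing.assert_array_equal(t.children_right, cr)
            np.testing.assert_array_equal(t.left_mask, mask)

    def test_single_slot_forest_relabeling_is_identity(self, xor_data):
        """A forest with one single-SNP split node has one label slot, so
        every relabeling is the identity."""
        X, y = xor_data
        est = ef.EpistasisForest(n_trees=1, mtry=3, min_node_size=2, random_state=0)
        est.fit(X, y)
        # replace with a deterministic one-node tree splitting on SNP 0
        tree = est.trees_[0]
        est.trees_ = [ef.Tree(
            feature_a=np.array([0, -1, -1], np.int32),
            feature_b=np.array([-1, -1, -1], np.int32),
            left_mask=np.array([1, 0, 0], np.int64),
            children_left=np.array([1, -1, -1], np.int32),
            children_right=np.array([2, -1, -1], np.int32),
            leaf_class=np.array([-1, 0, 1], np.int8),
            n0=np.array([4, 2, 2], np.int64),
            n1=np.array([4, 2, 2], np.int64),
            decrease=np.zeros(3),
        )]
        for seed in range(5):
            (la, lb), = ef.randomize_forest_labels(est, np.random.default_rng(seed))
            assert la[0] == 0 and lb[0] == -1

    def test_per_tree_scope_stays_within_trees(self, small_forest):
        labels = ef.randomize_forest_labels(small_forest, np.random.default_rng(1),
                                            scope="tree")
        for t, (la, lb) in zip(small_forest.trees_, labels):
            internal = t.leaf_class < 0
            orig = np.concatenate([t.feature_a[internal],
                                   t.feature_b[internal & (t.feature_b >= 0)]])
            new = np.concatenate([la[internal], lb[internal & (t.feature_b >= 0)]])
            assert sorted(orig.tolist()) == sorted(new.tolist())


class TestNormalizedScores:
    def test_centering_and_threshold_semantics(self):
        cfg = InteractionConfig(threshold_sigma=25.0, sd_floor=1.0)
        table = pd.DataFrame({
            "snps": [(0, 1), (2, 3)],
            "combo_size": 2,
            "raw": [30, 5],
            "baseline_mean": [5.0, 5.0],
            "baseline_sd": [1.0, 1.0],
            "normalized": [25.0, 0.0],
            "called": [False, False],
        })
        called = ef.call_interactions(table, cfg)
        assert len(called) == 0  # exactly 25 sigma is NOT above threshold

    def test_descending_order_and_strict_threshold(self):
        cfg = InteractionConfig()
        table = pd.DataFrame({
            "snps": [(0, 1), (2, 3), (4, 5)],
            "combo_size": 2,
            "raw": [40, 35, 20],
            "baseline_mean": [0.0] * 3,
            "baseline_sd": [1.0] * 3,
            "normalized": [27.0, 30.0, 15.0],
            "called": [True, True, False],
        })
        called = ef.call_interactions(table, cfg)
        assert list(called["normalized"]) == [30.0, 27.0]

    def test_empty_table(self):
        table = pd.DataFrame(columns=["snps", "combo_size", "raw", "baseline_mean",
                                      "baseline_sd", "normalized", "called"])
        assert len(ef.call_interactions(table)) == 0

    def test_raw_equals_baseline_gives_zero(self, small_forest):
        tab = ef.normalized_scores(
            small_forest, InteractionConfig(n_randomizations=20), random_state=0)
        close = tab[np.isclose(tab["raw"], tab["baseline_mean"])]
        if len(close):
            assert np.allclose(close["normalized"], 0.0)

    def test_sd_floor_applied(self, small_forest):
        tab = ef.normalized_scores(
            small_forest, InteractionConfig(n_randomizations=10), random_state=0)
        assert (tab["baseline_sd"] >= 1.0).all()

    def test_too_few_randomizations_rejected(self):
        with pytest.raises(ValueError):
            InteractionConfig(n_randomizations=1)

    def test_null_forest_scores_center_near_zero(self, small_forest, epistasis_dataset):
        """With the observed forest's labels themselves pre-randomized, its
        combinations' normalized scores have mean ~ 0."""
        nulled = ef.EpistasisForest.from_json(small_forest.to_json())
        labels = ef.randomize_forest_labels(nulled, np.random.default_rng(123))
        for t, (la, lb) in zip(nulled.trees_, labels):
            t.feature_a, t.feature_b = la, lb
        tab = ef.normalized_scores(nulled, InteractionConfig(n_randomizations=100),
                                   random_state=7)
        assert abs(tab["normalized"].mean()) < 0.5

    def test_deterministic_given_seed(self, small_forest):
        cfg = InteractionConfig(n_randomizations=10)
        a = ef.normalized_scores(small_forest, cfg, random_state=4)
        b = ef.normalized_scores(small_forest, cfg, random_state=4)
        pd.testing.assert_frame_equal(a, b)


def test_triple_suppresses_weaker_subpairs():
    cfg = InteractionConfig(combo_sizes=(2, 3))
    table = pd.DataFrame({
        "snps": [(0, 1, 2), (0, 1), (3, 4)],
        "combo_size": [3, 2, 2],
        "raw": [50, 45, 40],
        "baseline_mean": [0.0] * 3,
        "baseline_sd": [1.0] * 3,
        "normalized": [40.0, 30.0, 28.0],
        "called": [True, True, True],
    })
    called = ef.call_interactions(table, cfg)
    assert list(called["snps"]) == [(0, 1, 2), (3, 4)]
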