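"""kNN, CV, feature filters, PAM, complete linkage, and partition scores."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from bandsim.band_counts import ExpressionMatrix
from bandsim.eval_suite import (
    DistanceSpec,
    LabeledData,
    adjusted_rand_index,
    bw_select,
    choose_k,
    classical_dissimilarity,
    clustering_error,
    complete_linkage_tree,
    cross_dissimilarity,
    cv_error,
    knn_classify,
    pam_cluster,
    tree_to_newick,
    variance_select,
)


def labeled(X, labels):
    return LabeledData(X=ExpressionMatrix(np.asarray(X, dtype=float)),
                       labels=tuple(labels))


class TestClassicalDistances:
    def test_point_pair_values(self):
        A = np.array([[0.0, 0.0]])
        B = np.array([[3.0, 4.0]])
        assert cross_dissimilarity(np.vstack([A, B]), A, DistanceSpec.euclidean())[0, 1] == 5
        assert cross_dissimilarity(np.vstack([A, B]), A, DistanceSpec.manhattan())[0, 1] == 7
        d = cross_dissimilarity(np.vstack([A, B]), A, DistanceSpec.minkowski(0.5))[0, 1]
        assert d == pytest.approx((np.sqrt(3) + np.sqrt(4)) ** 2)

    def test_minkowski_matches_euclidean_and_manhattan(self, rng):
        X = rng.standard_normal((6, 4))
        for p, ref in [(2.0, DistanceSpec.euclidean()), (1.0, DistanceSpec.manhattan())]:
            np.testing.assert_allclose(
                classical_dissimilarity(X, DistanceSpec.minkowski(p)).values,
                classical_dissimilarity(X, ref).values,
                atol=1e-10,
            )

    def test_pearson_distance(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]])
        D = classical_dissimilarity(X, DistanceSpec.pearson()).values
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)  # perfectly linearly related
        assert D[0, 2] == pytest.approx(2.0, abs=1e-12)  # perfectly anti-related

    def test_pearson_zero_variance_rejected(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            classical_dissimilarity(X, DistanceSpec.pearson())

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            DistanceSpec.minkowski(0.0)
        with pytest.raises(ValueError):
            DistanceSpec("band")


class TestChooseK:
    @pytest.mark.parametrize("n,k", [(200, 13), (9, 3), (4, 1), (1, 1), (3, 1), (180, 13)])
    def test_rule(self, n, k):
        assert choose_k(n) == k

    def test_invalid(self):
        with pytest.raises(ValueError):
            choose_k(0)


class TestKnn:
    def test_k1_is_argmin(self):
        D = np.array([[0.3, 0.1, 0.5]])
        assert knn_classify(D, ["A", "B", "C"], 1) == ["B"]

    def test_majority_vote(self):
        D = np.array([[0.1, 0.2, 0.3, 0.9]])
        assert knn_classify(D, ["A", "B", "B", "A"], 3) == ["B"]

    def test_vote_tie_broken_by_nearest(self):
        # k = 4, two labels tied 2-2; the closest neighbour is B
        D = np.array([[0.2, 0.3, 0.1, 0.4]])
        assert knn_classify(D, ["A", "A", "B", "B"], 4) == ["B"]

    def test_distance_ties_prefer_lowest_index(self):
        D = np.zeros((1, 4))
        assert knn_classify(D, ["C", "A", "A", "A"], 1) == ["C"]
        # all-equal dissimilarities degenerate deterministically
        assert knn_classify(D, ["C", "A", "A", "A"], 3) == ["A"]

    def test_matches_exhaustive_euclidean_reference(self, rng):
        train = rng.standard_normal((20, 3))
        labels = [str(v) for v in rng.integers(0, 3, 20)]
        test = rng.standard_normal((10, 3))
        D = cross_dissimilarity(train, test, DistanceSpec.euclidean())
        pred = knn_classify(D, labels, 3)
        for q in range(10):
            dists = sorted(
                (np.linalg.norm(test[q] - train[i]), i) for i in range(20)
            )
            top = [labels[i] for _, i in dists[:3]]
            counts = {lab: top.count(lab) for lab in top}
            best = max(counts.values())
            tied = {lab for lab, cnt in counts.items() if cnt == best}
            expected = next(lab for lab in top if lab in tied)
            assert pred[q] == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            knn_classify(np.zeros((1, 3)), ["A", "B", "C"], 4)


class TestCrossValidation:
    def test_separated_classes_have_zero_error(self, rng):
        X = np.vstack([rng.standard_normal((20, 4)), rng.standard_normal((20, 4)) + 50])
        data = labeled(X, ["a"] * 20 + ["b"] * 20)
        errs = cv_error(data, DistanceSpec.euclidean(), folds=5, repeats=2, seed=1)
        np.testing.assert_allclose(errs, 0.0)

    def test_random_labels_give_chance_error(self, rng):
        X = rng.standard_normal((120, 5))
        labels = rng.permutation(["a"] * 60 + ["b"] * 60)
        data = labeled(X, labels)
        errs = cv_error(data, DistanceSpec.euclidean(), folds=10, repeats=3, seed=2)
        assert abs(errs.mean() - 0.5) < 0.05

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 3))
        labels = ["a"] * 20 + ["b"] * 20
        data = labeled(X, labels)
        e1 = cv_error(data, DistanceSpec.manhattan(), folds=5, repeats=2, seed=7)
        e2 = cv_error(data, DistanceSpec.manhattan(), folds=5, repeats=2, seed=7)
        np.testing.assert_array_equal(e1, e2)

    def test_feature_rule_refit_per_fold(self, rng):
        X = rng.standard_normal((40, 10))
        X[:20, 0] += 8  # only variable 0 is informative
        data = labeled(X, ["a"] * 20 + ["b"] * 20)
        errs = cv_error(data, DistanceSpec.euclidean(), folds=5, repeats=1,
                        feature_rule=("bw", 1), seed=3)
        assert errs.mean() < 0.1

    def test_small_class_rejected(self):
        data = labeled(np.random.default_rng(0).standard_normal((12, 2)),
                       ["a"] * 9 + ["b"] * 3)
        with pytest.raises(ValueError, match="fold"):
            cv_error(data, DistanceSpec.euclidean(), folds=5)


class TestFeatureSelection:
    def test_bw_hand_computed_toy(self):
        # labels (A,A,B,B); gene 0 separates perfectly with zero within-variance,
        # gene 1 has B/W = 81, gene 2 has B/W = 16, gene 3 is constant (0/0)
        X = np.array(
            [[0.0, 0.0, 0.0, 5.0],
             [0.0, 1.0, 2.0, 5.0],
             [10.0, 9.0, 8.0, 5.0],
             [10.0, 10.0, 10.0, 5.0]]
        )
        data = labeled(X, ["A", "A", "B", "B"])
        np.testing.assert_array_equal(bw_select(data, 1), [0])
        np.testing.assert_array_equal(bw_select(data, 3), [0, 1, 2])

    def test_bw_constant_gene_ranks_last(self):
        X = np.array([[5.0, 0.0], [5.0, 1.0], [5.0, 9.0], [5.0, 10.0]])
        data = labeled(X, ["A", "A", "B", "B"])
        np.testing.assert_array_equal(bw_select(data, 1), [1])

    def test_bw_single_class_rejected(self):
        data = labeled(np.ones((4, 2)) + np.arange(4)[:, None], ["A"] * 4)
        with pytest.raises(ValueError):
            bw_select(data, 1)

    def test_variance_select(self, rng):
        X = np.column_stack(
            [np.full(10, 3.0), rng.standard_normal(10), 10 * rng.standard_normal(10)]
        )
        np.testing.assert_array_equal(variance_select(X, 1), [2])
        np.testing.assert_array_equal(variance_select(X, 2), [1, 2])


class TestPam:
    def test_two_separated_clusters(self, rng):
        X = np.vstack([rng.standard_normal((10, 2)), rng.standard_normal((10, 2)) + 30])
        D = classical_dissimilarity(X, DistanceSpec.euclidean()).values
        part = pam_cluster(D, 2)
        truth = [0] * 10 + [1] * 10
        assert clustering_error(part.assignment, truth) == 0.0

    def test_all_zero_dissimilarity_runs(self):
        part = pam_cluster(np.zeros((6, 6)), 2)
        assert part.cost == 0.0
        assert len(part.assignment) == 6

    def test_matches_exhaustive_medoid_search(self, rng):
        for _ in range(10):
            D = rng.random((7, 7))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            part = pam_cluster(D, 2)
            best = min(
                np.minimum(D[i], D[j]).sum()
                for i, j in itertools.combinations(range(7), 2)
            )
            assert part.cost == pytest.approx(best)

    def test_deterministic(self, rng):
        D = rng.random((15, 15))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        p1 = pam_cluster(D, 3)
        p2 = pam_cluster(D, 3)
        assert p1.medoids == p2.medoids
        np.testing.assert_array_equal(p1.assignment, p2.assignment)

    def test_invalid_G(self):
        with pytest.raises(ValueError):
            pam_cluster(np.zeros((4, 4)), 4)


class TestCompleteLinkage:
    def test_three_point_hand_simulation(self):
        D = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 4.0], [5.0, 4.0, 0.0]])
        Z = complete_linkage_tree(D)
        assert (Z[0, 0], Z[0, 1], Z[0, 2]) == (0, 1, 1.0)
        assert Z[1, 2] == 5.0  # complete linkage takes the farthest pair

    def test_two_points(self):
        Z = complete_linkage_tree(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert Z.shape == (1, 4)
        assert Z[0, 2] == 2.0

    def test_ultrametric_heights_recovered(self):
        # heights 1 (a,b), 2 ((a,b),c)
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        Z = complete_linkage_tree(D)
        np.testing.assert_allclose(Z[:, 2], [1.0, 2.0])

    def test_matches_scipy_heights(self, rng):
        X = rng.standard_normal((12, 3))
        D = classical_dissimilarity(X, DistanceSpec.euclidean()).values
        Z = complete_linkage_tree(D)
        Z_ref = linkage(squareform(D, checks=False), method="complete")
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(Z_ref[:, 2]), atol=1e-10)

    def test_newick_export(self):
        import dendropy

        D = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 4.0], [5.0, 4.0, 0.0]])
        nwk = tree_to_newick(complete_linkage_tree(D), ["a", "b", "c"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"a", "b", "c"}


class TestPartitionScores:
    def test_clustering_error_examples(self):
        assert clustering_error([0, 0, 1, 1], [0, 0, 1, 1]) == 0.0
        assert clustering_error([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0
        assert clustering_error([1, 2, 2, 2], ["A", "A", "B", "B"]) == 0.25

    def test_clustering_error_relabel_invariance(self, rng):
        pred = rng.integers(0, 3, 30)
        truth = rng.integers(0, 3, 30)
        base = clustering_error(pred, truth)
        remap = np.array([2, 0, 1])
        assert clustering_error(remap[pred], truth) == base
        assert clustering_error(pred, remap[truth]) == base

    def test_clustering_error_matches_brute_force(self, rng):
        pred = rng.integers(0, 4, 25)
        truth = rng.integers(0, 4, 25)
        best = min(
            np.mean(np.array([perm[p] for p in pred]) != truth)
            for perm in itertools.permutations(range(4))
        )
        assert clustering_error(pred, truth) == pytest.approx(best)

    def test_clustering_error_bound(self, rng):
        pred = rng.integers(0, 2, 40)
        truth = rng.integers(0, 2, 40)
        assert 0 <= clustering_error(pred, truth) <= 0.5

    def test_ari_identical_partitions(self):
        assert adjusted_rand_index([0, 1, 1, 2], [5, 9, 9, 7]) == pytest.approx(1.0)

    def test_ari_hand_example(self):
        assert adjusted_rand_index([1, 2, 2, 2], ["A", "A", "B", "B"]) == pytest.approx(0.0)

    def test_ari_symmetric(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 4, 30)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))

    def test_ari_degenerate_partitions(self):
        assert adjusted_rand_index(list(range(6)), [0] * 6) == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            clustering_error([0, 1], [0, 1, 2])
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])
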