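import numpy as np
import pytest

from mixmerge import (
    ALL_CRITERIA,
    Criterion,
    TrialResult,
    ari,
    cluster_centers,
    d_inter,
    d_intra,
    f_measure,
    knn_outlier_proportions,
    label_entropy,
    merge_columns,
    psi,
    rank_table,
)
from mixmerge.errors import DomainError

from oracles import random_gamma


class TestClusterCenters:
    def test_hard_labels_give_arithmetic_means(self):
        g = np.zeros((4, 2))
        g[:2, 0] = 1.0
        g[2:, 1] = 1.0
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 4.0], [0.0, 6.0]])
        np.testing.assert_allclose(cluster_centers(g, X),
                                   [[1.0, 0.0], [0.0, 5.0]])

    def test_uniform_gamma_gives_grand_mean(self, rng):
        X = rng.normal(size=(10, 3))
        g = np.full((10, 4), 0.25)
        centers = cluster_centers(g, X)
        np.testing.assert_allclose(centers, np.tile(X.mean(axis=0), (4, 1)))

    def test_matches_loop_oracle(self, rng):
        g = random_gamma(rng, 8, 3)
        X = rng.normal(size=(8, 2))
        centers = cluster_centers(g, X)
        for k in range(3):
            num = sum(g[n, k] * X[n] for n in range(8))
            np.testing.assert_allclose(centers[k], num / g[:, k].sum())


class TestDistances:
    def test_singleton_clusters_zero_spread(self):
        g = np.eye(2)
        X = np.array([[0.0, 0.0], [0.0, 2.0]])
        assert d_intra(g, X) == pytest.approx(0.0)

    def test_two_points_one_cluster(self):
        g = np.ones((2, 1))
        X = np.array([[0.0, 0.0], [0.0, 2.0]])
        # center (0, 1); each point at distance 1
        assert d_intra(g, X) == pytest.approx(1.0)
        assert d_intra(g, X, squared=True) == pytest.approx(1.0)

    def test_merged_cluster_spread_bounded_below(self, rng):
        # law of total variance: the merged cluster's mean squared spread is
        # at least the mass-weighted mean of its members' spreads, so
        # merging tends to inflate intra-cluster distances
        for _ in range(10):
            g = random_gamma(rng, 30, 4)
            X = rng.normal(size=(30, 2))
            i, j = sorted(rng.choice(4, size=2, replace=False))
            centers = cluster_centers(g, X)
            mass = g.sum(axis=0)

            def spread_sq(col, center):
                return col @ ((X - center) ** 2).sum(axis=1) / col.sum()

            merged = merge_columns(g, i, j)
            col = merged.gamma[:, min(i, j)]
            c_m = cluster_centers(merged.gamma, X)[min(i, j)]
            lower = (mass[i] * spread_sq(g[:, i], centers[i])
                     + mass[j] * spread_sq(g[:, j], centers[j])) \
                / (mass[i] + mass[j])
            assert spread_sq(col, c_m) >= lower - 1e-12

    def test_inter_two_centers(self):
        g = np.eye(2)
        X = np.array([[0.0, 0.0], [0.0, 2.0]])
        assert d_inter(g, X) == pytest.approx(2.0)
        assert d_inter(g, X, squared=True) == pytest.approx(4.0)

    def test_duplicated_component_zero(self):
        g = np.tile([0.25, 0.25, 0.5], (6, 1))
        X = np.arange(12, dtype=float).reshape(6, 2)
        assert d_inter(g, X) == pytest.approx(0.0, abs=1e-9)

    def test_inter_matches_brute_force(self, rng):
        g = random_gamma(rng, 20, 4)
        X = rng.normal(size=(20, 2))
        centers = cluster_centers(g, X)
        brute = min(np.linalg.norm(centers[i] - centers[j])
                    for i in range(4) for j in range(i + 1, 4))
        assert d_inter(g, X) == pytest.approx(brute)

    def test_single_cluster_inter_undefined(self):
        with pytest.raises(DomainError):
            d_inter(np.ones((3, 1)), np.zeros((3, 2)))


def make_result(trial, intra_by_crit, inter_by_crit, ks):
    intra = {c: dict(zip(ks, intra_by_crit[c])) for c in intra_by_crit}
    inter = {c: dict(zip(ks, inter_by_crit[c])) for c in inter_by_crit}
    return TrialResult(trial=trial, intra=intra, inter=inter)


class TestRankTable:
    def test_single_trial_strict_ordering(self):
        ks = (10, 5)
        intra = {c: (r + 1.0, 6.0 - r) for r, c in enumerate(ALL_CRITERIA)}
        inter = {c: (r + 1.0, 6.0 - r) for r, c in enumerate(ALL_CRITERIA)}
        tbl_intra, tbl_inter = rank_table(
            [make_result(0, intra, inter, ks)])
        np.testing.assert_allclose(tbl_intra[10], np.arange(1, 7))
        # larger inter-distance is better: ordering reverses
        np.testing.assert_allclose(tbl_inter[10], np.arange(6, 0, -1))

    def test_all_tied_average_rank(self):
        ks = (5,)
        same = {c: (1.0,) for c in ALL_CRITERIA}
        tbl_intra, tbl_inter = rank_table([make_result(0, same, same, ks)])
        np.testing.assert_allclose(tbl_intra[5], 3.5)
        np.testing.assert_allclose(tbl_inter[5], 3.5)

    def test_three_trial_hand_average(self):
        ks = (5,)
        trials = []
        # criterion 'ent' is best twice and worst once for intra
        orders = [np.arange(6), np.arange(6), np.arange(6)[::-1]]
        for t, order in enumerate(orders):
            intra = {c: (float(order[r]),) for r, c in enumerate(ALL_CRITERIA)}
            trials.append(make_result(t, intra, intra, ks))
        tbl_intra, _ = rank_table(trials)
        assert tbl_intra.loc["ent", 5] == pytest.approx((1 + 1 + 6) / 3)

    def test_rank_sums_conserved(self, rng):
        ks = (10, 5)
        trials = []
        for t in range(4):
            intra = {c: tuple(rng.normal(size=2)) for c in ALL_CRITERIA}
            inter = {c: tuple(rng.normal(size=2)) for c in ALL_CRITERIA}
            trials.append(make_result(t, intra, inter, ks))
        tbl_intra, tbl_inter = rank_table(trials)
        np.testing.assert_allclose(tbl_intra.sum(axis=0), 21.0)
        np.testing.assert_allclose(tbl_inter.sum(axis=0), 21.0)

    def test_missing_cell_rejected(self):
        ks = (5,)
        intra = {c: (1.0,) for c in ALL_CRITERIA}
        broken = {c: {5: 1.0} for c in list(ALL_CRITERIA)[:-1]}
        result = TrialResult(trial=0, intra=broken,
                             inter={c: {5: 1.0} for c in ALL_CRITERIA})
        with pytest.raises((DomainError, KeyError)):
            rank_table([result])


class TestLabelEntropy:
    def test_pure_cluster_zero(self):
        labels = np.array([0, 0, 1, 1])
        assert label_entropy(labels, [True, True, False, False]) == 0.0

    def test_even_split_ln2(self):
        labels = np.array([0, 1, 0, 1])
        assert label_entropy(labels, np.ones(4, bool)) == pytest.approx(
            np.log(2))

    def test_three_one_split(self):
        labels = np.array([0, 0, 0, 1])
        assert label_entropy(labels, np.ones(4, bool)) == pytest.approx(
            psi(0.75) + psi(0.25))

    def test_empty_cluster_rejected(self):
        with pytest.raises(DomainError):
            label_entropy(np.array([0, 1]), np.zeros(2, bool))


class TestPairCountingScores:
    def test_identical_labelings_perfect(self):
        labels = np.array([0, 0, 1, 2, 2, 2])
        assert ari(labels, labels) == pytest.approx(1.0)
        assert f_measure(labels, labels) == pytest.approx(1.0)

    def test_single_cluster_vs_balanced_split_chance(self):
        a = np.zeros(8, dtype=int)
        b = np.repeat([0, 1], 4)
        assert ari(a, b) == pytest.approx(0.0)

    def test_permutation_invariance(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([2, 2, 0, 0, 1, 1])
        assert ari(a, b) == pytest.approx(1.0)
        assert f_measure(a, b) == pytest.approx(1.0)

    def test_f_measure_closed_form_2x2(self):
        # contingency [[2, 1], [1, 2]]: TP = 2, pred pairs = 6, true pairs = 6
        t = np.array([0, 0, 0, 1, 1, 1])
        p = np.array([0, 0, 1, 0, 1, 1])
        tp, pairs = 2.0, 6.0
        expected = 2 * (tp / pairs) * (tp / pairs) / (2 * tp / pairs)
        assert f_measure(t, p) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            ari([0, 1], [0, 1, 2])
        with pytest.raises(DomainError):
            f_measure([0, 1], [0, 1, 2])


class TestKnnOutliers:
    def test_uniform_grid_no_outliers(self):
        xs, ys = np.meshgrid(np.arange(8.0), np.arange(8.0))
        grid = np.column_stack([xs.ravel(), ys.ravel()])
        props = knn_outlier_proportions(grid)
        assert props[2.0] == 0.0

    def test_single_far_outlier(self, rng):
        tight = rng.normal(0, 0.02, size=(60, 2))
        data = np.vstack([tight, [[50.0, 50.0]]])
        props = knn_outlier_proportions(data)
        for t in (2.0, 3.0, 4.0, 5.0):
            assert props[t] == pytest.approx(1 / len(data))

    def test_nonincreasing_in_threshold(self, rng):
        data = rng.normal(size=(100, 2))
        props = knn_outlier_proportions(data)
        vals = [props[t] for t in sorted(props)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            knn_outlier_proportions(np.zeros((4, 2)), k=5)
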