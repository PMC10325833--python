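"""Typing engine: JSD, PAM, CH selection, silhouette null, BCA, drivers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon, pdist, squareform
from sklearn.metrics import calinski_harabasz_score

from orogut import (bca, ch_index, identify_drivers, jsd, jsd_distance_matrix,
                    null_silhouette_test, pam, select_k, shannon_entropy,
                    silhouette, to_relative)
from orogut.community_typing import DistanceMatrix, _sqrt_jsd_matrix

from conftest import make_table

LN2 = np.log(2.0)


def euclid_dm(points):
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 1)
    d = squareform(pdist(pts))
    return DistanceMatrix(tuple(str(i) for i in range(len(pts))), d, "euclidean")


# ---------------------------------------------------------------------------
# entropy & JSD
# ---------------------------------------------------------------------------

class TestEntropyJsd:
    @pytest.mark.parametrize("p, expected", [
        ([1.0, 0.0], 0.0),
        ([0.5, 0.5], LN2),
        ([0.25] * 4, np.log(4.0)),
    ])
    def test_entropy_analytic(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_entropy_rejects_negative(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.2, -0.2])

    @pytest.mark.parametrize("p, q, expected", [
        ([0.3, 0.7], [0.3, 0.7], 0.0),
        ([1.0, 0.0], [0.0, 1.0], LN2),
        ([1.0, 0.0], [0.5, 0.5], 0.215762),
    ])
    def test_jsd_analytic(self, p, q, expected):
        assert jsd(p, q) == pytest.approx(expected, abs=1e-6)

    def test_jsd_length_mismatch(self):
        with pytest.raises(ValueError):
            jsd([1.0], [0.5, 0.5])

    def test_jsd_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            ours = jsd(p, q)
            scipy_val = jensenshannon(p, q, base=np.e) ** 2
            assert ours == pytest.approx(scipy_val, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=10),
           st.lists(st.floats(0.01, 10.0), min_size=2, max_size=10))
    def test_jsd_symmetric_and_bounded(self, a, b):
        m = min(len(a), len(b))
        p = np.asarray(a[:m]) / np.sum(a[:m])
        q = np.asarray(b[:m]) / np.sum(b[:m])
        d1, d2 = jsd(p, q), jsd(q, p)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert -1e-12 <= d1 <= LN2 + 1e-12


class TestJsdMatrix:
    def test_identical_rows_zero(self):
        t = make_table([[0.2, 0.8], [0.2, 0.8], [0.5, 0.5]], mode="relative")
        d = jsd_distance_matrix(t)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_supports_analytic(self):
        t = make_table([[1, 0], [0, 1], [0.5, 0.5]], mode="relative")
        d = jsd_distance_matrix(t)
        assert d.values[0, 1] == pytest.approx(np.sqrt(LN2), abs=1e-4)

    def test_requires_relative_and_min_samples(self):
        with pytest.raises(ValueError):
            jsd_distance_matrix(make_table([[1, 2], [3, 4], [5, 6]]))
        with pytest.raises(ValueError):
            jsd_distance_matrix(make_table([[0.5, 0.5]], mode="relative"))

    def test_triangle_inequality_exhaustive(self):
        rng = np.random.default_rng(1)
        rows = rng.dirichlet(np.full(20, 0.5), size=10)
        d = _sqrt_jsd_matrix(rows)
        for i, j, k in itertools.permutations(range(10), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_sub_simplex_rows_accepted(self):
        """Filtered tables (row sums < 1) renormalise inside the metric."""
        t = make_table([[0.4, 0.4], [0.1, 0.7], [0.3, 0.3]], mode="relative")
        d = jsd_distance_matrix(t)
        assert d.values[0, 2] == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

class TestPam:
    def test_k_equals_n_zero_cost(self):
        d = euclid_dm([0.0, 1.0, 10.0])
        med, labels, cost = pam(d, 3)
        assert med == (0, 1, 2)
        assert cost == 0.0

    def test_single_medoid_1d(self):
        """Exhaustive over the 3 candidates: costs 11, 10, 19 -> medoid 1."""
        med, labels, cost = pam(euclid_dm([0.0, 1.0, 10.0]), 1)
        assert med == (1,)
        assert cost == pytest.approx(10.0)

    def test_two_tight_triads_match_exhaustive(self):
        pts = [0.0, 0.1, 0.2, 10.0, 10.1, 10.2]
        d = euclid_dm(pts)
        med, labels, cost = pam(d, 2)
        best = min(((d.values[:, list(c)].min(axis=1).sum(), c)
                    for c in itertools.combinations(range(6), 2)),
                   key=lambda t: t[0])
        assert cost == pytest.approx(best[0])
        assert set(med) == set(best[1])

    def test_matches_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, 4))
            d = squareform(pdist(rng.random((n, 3))))
            _, _, cost = pam(d, k)
            best = min(d[:, list(c)].min(axis=1).sum()
                       for c in itertools.combinations(range(n), k))
            assert cost == pytest.approx(best, abs=1e-12)

    def test_build_swap_path_reaches_local_optimum(self):
        """On a larger instance (heuristic path) no single swap improves."""
        rng = np.random.default_rng(5)
        d = squareform(pdist(rng.random((40, 3))))
        med, labels, cost = pam(d, 4)
        for pos in range(4):
            for h in range(40):
                if h in med:
                    continue
                cand = list(med)
                cand[pos] = h
                assert d[:, cand].min(axis=1).sum() >= cost - 1e-12

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        d = squareform(pdist(rng.random((30, 3))))
        perm = rng.permutation(30)
        _, lab1, cost1 = pam(d, 3)
        _, lab2, cost2 = pam(d[np.ix_(perm, perm)], 3)
        assert cost1 == pytest.approx(cost2)
        # same partition up to relabelling
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(lab1[perm], lab2) == pytest.approx(1.0)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            pam(euclid_dm([0.0, 1.0]), 3)


# ---------------------------------------------------------------------------
# CH index & model selection
# ---------------------------------------------------------------------------

class TestChIndex:
    def test_worked_example_ch_200(self):
        d = euclid_dm([0.0, 1.0, 10.0, 11.0])
        assert ch_index(d, [0, 0, 1, 1]) == pytest.approx(200.0, abs=1e-8)

    def test_coincident_points_infinite(self):
        d = DistanceMatrix(("a", "b", "c", "d"), np.zeros((4, 4)))
        assert ch_index(d, [0, 0, 1, 1]) == np.inf

    def test_matches_centroid_form_on_euclidean_data(self):
        rng = np.random.default_rng(7)
        pts = rng.random((25, 4))
        d = squareform(pdist(pts))
        for _ in range(50):
            labels = rng.integers(0, 3, 25)
            if len(np.unique(labels)) < 2:
                continue
            ours = ch_index(d, labels)
            ref = calinski_harabasz_score(pts, labels)
            assert ours == pytest.approx(ref, rel=1e-8)

    def test_k_range_validated(self):
        d = euclid_dm([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            ch_index(d, [0, 1, 2])          # k = n


class TestSelectK:
    @pytest.mark.parametrize("n_blobs", [2, 3])
    def test_recovers_planted_blob_count(self, n_blobs):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = np.concatenate([rng.normal(10 * c, 0.3, size=(12, 2))
                                  for c in range(n_blobs)])
            d = DistanceMatrix(tuple(map(str, range(len(pts)))),
                               squareform(pdist(pts)))
            assert select_k(d, (2, 6)).k == n_blobs

    def test_ch_profile_covers_searched_range(self):
        rng = np.random.default_rng(8)
        d = DistanceMatrix(tuple(map(str, range(20))),
                           squareform(pdist(rng.random((20, 3)))))
        sol = select_k(d, (2, 5))
        assert sorted(sol.ch_by_k) == [2, 3, 4, 5]
        assert sol.ch_by_k[sol.k] == max(sol.ch_by_k.values())

    def test_empty_range_errors(self):
        d = euclid_dm([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            select_k(d, (4, 2))


# ---------------------------------------------------------------------------
# silhouette & null test
# ---------------------------------------------------------------------------

class TestSilhouette:
    def test_worked_example(self):
        d = euclid_dm([0.0, 1.0, 10.0, 11.0])
        vals, mean = silhouette(d, [0, 0, 1, 1])
        assert mean == pytest.approx((9.5 / 10.5 + 8.5 / 9.5) / 2, abs=1e-8)

    def test_separated_blobs_approach_one(self):
        d = euclid_dm([0.0, 0.0, 100.0, 100.0])
        _, mean = silhouette(d, [0, 0, 1, 1])
        assert mean == pytest.approx(1.0)

    def test_singleton_scores_zero(self):
        d = euclid_dm([0.0, 1.0, 10.0])
        vals, _ = silhouette(d, [0, 0, 1])
        assert vals[2] == 0.0

    def test_single_cluster_errors(self):
        d = euclid_dm([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            silhouette(d, [0, 0, 0])


class TestNullSilhouetteTest:
    def test_structured_data_minimal_p(self, gut_filtered):
        sol, p = null_silhouette_test(gut_filtered, (2, 6), n_null=19, seed=0)
        assert p == pytest.approx(1 / 20)
        assert sol.silhouette_p == p
        assert sol.k == 3

    def test_deterministic_under_seed(self, gut_filtered):
        _, p1 = null_silhouette_test(gut_filtered, (2, 4), n_null=19, seed=5)
        _, p2 = null_silhouette_test(gut_filtered, (2, 4), n_null=19, seed=5)
        assert p1 == p2

    def test_n_null_floor(self, gut_filtered):
        with pytest.raises(ValueError):
            null_silhouette_test(gut_filtered, n_null=5)


# ---------------------------------------------------------------------------
# BCA & drivers
# ---------------------------------------------------------------------------

class TestBca:
    def test_single_class_zero_ratio(self):
        t = make_table(np.random.default_rng(0).dirichlet(np.ones(4), 6),
                       mode="relative")
        res = bca(t, [0] * 6)
        assert res.between_inertia_ratio == pytest.approx(0.0, abs=1e-12)

    def test_homogeneous_classes_ratio_one(self):
        rows = [[0.2, 0.8], [0.2, 0.8], [0.7, 0.3], [0.7, 0.3]]
        res = bca(make_table(rows, mode="relative"), [0, 0, 1, 1])
        assert res.between_inertia_ratio == pytest.approx(1.0)

    def test_first_axis_parallel_to_mean_difference_two_classes(self):
        rng = np.random.default_rng(9)
        a = rng.dirichlet([8, 2, 2, 2], 20)
        b = rng.dirichlet([2, 2, 8, 2], 20)
        t = make_table(np.vstack([a, b]), mode="relative")
        labels = [0] * 20 + [1] * 20
        res = bca(t, labels)
        diff = a.mean(0) - b.mean(0)
        axis = res.axes[:, 0]
        cos = abs(diff @ axis) / np.linalg.norm(diff)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalue_count_at_most_k_minus_one(self):
        rng = np.random.default_rng(10)
        t = make_table(rng.dirichlet(np.ones(6), 30), mode="relative")
        labels = rng.integers(0, 3, 30)
        res = bca(t, labels)
        assert len(res.eigenvalues) <= 2
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)


class TestDrivers:
    def test_single_taxon_is_every_types_driver(self):
        t = make_table([[1.0]] * 4, mode="relative")
        d = euclid_dm([0.0, 0.0, 1.0, 1.0])
        sol = select_k(DistanceMatrix(t.sample_ids,
                                      euclid_dm([0, 0, 10, 10]).values), (2, 2))
        drivers, _ = identify_drivers(t, sol)
        assert set(drivers.values()) == {"T1"}

    def test_tie_broken_lexicographically(self):
        rows = [[0.4, 0.4, 0.2], [0.4, 0.4, 0.2],
                [0.1, 0.1, 0.8], [0.1, 0.1, 0.8]]
        t = make_table(rows, mode="relative", taxa=["B_tax", "A_tax", "C_tax"])
        sol = select_k(DistanceMatrix(t.sample_ids,
                                      euclid_dm([0, 0, 10, 10]).values), (2, 2))
        drivers, summary = identify_drivers(t, sol)
        cluster_of_first_two = sol.labels[0]
        name = sol.type_names[cluster_of_first_two]
        assert drivers[name] == "A_tax"
        assert {"mean", "q1", "q3", "min", "max"} <= set(summary.columns)

    def test_gut_preset_drivers_recovered(self, study_cohort, gut_filtered):
        sol = select_k(jsd_distance_matrix(gut_filtered), (2, 6), site="gut")
        drivers, _ = identify_drivers(gut_filtered, sol)
        assert set(drivers.values()) == {
            "Bifidobacterium", "Ruminococcus", "Prevotella"}


def test_type_names_by_descending_size():
    d = euclid_dm([0.0, 0.1, 0.2, 10.0, 10.1])
    sol = select_k(d, (2, 2), site="gut")
    sizes = np.bincount(sol.labels)
    biggest = int(np.argmax(sizes))
    assert sol.type_names[biggest] == "E1"
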