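"""k-medoids, validity indices, k selection and bootstrap stability."""

import itertools

import numpy as np
import pandas as pd
import pytest

from roaddust.cluster import (
    _dunn,
    kmedoids,
    select_k,
    stability,
    stability_label,
    standardize,
    validity,
)
from scipy.spatial.distance import pdist, squareform


def exhaustive_optimum(X: np.ndarray, k: int) -> float:
    D = squareform(pdist(X))
    return min(
        D[:, list(meds)].min(axis=1).sum()
        for meds in itertools.combinations(range(len(X)), k)
    )


def two_clouds(rng, n_per=8, sep=20.0, dim=3):
    a = rng.normal(0, 1, size=(n_per, dim))
    b = rng.normal(sep, 1, size=(n_per, dim))
    return np.vstack([a, b]), np.array([0] * n_per + [1] * n_per)


class TestKmedoids:
    def test_line_example_brute_force(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        sol = kmedoids(X, 2, seed=0)
        groups = {tuple(np.flatnonzero(sol.labels == c)) for c in range(2)}
        assert groups == {(0, 1, 2), (3, 4)}
        assert "1" in sol.medoid_sites  # medoid of {0,1,2} is the middle point
        assert sol.total_cost == pytest.approx(exhaustive_optimum(X, 2))

    def test_k_equals_n_zero_cost(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        sol = kmedoids(X, 4, seed=0)
        assert sol.total_cost == 0.0
        assert sorted(sol.medoid_sites) == sorted(["0", "1", "2", "3"])

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kmedoids(np.zeros((4, 2)), 1, seed=0)
        with pytest.raises(ValueError):
            kmedoids(np.zeros((4, 2)), 5, seed=0)

    def test_separated_clouds_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X, truth = two_clouds(rng)
        sol = kmedoids(X, 2, seed=1)
        same = sol.labels == sol.labels[0]
        assert (same == (truth == truth[0])).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 4))
        a, b = kmedoids(X, 3, seed=99), kmedoids(X, 3, seed=99)
        assert a.medoid_sites == b.medoid_sites
        assert a.total_cost == b.total_cost
        assert (a.labels == b.labels).all()

    def test_assignment_is_nearest_medoid(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 3))
        sol = kmedoids(X, 3, seed=2)
        D = squareform(pdist(X))
        med_idx = [int(s) for s in sol.medoid_sites]
        np.testing.assert_array_equal(sol.labels, D[:, med_idx].argmin(axis=1))

    def test_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            X = rng.normal(size=(n, 3))
            sol = kmedoids(X, k, seed=int(rng.integers(2**31)))
            assert sol.total_cost == pytest.approx(exhaustive_optimum(X, k), abs=1e-9)


class TestValidity:
    def test_dunn_hand_computation(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = squareform(pdist(X))
        labels = np.array([0, 0, 1, 1])
        assert _dunn(D, labels) == pytest.approx(9.0)  # min inter 9 / max diam 1

    def test_silhouette_approaches_one_with_separation(self):
        rng = np.random.default_rng(1)
        near, _ = two_clouds(rng, sep=5.0)
        far, _ = two_clouds(rng, sep=500.0)
        s_near = validity(kmedoids(near, 2, seed=0), near)["silhouette"]
        s_far = validity(kmedoids(far, 2, seed=0), far)["silhouette"]
        assert s_far > s_near
        assert s_far > 0.98

    def test_connectivity_zero_for_isolated_clusters(self):
        rng = np.random.default_rng(2)
        X, _ = two_clouds(rng, n_per=12, sep=100.0)
        scores = validity(kmedoids(X, 2, seed=0), X, n_neighbors=10)
        assert scores["connectivity"] == 0.0


class TestSelectK:
    def test_two_clouds_majority_two(self):
        rng = np.random.default_rng(3)
        X, _ = two_clouds(rng, n_per=10, sep=30.0)
        sel = select_k(X, range(2, 7), seed=5)
        assert sel.chosen_k == 2
        assert sel.votes[2] >= 3

    def test_three_clouds_majority_three(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [40, 0], [20, 35]], dtype=float)
        X = np.vstack([rng.normal(c, 1.0, size=(8, 2)) for c in centers])
        sel = select_k(X, range(2, 7), seed=5)
        assert sel.chosen_k == 3

    def test_vote_tie_goes_to_smaller_k(self):
        from roaddust.cluster import KSelection
        from collections import Counter
        votes = Counter({4: 2, 2: 2, 5: 1})
        top = max(votes.values())
        chosen = min(k for k, v in votes.items() if v == top)
        sel = KSelection((2, 3, 4, 5), dict(votes), chosen)
        assert sel.chosen_k == 2


class TestStability:
    def test_duplicated_two_cloud_data_is_highly_stable(self):
        rng = np.random.default_rng(6)
        X, _ = two_clouds(rng, n_per=10, sep=50.0)
        jac = stability(X, 2, B=40, seed=3)
        assert (jac >= 0.95).all()
        assert all(stability_label(v) == "highly stable" for v in jac)

    def test_noise_less_stable_than_structure(self):
        rng = np.random.default_rng(10)
        structured, _ = two_clouds(rng, n_per=10, sep=50.0)
        noise = rng.normal(size=(20, 3))
        j_structured = stability(structured, 3, B=30, seed=4).mean()
        j_noise = stability(noise, 3, B=30, seed=4).mean()
        assert j_noise < j_structured

    def test_single_resample_reproducible(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 2))
        with pytest.warns(UserWarning):
            a = stability(X, 2, B=1, seed=7)
        with pytest.warns(UserWarning):
            b = stability(X, 2, B=1, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_label_thresholds(self):
        assert stability_label(0.92) == "highly stable"
        assert stability_label(0.80) == "stable"
        assert stability_label(0.5) == "unstable"


def test_standardize_unit_variance():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.lognormal(3, 1, size=(30, 4)))
    Z = standardize(df)
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, rtol=1e-12)
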