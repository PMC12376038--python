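"""JSD, PAM, Calinski-Harabasz, validation and the independence test."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon
from scipy.stats import chi2_contingency
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from conftest import blob_distance_matrix
from enterolink.enterotypes import (
    average_per_animal,
    between_class_weights,
    calinski_harabasz,
    enterotype_independence,
    fit_enterotypes,
    jsd_matrix,
    pam_cluster,
    pam_exhaustive,
    validate_clustering,
)
from enterolink.synthetic import SyntheticConfig, simulate_enterotype_communities


class TestAveragePerAnimal:
    def test_constant_profile_unchanged(self, repeated_measures_community):
        prof = average_per_animal(repeated_measures_community)
        np.testing.assert_allclose(prof.loc["a3"], [0.5, 0.5, 0.0], atol=1e-12)

    def test_hand_computed_means(self, repeated_measures_community):
        prof = average_per_animal(repeated_measures_community)
        # a1: mean of (0.8,0.2,0), (0.6,0.4,0), (0.4,0.6,0)
        np.testing.assert_allclose(prof.loc["a1"], [0.6, 0.4, 0.0], atol=1e-12)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-12)

    def test_opposite_profiles_average_to_half(self):
        counts = pd.DataFrame([[10, 0], [0, 10]], index=["s1", "s2"], columns=["x", "y"])
        meta = pd.DataFrame(
            {"animal": ["a", "a"], "timepoint": ["T1", "T2"], "site": "r"},
            index=counts.index,
        )
        from enterolink.community import CommunityMatrix

        prof = average_per_animal(CommunityMatrix(counts, meta))
        np.testing.assert_allclose(prof.loc["a"], [0.5, 0.5], atol=1e-12)


class TestJSD:
    def test_identical_rows_zero(self):
        prof = pd.DataFrame([[0.3, 0.7], [0.3, 0.7]], index=["a", "b"])
        d = jsd_matrix(prof)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_supports_approach_one(self):
        prof = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        d = jsd_matrix(prof, pseudocount=1e-12)
        assert d.iloc[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_kl_summation_oracle(self):
        # D((1,0),(0.5,0.5)) = sqrt(0.5 log2(4/3) + 0.25 log2(2/3) + 0.25)
        expected = np.sqrt(0.5 * np.log2(4 / 3) + 0.25 * np.log2(2 / 3) + 0.25)
        prof = pd.DataFrame([[1.0, 0.0], [0.5, 0.5]], index=["a", "b"])
        d = jsd_matrix(prof, pseudocount=1e-15)
        assert d.iloc[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_matches_scipy_on_random_profiles(self):
        rng = np.random.default_rng(4)
        x = rng.dirichlet(np.ones(6), size=5)
        prof = pd.DataFrame(x, index=[f"a{i}" for i in range(5)])
        d = jsd_matrix(prof, pseudocount=0.0)
        for i in range(5):
            for j in range(i + 1, 5):
                assert d.iloc[i, j] == pytest.approx(
                    jensenshannon(x[i], x[j], base=2), abs=1e-10
                )

    def test_metric_properties_on_fixture(self):
        rng = np.random.default_rng(8)
        x = rng.dirichlet(np.ones(8), size=7)
        d = jsd_matrix(pd.DataFrame(x)).to_numpy()
        assert (d >= 0).all() and (d <= 1 + 1e-9).all()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        for i in range(7):
            for j in range(7):
                for k in range(7):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            jsd_matrix(pd.DataFrame([[-0.1, 1.1], [0.5, 0.5]]))


class TestPAM:
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_optimum(self, k):
        rng = np.random.default_rng(10 + k)
        x = rng.normal(size=(10, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = pd.DataFrame(d, index=range(10), columns=range(10))
        _, medoids = pam_cluster(dm, k)
        cost = d[:, medoids].min(axis=1).sum()
        best_cost, _ = pam_exhaustive(dm, k)
        assert cost == pytest.approx(best_cost, abs=1e-10)

    def test_recovers_planted_blobs(self):
        d = blob_distance_matrix(seed=1)
        assign, _ = pam_cluster(d, 2)
        truth = [0] * 6 + [1] * 6
        assert adjusted_rand_score(truth, assign.to_numpy()) == 1.0

    def test_duplicates_co_assigned(self):
        d = pd.DataFrame(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        assign, _ = pam_cluster(d, 2)
        assert assign["a"] == assign["b"] and assign["c"] == assign["d"]

    def test_cost_beats_random_medoid_sets(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = pd.DataFrame(d, index=range(20), columns=range(20))
        _, medoids = pam_cluster(dm, 3)
        cost = d[:, medoids].min(axis=1).sum()
        for _ in range(100):
            cand = rng.choice(20, size=3, replace=False)
            assert cost <= d[:, cand].min(axis=1).sum() + 1e-10

    def test_invalid_k(self):
        d = blob_distance_matrix()
        with pytest.raises(ValueError):
            pam_cluster(d, d.shape[0])


class TestCalinskiHarabasz:
    def test_matches_sklearn_on_euclidean_data(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(4, 1, (6, 3))])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = pd.Series([0] * 6 + [1] * 6, index=range(12))
        ours = calinski_harabasz(pd.DataFrame(d, index=range(12), columns=range(12)), labels)
        ref = calinski_harabasz_score(x, labels.to_numpy())
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_perfect_separation_is_infinite(self):
        d = pd.DataFrame(
            [[0, 0, 9, 9], [0, 0, 9, 9], [9, 9, 0, 0], [9, 9, 0, 0]],
            index=range(4), columns=range(4), dtype=float,
        )
        labels = pd.Series([0, 0, 1, 1], index=range(4))
        assert calinski_harabasz(d, labels) == float("inf")

    def test_no_spurious_k2_optimum_on_null(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=(20, 4))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            dm = pd.DataFrame(d, index=range(20), columns=range(20))
            scores = {}
            for k in (2, 3, 4, 5):
                assign, _ = pam_cluster(dm, k)
                scores[k] = calinski_harabasz(dm, assign)
            hits += max(scores, key=scores.get) == 2
        assert hits < 20  # no systematic k=2 optimum under the null


class TestValidation:
    def test_planted_clusters_stable_with_high_silhouettes(self):
        d = blob_distance_matrix(seed=3, n_per=8)
        rng = np.random.default_rng(3)
        x = np.vstack(
            [rng.dirichlet([10, 1, 1], size=8), rng.dirichlet([1, 1, 10], size=8)]
        )
        prof = pd.DataFrame(x, index=d.index)
        dj = pd.DataFrame(
            np.array([[jensenshannon(a, b, base=2) for b in x] for a in x]),
            index=d.index, columns=d.index,
        )
        sil, stability = validate_clustering(prof, dj, k=2, k_range=(2,), n_boot=50, seed=0)
        assert stability >= 0.95
        assert all(sil[m][2] > 0.5 for m in sil)

    def test_null_data_less_stable_than_planted(self):
        rng = np.random.default_rng(12)
        x = rng.dirichlet(np.ones(6), size=16)
        prof = pd.DataFrame(x, index=[f"a{i}" for i in range(16)])
        dj = pd.DataFrame(
            np.array([[jensenshannon(a, b, base=2) for b in x] for a in x]),
            index=prof.index, columns=prof.index,
        )
        _, null_stab = validate_clustering(prof, dj, k=2, k_range=(2,), n_boot=50, seed=0)

        xs = np.vstack(
            [rng.dirichlet([20, 1, 1, 1, 1, 1], size=8), rng.dirichlet([1, 1, 1, 1, 1, 20], size=8)]
        )
        profs = pd.DataFrame(xs, index=prof.index)
        djs = pd.DataFrame(
            np.array([[jensenshannon(a, b, base=2) for b in xs] for a in xs]),
            index=prof.index, columns=prof.index,
        )
        _, planted_stab = validate_clustering(profs, djs, k=2, k_range=(2,), n_boot=50, seed=0)
        assert planted_stab - null_stab >= 0.3

    def test_unknown_metric_rejected(self):
        d = blob_distance_matrix()
        prof = pd.DataFrame(np.ones((12, 3)) / 3, index=d.index)
        with pytest.raises(ValueError, match="unknown metric"):
            validate_clustering(prof, d, k=2, metrics=("mystery",))

    def test_singleton_clustering_rejected(self):
        d = blob_distance_matrix(n_per=2)
        prof = pd.DataFrame(np.ones((4, 3)) / 3, index=d.index)
        with pytest.raises(ValueError):
            validate_clustering(prof, d, k=2, k_range=(4,))


class TestBetweenClass:
    def test_single_differing_taxon_dominates_weights(self):
        # the only between-class contrast is taxon A boosted in cluster 0
        g0 = np.tile([0.4, 0.15, 0.15, 0.15, 0.15], (6, 1))
        g1 = np.tile([0.1, 0.225, 0.225, 0.225, 0.225], (6, 1))
        prof = pd.DataFrame(np.vstack([g0, g1]), index=range(12), columns=list("ABCDE"))
        labels = pd.Series([0] * 6 + [1] * 6, index=range(12))
        weights, dominant = between_class_weights(prof, labels)
        assert weights.abs().idxmax() == "A"
        assert dominant[0] == "A"

    def test_identical_class_means_zero_weights(self):
        prof = pd.DataFrame(
            [[0.2, 0.8]] * 4, index=range(4), columns=["A", "B"]
        )
        labels = pd.Series([0, 0, 1, 1], index=range(4))
        weights, _ = between_class_weights(prof, labels)
        np.testing.assert_allclose(weights, 0.0, atol=1e-12)

    def test_one_cluster_rejected(self):
        prof = pd.DataFrame([[0.5, 0.5]] * 3, index=range(3))
        with pytest.raises(ValueError):
            between_class_weights(prof, pd.Series([0, 0, 0], index=range(3)))


class TestIndependence:
    def test_fig_1c_style_table_matches_expected_count_oracle(self):
        table = [[15, 12], [18, 29]]
        stat, df, p = enterotype_independence(table)
        ref = chi2_contingency(np.array(table), correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert df == 1
        assert p > 0.05  # independence not rejected

    def test_proportional_table_statistic_zero(self):
        stat, _, p = enterotype_independence([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_extreme(self):
        _, _, p = enterotype_independence([[50, 0], [0, 50]])
        assert p < 1e-10

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            enterotype_independence([[0, 0], [5, 5]])


class TestEndToEnd:
    def test_recovers_planted_enterotypes(self):
        cfg = SyntheticConfig(seed=11)
        m, truth = simulate_enterotype_communities(cfg)
        model = fit_enterotypes(m, n_boot=30, seed=1)
        assert model.k == 2
        planted = [truth.enterotype_of_animal[a] for a in model.assignments.index]
        assert adjusted_rand_score(planted, model.assignments.to_numpy()) >= 0.9
        assert set(model.dominant_taxon.values()) == truth.true_effect_taxa

    def test_pipeline_deterministic(self):
        cfg = SyntheticConfig(n_animals=20, seed=5)
        m, _ = simulate_enterotype_communities(cfg)
        m1 = fit_enterotypes(m, n_boot=10, seed=2)
        m2 = fit_enterotypes(m, n_boot=10, seed=2)
        assert m1.k == m2.k
        assert (m1.assignments == m2.assignments).all()
        assert m1.stability == m2.stability
        assert m1.ch_by_k == m2.ch_by_k
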