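"""Correlation distances, classical/nonmetric MDS, UPGMA clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from thyrosig import (
    ConfigurationError,
    DataError,
    NonmetricMDS,
    classical_mds,
    correlation_distances,
    hierarchical_cluster,
    nonmetric_mds,
)
from thyrosig.embedding import DistanceMatrix


def euclidean_dm(points):
    pts = np.asarray(points, dtype=float)
    return DistanceMatrix(
        ids=[f"x{i}" for i in range(len(pts))],
        values=squareform(pdist(pts)),
    )


class TestCorrelationDistances:
    def test_duplicated_columns_have_zero_distance(self, rng):
        profile = rng.normal(size=20)
        m = pd.DataFrame(
            {"s1": profile, "s2": profile, "s3": rng.normal(size=20)}
        )
        d = correlation_distances(m)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_have_distance_two(self, rng):
        profile = rng.normal(size=30)
        m = pd.DataFrame({"s1": profile, "s2": -profile})
        d = correlation_distances(m)
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_loop_based_pearson_oracle(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(4, 3)), columns=["s1", "s2", "s3"]
        )
        d = correlation_distances(m)
        for i, j in itertools.combinations(range(3), 2):
            x = m.iloc[:, i].to_numpy()
            y = m.iloc[:, j].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert abs(d.values[i, j] - (1 - r)) < 1e-12

    def test_zero_variance_profile_named_in_error(self):
        m = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [0.0, 1.0, 2.0]})
        with pytest.raises(DataError, match="flat"):
            correlation_distances(m)

    def test_probe_subset_restricts_profiles(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(10, 3)),
            index=[f"p{i}" for i in range(10)],
            columns=["s1", "s2", "s3"],
        )
        d_sub = correlation_distances(m, probe_subset=[f"p{i}" for i in range(5)])
        d_manual = correlation_distances(m.iloc[:5])
        assert np.allclose(d_sub.values, d_manual.values)


class TestClassicalMds:
    def test_collinear_points_recovered_in_1d(self):
        D = euclidean_dm([[0.0], [1.0], [3.0]])
        X = classical_mds(D, 1)
        assert np.allclose(
            squareform(pdist(X)), D.values, atol=1e-9
        )

    def test_unit_square_recovered_in_2d(self):
        D = euclidean_dm([[0, 0], [1, 0], [1, 1], [0, 1]])
        X = classical_mds(D, 2)
        assert np.allclose(squareform(pdist(X)), D.values, atol=1e-9)

    def test_two_points_at_given_separation(self):
        D = DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 0.7],
                                                            [0.7, 0.0]]))
        X = classical_mds(D, 1)
        assert abs(pdist(X)[0] - 0.7) < 1e-12

    def test_k_not_smaller_than_n_rejected(self):
        D = euclidean_dm([[0, 0], [1, 0], [0, 1]])
        with pytest.raises(ConfigurationError):
            classical_mds(D, 3)


class TestNonmetricMds:
    def test_euclidean_embeddable_input_reaches_near_zero_stress(self, rng):
        pts = rng.normal(size=(9, 2))
        emb = nonmetric_mds(euclidean_dm(pts), k=2, seed=0)
        assert emb.stress <= 1e-3

    def test_five_point_stress_close_to_brute_force_minimum(self, rng):
        pts = rng.normal(size=(5, 3))  # 3D points squeezed into the plane
        D = euclidean_dm(pts)
        emb = nonmetric_mds(D, k=2, seed=0)
        # dense random-restart brute force at this size
        best = min(
            nonmetric_mds(D, k=2, n_restarts=1, max_iter=500, seed=s).stress
            for s in range(40)
        )
        assert emb.stress <= best + 1e-2

    def test_matches_sklearn_smacof_quality(self, default_cohort):
        """Independent cross-check: our optimizer should not be worse than
        sklearn's nonmetric SMACOF on the same dissimilarities."""
        from sklearn.manifold import smacof

        _, ratios, _, _ = default_cohort
        D = correlation_distances(ratios)
        emb = nonmetric_mds(D, k=2, seed=0)
        _, sk_stress = smacof(
            D.values, metric=False, n_components=2, n_init=2,
            normalized_stress=True, random_state=0,
        )
        assert emb.stress <= sk_stress + 1e-2

    def test_default_cohort_classes_separate_in_embedding(self, default_cohort):
        from sklearn.metrics import silhouette_score

        _, ratios, sheet, _ = default_cohort
        emb = nonmetric_mds(correlation_distances(ratios), k=2, seed=0)
        assert silhouette_score(emb.coords, sheet.to_numpy()) > 0

    def test_coordinates_centered_at_origin(self, rng):
        emb = nonmetric_mds(euclidean_dm(rng.normal(size=(6, 4))), k=2, seed=0)
        assert np.allclose(emb.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_estimator_wrapper_precomputed(self, rng):
        pts = rng.normal(size=(7, 2))
        est = NonmetricMDS(n_components=2, dissimilarity="precomputed",
                           random_state=0)
        coords = est.fit_transform(squareform(pdist(pts)))
        assert coords.shape == (7, 2)
        assert est.stress_ <= 1e-3
        assert est.get_params()["n_components"] == 2
        est.set_params(n_components=1)
        assert est.n_components == 1


def brute_force_upgma_height(D, cluster_a, cluster_b):
    """Mean pairwise distance between two leaf sets."""
    return float(
        np.mean([D[i, j] for i in cluster_a for j in cluster_b])
    )


class TestHierarchicalCluster:
    def test_hand_worked_three_sample_upgma(self):
        # d(A,B)=0.1, d(A,C)=0.5, d(B,C)=0.6 -> merge (A,B)@0.1 then @0.55
        from scipy.cluster import hierarchy

        D = DistanceMatrix(
            ids=["A", "B", "C"],
            values=np.array([[0, 0.1, 0.5], [0.1, 0, 0.6], [0.5, 0.6, 0]]),
        )
        Z = hierarchy.linkage(D.condensed(), method="average")
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.55)

    def test_identical_column_groups_merge_at_zero_first(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        m = pd.DataFrame({"a1": a, "a2": a, "b1": b, "b2": b})
        dendro = hierarchical_cluster(m)
        heights = dendro.heights
        assert heights[0] == pytest.approx(0.0, abs=1e-12)
        assert heights[1] == pytest.approx(0.0, abs=1e-12)
        assert heights[2] > 0

    def test_heights_equal_brute_force_cluster_means(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(30, 8)), columns=[f"s{i}" for i in range(8)]
        )
        D = correlation_distances(m)
        dendro = hierarchical_cluster(m)
        # replay merges, checking each height against the brute-force mean
        clusters = {i: [i] for i in range(8)}
        for merge_idx, (ia, ib, height, _) in enumerate(dendro.linkage):
            ca, cb = clusters.pop(int(ia)), clusters.pop(int(ib))
            expected = brute_force_upgma_height(D.values, ca, cb)
            assert height == pytest.approx(expected, abs=1e-10)
            clusters[8 + merge_idx] = ca + cb

    def test_heights_non_decreasing(self, default_cohort):
        _, ratios, _, truth = default_cohort
        dendro = hierarchical_cluster(
            ratios, probe_subset=truth.probes("SIGNATURE")
        )
        assert (np.diff(dendro.heights) >= -1e-12).all()

    def test_signature_probes_two_cluster_cut_separates_classes(
        self, default_cohort
    ):
        _, ratios, sheet, truth = default_cohort
        dendro = hierarchical_cluster(
            ratios, probe_subset=truth.probes("SIGNATURE")
        )
        cut = dendro.cut(2)
        by_group = cut.groupby(sheet.loc[cut.index])
        assert by_group.nunique().tolist() == [1, 1]
        assert cut[sheet == "ATC"].iloc[0] != cut[sheet == "PTC"].iloc[0]

    def test_empty_probe_subset_rejected(self, default_cohort):
        _, ratios, _, _ = default_cohort
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(ratios, probe_subset=[])

    def test_newick_export_contains_all_leaves(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)),
                         columns=["s1", "s2", "s3", "s4"])
        nwk = hierarchical_cluster(m).to_newick()
        assert nwk.endswith(";")
        for s in m.columns:
            assert s in nwk
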