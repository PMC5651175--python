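import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from esomix.io_formats import OmicsMatrix
from esomix.subtype_cluster import (
    CentroidSet,
    PlatformClustering,
    centroid_classify,
    hierarchical_cluster,
    integrate_clusters,
    mean_silhouette,
    select_features,
    transform_for_clustering,
    _sample_dissimilarity,
)


def matrix(values, scale="RPKM", prefix="S"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{i}" for i in range(values.shape[1])]), scale)


def ward_d2_oracle(d_square):
    """Brute-force ward.D2 agglomeration: O(n^3) Lance-Williams updates
    recomputed from the full matrix at every step."""
    n = d_square.shape[0]
    d = d_square.astype(float).copy()
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    heights = []
    current = {i: i for i in range(n)}
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                u, v = active[i], active[j]
                if best is None or d[u, v] < best[0]:
                    best = (d[u, v], u, v)
        h, u, v = best
        heights.append(h)
        nu, nv = sizes[u], sizes[v]
        new = max(sizes) + 1 if False else u  # reuse u's slot
        for w in active:
            if w in (u, v):
                continue
            nw = sizes[w]
            d2 = ((nu + nw) * d[u, w] ** 2 + (nv + nw) * d[v, w] ** 2
                  - nw * d[u, v] ** 2) / (nu + nv + nw)
            d[u, w] = d[w, u] = np.sqrt(max(d2, 0.0))
        sizes[u] = nu + nv
        active.remove(v)
    return np.array(heights)


class TestSelectFeatures:
    def test_mean_filter_then_fraction_of_all(self, caplog):
        rng = np.random.default_rng(0)
        values = rng.lognormal(1, 0.5, size=(100, 20))
        values[:30] *= 50  # 30 genes pass mean > 10
        m = matrix(values)
        with caplog.at_level("WARNING", logger="esomix"):
            feats = select_features(m, fraction=0.25, min_mean=10)
        # top 25% of 100 = 25 requested, 30 qualify -> 25 returned
        assert len(feats) == 25

    def test_cap_at_qualifying_features_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        values = rng.lognormal(1, 0.5, size=(100, 20))
        values[:10] *= 50  # only 10 qualify but 25 requested
        with caplog.at_level("WARNING", logger="esomix"):
            feats = select_features(matrix(values), fraction=0.25, min_mean=10)
        assert len(feats) == 10
        assert any("qualifying" in r.message for r in caplog.records)

    def test_constant_gene_never_selected_over_variable(self):
        values = np.vstack([np.full(10, 20.0),
                            20 + np.arange(10.0) * 3]).repeat(1, axis=0)
        feats = select_features(matrix(values), fraction=0.5, min_mean=10)
        assert feats == ["G1"]

    def test_planted_high_variance_genes_rank_first(self):
        rng = np.random.default_rng(2)
        values = np.abs(rng.normal(50, 0.5, size=(1000, 30)))
        hot = rng.choice(1000, 20, replace=False)
        values[hot] = np.abs(rng.normal(50, 30, size=(20, 30)))
        feats = select_features(matrix(values), fraction=0.02, min_mean=10)
        assert set(feats) == {f"G{i}" for i in hot}

    def test_no_qualifying_feature_is_error(self):
        with pytest.raises(ValueError, match="mean"):
            select_features(matrix(np.ones((5, 4))), min_mean=10)

    def test_top_n_override(self, expr_matrix_factory):
        m = expr_matrix_factory(n_genes=500)
        assert len(select_features(m, top_n=303, min_mean=0)) == 303


class TestTransform:
    def test_log_then_zscore_arithmetic(self):
        m = matrix([[0, 9, 99]])
        out = transform_for_clustering(m).values.to_numpy()[0]
        # log10 -> [0, 1, 2] -> z-scored (population sd) -> scaled
        expected = (np.array([0, 1, 2]) - 1) / np.std([0, 1, 2])
        np.testing.assert_allclose(out, expected)

    def test_constant_row_maps_to_zeros(self):
        out = transform_for_clustering(matrix([[5, 5, 5]])).values.to_numpy()
        np.testing.assert_array_equal(out, np.zeros((1, 3)))

    def test_scaled_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        m = matrix(rng.lognormal(2, 1, size=(50, 12)))
        out = transform_for_clustering(m).values.to_numpy()
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1), 1, atol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            transform_for_clustering(matrix([[-1, 2, 3]]))


class TestHierarchical:
    def test_identical_samples_merge_first_at_zero_height(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(30, 5))
        values[:, 3] = values[:, 0]  # S3 == S0
        pc = hierarchical_cluster(matrix(values, "zscore"), k=4)
        z = pc.linkage_matrix
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 3}

    def test_three_group_recovery(self):
        rng = np.random.default_rng(5)
        truth = np.repeat([0, 1, 2], 15)
        centers = rng.normal(0, 3, size=(40, 3))
        values = centers[:, truth] + rng.normal(0, 0.5, size=(40, 45))
        pc = hierarchical_cluster(matrix(values, "zscore"), k=3)
        assert adjusted_rand_score(truth, pc.labels.to_numpy()) >= 0.9

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(20, 10))
        m = matrix(values, "zscore")
        perm = list(np.random.default_rng(0).permutation(m.col_ids))
        pc1 = hierarchical_cluster(m, k=3)
        pc2 = hierarchical_cluster(m.subset_cols(perm), k=3)
        assert adjusted_rand_score(pc1.labels[m.col_ids],
                                   pc2.labels[m.col_ids]) == 1.0

    def test_zero_variance_sample_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(15, 6))
        values[:, 2] = 1.0
        with caplog.at_level("WARNING", logger="esomix"):
            pc = hierarchical_cluster(matrix(values, "zscore"), k=2)
        assert pc.excluded_samples == ["S2"]
        assert "S2" not in pc.labels.index

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(matrix(np.random.default_rng(0).normal(size=(5, 3)),
                                        "zscore"), k=4)

    def test_merge_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for n in (6, 9, 12):
            values = rng.normal(size=(25, n))
            m = matrix(values, "zscore")
            pc = hierarchical_cluster(m, k=2)
            d = squareform(_sample_dissimilarity(values, "correlation"))
            oracle = ward_d2_oracle(d)
            np.testing.assert_allclose(np.sort(pc.linkage_matrix[:, 2]),
                                       np.sort(oracle), rtol=1e-8)


class TestCentroidClassify:
    def make_centroids(self, rng, n_genes=100, subtypes=("basal", "classical",
                                                         "primitive", "secretory")):
        values = rng.normal(2, 1, size=(n_genes, len(subtypes)))
        return CentroidSet(pd.DataFrame(
            values, index=[f"G{i}" for i in range(n_genes)], columns=subtypes))

    def test_exact_centroid_gets_correlation_one(self):
        rng = np.random.default_rng(9)
        cents = self.make_centroids(rng)
        # build samples whose log2(x+1), median-centred profile equals
        # each centroid: invert the transform around a 2-sample design
        expr = 2 ** (cents.centroids.to_numpy() + 5.0) - 1
        m = matrix(expr)
        res = centroid_classify(m, cents)
        # medians over 4 columns shift profiles, but correlation with the
        # own centroid remains maximal
        assert (res["subtype"].to_numpy() == np.array(cents.centroids.columns)).all()

    def test_noise_recovery_95_percent(self):
        rng = np.random.default_rng(10)
        cents = self.make_centroids(rng, n_genes=200)
        truth, cols = [], {}
        for i in range(100):
            st = cents.centroids.columns[i % 4]
            truth.append(st)
            sd = cents.centroids[st].std()
            profile = cents.centroids[st] + rng.normal(0, 0.5 * sd, 200)
            cols[f"T{i}"] = 2 ** profile - 1
        m = OmicsMatrix(pd.DataFrame(cols).clip(lower=0), "RPKM")
        res = centroid_classify(m, cents)
        acc = (res["subtype"].to_numpy() == np.array(truth)).mean()
        assert acc >= 0.95

    def test_low_confidence_flag_for_anticorrelated_sample(self):
        rng = np.random.default_rng(11)
        cents = self.make_centroids(rng, n_genes=50, subtypes=("a", "b"))
        anti = 2 ** (10 - cents.centroids.min(axis=1)) - 1
        m = OmicsMatrix(pd.DataFrame({"T0": anti, "T1": anti * 1.5}).clip(lower=0),
                        "RPKM")
        res = centroid_classify(m, cents)
        assert res["low_confidence"].any() or (res["correlation"] < 0.5).all()

    def test_too_few_shared_genes_rejected(self):
        rng = np.random.default_rng(12)
        cents = self.make_centroids(rng, n_genes=5)
        m = matrix(rng.lognormal(2, 1, size=(5, 3)))
        with pytest.raises(ValueError, match="shared"):
            centroid_classify(m, cents, min_shared_genes=10)


def labelled(platform, labels_dict, k=None):
    s = pd.Series(labels_dict)
    return PlatformClustering(platform=platform, labels=s,
                              k=k or s.nunique())


class TestIntegration:
    def test_identical_labelings_reproduced(self):
        labels = {f"s{i}": (i % 3) + 1 for i in range(30)}
        res = integrate_clusters([labelled("a", labels), labelled("b", labels)],
                                 method="COCA", k=3)
        assert adjusted_rand_score(res.labels[list(labels)],
                                   pd.Series(labels)[list(labels)]) == 1.0

    def test_supercluster_duplication_invariance(self):
        rng = np.random.default_rng(13)
        truth = {f"s{i}": i % 3 for i in range(60)}

        def noisy():
            return {s: (l if rng.random() > 0.1 else int(rng.integers(3)))
                    for s, l in truth.items()}

        a, b = noisy(), noisy()
        base = integrate_clusters([labelled("a", a), labelled("b", b)],
                                  method="SuperCluster", k=3)
        dup = integrate_clusters([labelled("a", a), labelled("b", b),
                                  labelled("a2", a)],
                                 method="SuperCluster", k=3)
        samples = list(truth)
        assert adjusted_rand_score(base.labels[samples], dup.labels[samples]) == 1.0

    def test_supercluster_blocks_have_equal_total_variance(self):
        rng = np.random.default_rng(14)
        labels_a = {f"s{i}": i % 2 for i in range(40)}
        labels_b = {f"s{i}": i % 5 for i in range(40)}
        res = integrate_clusters([labelled("a", labels_a), labelled("b", labels_b)],
                                 method="SuperCluster", k=2)
        samples = sorted(labels_a)
        for pc, labels in [("a", labels_a), ("b", labels_b)]:
            block = pd.get_dummies(pd.Series(labels).astype(str)).astype(float)
            total = (block.var(axis=0, ddof=0).sum()) * res.weights[pc] ** 2
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_noisy_platforms_integrate_above_single_platform(self):
        # five platforms, as in a full multi-omic study (methylation,
        # SCNA, mRNA, miRNA, protein), each with 10% label noise
        rng = np.random.default_rng(15)
        truth = pd.Series({f"s{i}": i % 3 for i in range(90)})
        aris_int, aris_single = [], []
        for rep in range(5):
            platforms = []
            for p in range(5):
                noisy = {s: (l if rng.random() > 0.1 else int(rng.integers(3)))
                         for s, l in truth.items()}
                platforms.append(labelled(f"p{p}", noisy, k=3))
                aris_single.append(adjusted_rand_score(
                    truth[list(truth.index)], platforms[-1].labels[truth.index]))
            res = integrate_clusters(platforms, method="COCA", k=3)
            aris_int.append(adjusted_rand_score(truth[truth.index],
                                                res.labels[truth.index]))
        assert np.mean(aris_int) >= 0.9
        assert np.mean(aris_int) > np.mean(aris_single)

    def test_all_k1_platforms_rejected(self):
        one = {f"s{i}": 1 for i in range(10)}
        with pytest.raises(ValueError):
            integrate_clusters([labelled("a", one, k=1), labelled("b", one, k=1)],
                               method="COCA", k=2)

    def test_missing_samples_flagged(self):
        a = {f"s{i}": i % 2 for i in range(20)}
        b = {f"s{i}": i % 2 for i in range(15)}  # 5 samples missing
        res = integrate_clusters([labelled("a", a), labelled("b", b)],
                                 method="COCA", k=2)
        assert sorted(res.missing["b"]) == [f"s{i}" for i in range(15, 20)]
        assert set(res.labels.index) == set(a)


class TestNegativeControl:
    def test_no_structure_gives_low_silhouette(self, expr_matrix_factory):
        # two "subtypes" drawn from one distribution: no stable 2-split
        m = expr_matrix_factory(n_genes=300, n_samples=60, seed=16)
        trans = transform_for_clustering(m)
        pc = hierarchical_cluster(trans, k=2)
        d = squareform(_sample_dissimilarity(trans.values.to_numpy(),
                                             "correlation"))
        sil = mean_silhouette(d, pc.labels[list(trans.col_ids)].to_numpy())
        assert sil < 0.1
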