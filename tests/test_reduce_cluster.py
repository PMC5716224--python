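import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import cellpipe as cp
from cellpipe import CellpipeError
from cellpipe.reduce_cluster import default_perplexity

from conftest import make_matrix


def blobs(rng, k=3, per=20, dim=5, sep=5.0, sigma=0.1):
    centers = rng.normal(0, sep, (k, dim))
    # enforce pairwise separation
    while True:
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= sep:
            break
        centers = rng.normal(0, 2 * sep, (k, dim))
    X = np.concatenate([rng.normal(c, sigma, (per, dim)) for c in centers])
    labels = np.repeat(np.arange(1, k + 1), per)
    return X, labels


class TestSelectTopGenes:
    def test_keeps_highest_mean_genes(self, rng):
        m = make_matrix(rng.lognormal(0, 1, (1000, 5)))
        top = cp.select_top_genes(m, 500)
        kept = set(top.gene_ids)
        means = dict(zip(m.gene_ids, m.values.mean(axis=1)))
        worst_kept = min(means[g] for g in kept)
        best_dropped = max(means[g] for g in m.gene_ids if g not in kept)
        assert top.n_genes == 500
        assert worst_kept >= best_dropped

    def test_n_larger_than_gene_count_is_identity(self, rng):
        m = make_matrix(rng.random((10, 3)))
        assert cp.select_top_genes(m, 50) is m

    def test_boundary_tie_keeps_earlier_gene(self):
        X = np.array([[5.0], [1.0], [1.0], [0.5]])
        m = make_matrix(X)
        top = cp.select_top_genes(m, 2)
        assert top.gene_ids == ["g1", "g2"]


class TestCorrelationDistance:
    def test_affine_column_has_zero_distance(self, rng):
        a = rng.normal(0, 1, 50)
        m = make_matrix(np.column_stack([a, 2 * a + 3]),
                        value_space="normalized")
        d = cp.correlation_distance(m)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_column_has_distance_two(self, rng):
        a = rng.normal(0, 1, 50)
        m = make_matrix(np.column_stack([a, -a]), value_space="normalized")
        d = cp.correlation_distance(m)
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_independent_columns_near_one(self, rng):
        m = make_matrix(rng.normal(0, 1, (10000, 4)), value_space="normalized")
        d = cp.correlation_distance(m)
        off = d.values[np.triu_indices(4, 1)]
        assert np.all(np.abs(off - 1) < 0.05)

    def test_constant_column_is_named(self, rng):
        X = rng.normal(0, 1, (10, 3))
        X[:, 1] = 7.0
        with pytest.raises(CellpipeError, match="s2"):
            cp.correlation_distance(make_matrix(X, value_space="normalized"))

    def test_invariant_to_positive_affine_transforms(self, rng):
        X = rng.normal(0, 1, (60, 5))
        m1 = make_matrix(X, value_space="normalized")
        m2 = make_matrix(X * 3.5 + 2.0, value_space="normalized")
        d1 = cp.correlation_distance(m1)
        d2 = cp.correlation_distance(m2)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)


class TestPcaEmbed:
    def test_collinear_samples_have_zero_pc2(self, rng):
        t = rng.normal(0, 2, 10)
        direction = rng.normal(0, 1, 6)
        X = np.outer(direction, t)  # genes x samples, rank 1
        emb = cp.pca_embed(make_matrix(X, value_space="normalized"))
        assert np.max(np.abs(emb.coords[:, 1])) < 1e-9

    def test_duplicating_genes_keeps_score_directions(self, rng):
        X = rng.normal(0, 1, (20, 8))
        e1 = cp.pca_embed(make_matrix(X, value_space="normalized"))
        e2 = cp.pca_embed(make_matrix(np.vstack([X, X]),
                                      value_space="normalized"))
        for c in range(2):
            r = np.corrcoef(e1.coords[:, c], e2.coords[:, c])[0, 1]
            assert abs(r) > 1 - 1e-9

    def test_scores_are_uncorrelated(self, rng):
        X = rng.normal(0, 1, (30, 12))
        emb = cp.pca_embed(make_matrix(X, value_space="normalized"))
        cov = np.cov(emb.coords.T)
        assert abs(cov[0, 1]) < 1e-9


class TestTsneEmbed:
    def test_same_seed_identical(self, rng):
        m = make_matrix(rng.lognormal(0, 1, (50, 30)))
        d = cp.correlation_distance(m)
        a = cp.tsne_embed(d, seed=3, perplexity=5)
        b = cp.tsne_embed(d, seed=3, perplexity=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_perplexity_bound_enforced(self, rng):
        m = make_matrix(rng.lognormal(0, 1, (20, 12)))
        d = cp.correlation_distance(m)
        with pytest.raises(CellpipeError, match="perplexity"):
            cp.tsne_embed(d, seed=0, perplexity=12)

    def test_separated_clusters_stay_separated(self):
        # 3 well-separated expression clusters must map to embeddings
        # whose within-cluster distances fall below between-cluster ones
        for seed in range(3):
            r = np.random.default_rng(seed)
            shift = r.normal(0, 4, (3, 60))
            X = np.concatenate(
                [r.normal(shift[c], 0.3, (15, 60)) for c in range(3)]
            ).T  # genes x samples
            labels = np.repeat([0, 1, 2], 15)
            m = make_matrix(X, value_space="normalized")
            emb = cp.tsne_embed(cp.correlation_distance(m), seed=seed,
                                perplexity=10)
            D = np.linalg.norm(emb.coords[:, None] - emb.coords[None], axis=-1)
            same = labels[:, None] == labels[None]
            np.fill_diagonal(same, False)
            assert D[same].mean() < D[~same & ~np.eye(45, dtype=bool)].mean()


class TestClusterers:
    def test_kmeans_two_point_masses(self):
        X = np.vstack([np.zeros((10, 3)), np.ones((10, 3)) * 9])
        a = cp.cluster_kmeans(X, 2, seed=0)
        assert len(set(a.labels[:10])) == 1
        assert len(set(a.labels[10:])) == 1
        assert a.labels[0] != a.labels[10]
        assert a.labels[0] == 1  # renumbered by first occurrence

    def test_kmeans_k_equals_m(self, rng):
        X = rng.normal(0, 1, (6, 2))
        a = cp.cluster_kmeans(X, 6, seed=0)
        assert sorted(a.labels) == list(range(1, 7))

    def test_kmeans_blob_recovery_20_seeds(self):
        exact = 0
        for seed in range(20):
            X, truth = blobs(np.random.default_rng(seed))
            a = cp.cluster_kmeans(X, 3, seed=seed)
            exact += adjusted_rand_score(truth, a.labels) == 1.0
        assert exact == 20

    def test_kmeans_k_above_m_errors(self, rng):
        with pytest.raises(CellpipeError):
            cp.cluster_kmeans(rng.normal(0, 1, (4, 2)), 5, seed=0)

    def test_hclust_blob_recovery(self):
        X, truth = blobs(np.random.default_rng(11))
        a = cp.cluster_hclust(X, 3)
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_hclust_two_samples(self):
        a = cp.cluster_hclust(np.array([[0.0], [5.0]]), 2)
        assert sorted(a.labels) == [1, 2]

    def test_hclust_complete_linkage_line(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        a = cp.cluster_hclust(X, 2, linkage="complete")
        assert a.labels[0] == a.labels[1]
        assert a.labels[2] == a.labels[3]
        assert a.labels[0] != a.labels[2]

    def test_nmf_block_diagonal_recovery(self, rng):
        X = np.zeros((40, 20))
        X[:20, :10] = rng.lognormal(1, 0.2, (20, 10))
        X[20:, 10:] = rng.lognormal(1, 0.2, (20, 10))
        a = cp.cluster_nmf(make_matrix(X, value_space="log"), 2, seed=0)
        assert len(set(a.labels[:10])) == 1
        assert len(set(a.labels[10:])) == 1
        assert a.labels[0] != a.labels[10]

    def test_nmf_rejects_negative_values(self, rng):
        m = make_matrix(rng.normal(0, 1, (5, 5)), value_space="normalized")
        with pytest.raises(CellpipeError, match="non-negative"):
            cp.cluster_nmf(m, 2, seed=0)

    def test_argmax_tie_takes_lowest_component(self):
        col = np.array([0.4, 0.4, 0.2])
        assert int(np.argmax(col)) == 0  # the convention cluster_nmf relies on


class TestExplainedVariance:
    def _ev_oracle(self, X, labels):
        grand = X.mean(axis=0)
        total = sum(float(np.sum((x - grand) ** 2)) for x in X)
        within = 0.0
        for lab in set(labels):
            pts = X[np.array(labels) == lab]
            c = pts.mean(axis=0)
            within += sum(float(np.sum((p - c) ** 2)) for p in pts)
        return 1 - within / total

    def test_singleton_clusters_give_ev_one(self, rng):
        X = rng.normal(0, 1, (5, 2))
        a = cp.ClusterAssignment([f"s{i}" for i in range(5)],
                                 np.arange(1, 6), 5, "kmeans")
        assert cp.explained_variance(X, a) == pytest.approx(1.0)

    def test_single_cluster_gives_ev_zero(self, rng):
        X = rng.normal(0, 1, (6, 2))
        a = cp.ClusterAssignment([f"s{i}" for i in range(6)],
                                 np.ones(6, dtype=int), 1, "kmeans")
        assert cp.explained_variance(X, a) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            X = rng.normal(0, 1, (20, 3))
            labels = rng.integers(1, 4, 20)
            while len(set(labels.tolist())) < 3:
                labels = rng.integers(1, 4, 20)
            a = cp.ClusterAssignment([f"s{i}" for i in range(20)], labels, 3,
                                     "kmeans")
            assert cp.explained_variance(X, a) == pytest.approx(
                self._ev_oracle(X, labels.tolist()), abs=1e-10
            )

    def test_degenerate_data_errors(self):
        X = np.ones((4, 2))
        a = cp.ClusterAssignment(list("abcd"), np.array([1, 1, 2, 2]), 2,
                                 "kmeans")
        with pytest.raises(CellpipeError):
            cp.explained_variance(X, a)


def elbow_oracle(ks, ev, grid=4000):
    """Independent elbow search: beta fit by 1-D grid refinement."""
    ks = np.asarray(ks)
    ev = np.asarray(ev, dtype=float)
    sst = float(((ev - ev.mean()) ** 2).sum())
    if sst == 0:
        return int(ks.min())
    best_m, best_r2 = None, -np.inf
    for m in range(1, int(ks.max()) + 1):
        x = np.minimum(ks, m).astype(float)
        lo, hi = 0.0, max(1.0, 2 * float(np.abs(ev).max()))
        for _ in range(3):
            betas = np.linspace(lo, hi, grid)
            ssr = ((ev[None, :] - betas[:, None] * x[None, :]) ** 2).sum(axis=1)
            b = int(np.argmin(ssr))
            width = (hi - lo) / grid
            lo, hi = max(0.0, betas[b] - 2 * width), betas[b] + 2 * width
        r2 = 1 - ssr[b] / sst
        if r2 > best_r2 + 1e-9:
            best_m, best_r2 = m, r2
    return best_m


class TestElbowPoint:
    def test_exact_breakpoint_model(self):
        ks = list(range(2, 11))
        ev = [min(k, 5) / 10 for k in ks]
        m, r2 = cp.elbow_point(ks, ev)
        assert m == 5
        assert r2[5] == pytest.approx(1.0)

    def test_pure_linear_curve_selects_last_m(self):
        ks = list(range(2, 11))
        m, r2 = cp.elbow_point(ks, [k / 10 for k in ks])
        assert m == 10
        assert r2[10] == pytest.approx(1.0)

    def test_constant_curve_returns_min_k(self):
        assert cp.elbow_point(range(2, 11), [0.4] * 9)[0] == 2

    def test_fewer_than_three_points_error(self):
        with pytest.raises(CellpipeError):
            cp.elbow_point([2, 3], [0.1, 0.2])

    def test_matches_grid_search_oracle_on_random_curves(self):
        agree = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            ks = np.arange(2, 11)
            mstar = int(r.integers(3, 9))
            ev = np.clip(0.1 * np.minimum(ks, mstar) + r.normal(0, 0.02, 9),
                         0, 1)
            got, _ = cp.elbow_point(ks, ev)
            agree += got == elbow_oracle(ks, ev)
        assert agree >= 198  # grid refinement can land a hair off exact LS


class TestAutoCluster:
    def test_two_point_masses_select_k2(self, rng):
        X = np.vstack([np.zeros((8, 2)), np.full((8, 2), 10.0)])
        X += rng.normal(0, 1e-6, X.shape)
        a, prof = cp.auto_cluster(X, "kmeans", seed=0, k_range=range(2, 9))
        assert prof.elbow == 2
        assert a.k == 2

    def test_four_blobs_recovered(self):
        hits = 0
        for seed in range(5):
            X, truth = blobs(np.random.default_rng(100 + seed), k=4, per=10)
            a, prof = cp.auto_cluster(X, "kmeans", seed=seed,
                                      k_range=range(2, 9))
            if prof.elbow == 4 and adjusted_rand_score(truth, a.labels) == 1.0:
                hits += 1
        assert hits >= 4

    def test_k_range_above_sample_count_errors(self, rng):
        X = rng.normal(0, 1, (5, 2))
        with pytest.raises(CellpipeError):
            cp.auto_cluster(X, "kmeans", seed=0, k_range=range(2, 11))

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(0, 1, (30, 2))
        a1, p1 = cp.auto_cluster(X, "kmeans", seed=5, k_range=range(2, 6))
        a2, p2 = cp.auto_cluster(X, "kmeans", seed=5, k_range=range(2, 6))
        np.testing.assert_array_equal(a1.labels, a2.labels)
        assert p1.ev == p2.ev

    def test_default_perplexity_respects_bound(self):
        for m in [7, 10, 31, 92, 300]:
            assert default_perplexity(m) < (m - 1) / 3
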