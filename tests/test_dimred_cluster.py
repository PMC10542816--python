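import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from cryptshift import (
    GeneSetCollection,
    NormalizedMatrix,
    annotate_clusters,
    annotated_types,
    density_shift_1d,
    kmeans_cluster,
    normalize_log,
    run_pca,
    select_hvg_mvp,
    select_hvg_vst,
    snn_cluster,
    subcluster,
)

from conftest import make_embedding, make_umi


def make_nm(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return NormalizedMatrix(
        values=np.log10(1 + values),
        cell_ids=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        gene_ids=np.array(
            [f"g{j}" for j in range(n_genes)] if gene_ids is None else gene_ids,
            dtype=object,
        ),
        metadata={"mode": "scale_to_median", "log_base": "10",
                  "pseudocount": 1.0, "target": 100.0},
    )


class TestHvgMvp:
    def test_null_selection_matches_normal_tail(self, rng):
        # i.i.d. genes: selected fraction ~ P(Z > 0.9)
        vals = rng.poisson(5.0, (400, 2000))
        nm = make_nm(vals)
        fs = select_hvg_mvp(nm, mean_low=0.0, mean_high=np.inf)
        frac = len(fs.selected) / 2000
        assert abs(frac - (1 - stats.norm.cdf(0.9))) < 0.05

    def test_inflated_dispersion_recall(self, rng):
        n_cells, n_genes = 400, 2000
        vals = rng.poisson(5.0, (n_cells, n_genes)).astype(float)
        # 100 genes with ~5x inflated dispersion at the same mean
        hot = rng.choice(n_genes, 100, replace=False)
        g = rng.gamma(1.25, 0.8, (n_cells, 100))  # mean 1, variance 0.8
        vals[:, hot] = rng.poisson(5.0 * g)
        nm = make_nm(vals)
        fs = select_hvg_mvp(nm, mean_low=0.0, mean_high=np.inf)
        recall = len(set(fs.selected) & {f"g{j}" for j in hot}) / 100
        assert recall >= 0.9

    def test_constant_matrix_selects_nothing(self):
        nm = make_nm(np.full((50, 40), 3.0))
        fs = select_hvg_mvp(nm, n_bins=5, mean_low=0.0, mean_high=np.inf)
        assert fs.selected == []

    def test_bins_are_equal_frequency(self, rng):
        vals = rng.poisson(4.0, (100, 207))
        nm = make_nm(vals)
        n_bins = 20
        mean = (10 ** nm.values - 1).mean(axis=0)
        order = np.argsort(mean[mean > 0], kind="stable")
        sizes = [len(c) for c in np.array_split(order, n_bins)]
        assert max(sizes) - min(sizes) <= 1


class TestHvgVst:
    def test_on_trend_genes_standardize_to_one(self, rng):
        # all genes drawn from the same family: standardized variances stay
        # near 1 and no gene dominates
        vals = rng.poisson(rng.uniform(1, 20, 2000)[None, :].repeat(500, 0))
        nm = make_nm(vals)
        fs = select_hvg_vst(nm, n_select=100)
        sv = fs.dispersion[fs.dispersion > 0]
        assert np.median(sv) == pytest.approx(1.0, abs=0.3)
        assert np.max(sv) / np.median(sv) <= 2.5

    def test_spiked_variance_genes_rank_top(self, rng):
        n_cells, n_genes = 500, 2000
        means = rng.uniform(1, 20, n_genes)
        vals = rng.poisson(means[None, :].repeat(n_cells, 0)).astype(float)
        hot = rng.choice(n_genes, 50, replace=False)
        g = rng.gamma(0.1, 10.0, (n_cells, 50))  # 10x inflated variance
        vals[:, hot] = rng.poisson(means[hot][None, :] * g)
        nm = make_nm(vals)
        fs = select_hvg_vst(nm, n_select=100)
        assert {f"g{j}" for j in hot} <= set(fs.selected)

    def test_select_all_genes(self, rng):
        nm = make_nm(rng.poisson(5.0, (50, 30)))
        fs = select_hvg_vst(nm, n_select=30)
        assert sorted(fs.selected) == sorted(nm.gene_ids)

    def test_n_select_too_large_rejected(self, rng):
        nm = make_nm(rng.poisson(5.0, (50, 30)))
        with pytest.raises(ValueError, match="n_select"):
            select_hvg_vst(nm, n_select=31)


class TestPca:
    def test_two_cells_single_component_along_difference(self):
        nm = make_nm([[1, 5, 2], [3, 1, 4]])
        emb = run_pca(nm, center=True, scale=False, n_components=5)
        assert emb.scores.shape[1] == 1
        diff = nm.values[1] - nm.values[0]
        cos = np.abs(
            emb.loadings[:, 0] @ diff / np.linalg.norm(diff)
        )
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_reconstruction(self, rng):
        vals = rng.poisson(10.0, (15, 8))
        nm = make_nm(vals)
        emb = run_pca(nm, center=True, scale=True, n_components=8)
        X = nm.values
        sd = X.std(axis=0, ddof=1)
        Xc = (X - X.mean(axis=0)) / sd
        np.testing.assert_allclose(
            emb.scores @ emb.loadings.T, Xc, atol=1e-8
        )
        assert emb.explained_variance.sum() <= Xc.var(axis=0, ddof=1).sum() + 1e-8

    def test_duplicated_cells_keep_directions(self, rng):
        vals = rng.poisson(10.0, (40, 12))
        nm1 = make_nm(vals)
        nm2 = make_nm(np.vstack([vals, vals]))
        e1 = run_pca(nm1, n_components=3)
        e2 = run_pca(nm2, n_components=3)
        for j in range(3):
            cos = abs(e1.loadings[:, j] @ e2.loadings[:, j])
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_genes_dropped_with_warning(self, rng):
        vals = rng.poisson(10.0, (20, 5)).astype(float)
        vals[:, 2] = 7.0
        nm = make_nm(vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            emb = run_pca(nm, n_components=2)
        assert "g2" not in list(emb.gene_ids)

    def test_single_cell_rejected(self):
        nm = make_nm([[1, 2, 3]])
        with pytest.raises(ValueError, match="2 cells"):
            run_pca(nm)


def three_blobs(rng, n_per=50, sep=12, dim=4):
    centers = np.array([[0] * dim, [sep] + [0] * (dim - 1),
                        [0, sep] + [0] * (dim - 2)], dtype=float)
    pts = np.vstack([rng.normal(c, 1.0, (n_per, dim)) for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return make_embedding(pts), labels


class TestKmeans:
    def test_k1_wss_equals_total_ss(self, rng):
        emb = make_embedding(rng.normal(0, 1, (30, 3)))
        a = kmeans_cluster(emb, k=1, seed=0)
        assert a.k == 1 and set(a.labels) == {1}

    def test_separated_blobs_recovered(self, rng):
        emb, truth = three_blobs(rng)
        a = kmeans_cluster(emb, k=3, seed=1)
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_best_of_n_init_beats_single_starts(self, rng):
        from sklearn.cluster import KMeans

        emb, _ = three_blobs(rng, n_per=30)
        a = kmeans_cluster(emb, k=3, n_init=10, seed=5)
        best = KMeans(n_clusters=3, n_init=10, random_state=5,
                      algorithm="lloyd").fit(emb.scores).inertia_
        for s in range(5):
            single = KMeans(n_clusters=3, n_init=1, random_state=s,
                            algorithm="lloyd").fit(emb.scores).inertia_
            assert best <= single + 1e-9

    def test_invalid_k(self, rng):
        emb = make_embedding(rng.normal(0, 1, (10, 2)))
        with pytest.raises(ValueError):
            kmeans_cluster(emb, k=0)


class TestSubcluster:
    def test_two_cells_split_into_singletons(self):
        emb = make_embedding([[0.0, 0.0], [10.0, 0.0]])
        base = kmeans_cluster(emb, k=1, seed=0)
        out = subcluster(emb, base, cluster_id=1, k2=2, seed=0)
        assert out.k == 2
        assert sorted(out.labels) == [1, 2]

    def test_merged_blobs_recovered_and_others_untouched(self, rng):
        emb, truth = three_blobs(rng)
        base = kmeans_cluster(emb, k=3, seed=1)
        # merge clusters of blob 0 and 1 artificially
        lab0 = base.labels[0]
        lab1 = base.labels[50]
        merged = base.labels.copy()
        merged[merged == lab1] = lab0
        # relabel to contiguous 1..2
        uniq = {l: i + 1 for i, l in enumerate(sorted(set(merged)))}
        merged = np.array([uniq[l] for l in merged])
        from cryptshift.dimred_cluster import ClusterAssignment

        base2 = ClusterAssignment(labels=merged, k=2, method="kmeans", seed=0)
        out = subcluster(emb, base2, cluster_id=uniq[lab0], k2=2, seed=2)
        assert adjusted_rand_score(truth, out.labels) == 1.0
        outside = merged != uniq[lab0]
        np.testing.assert_array_equal(
            out.labels[outside], merged[outside]
        )

    def test_too_small_cluster_rejected(self, rng):
        emb = make_embedding(rng.normal(0, 1, (5, 2)))
        base = kmeans_cluster(emb, k=5, seed=0)
        some = int(base.labels[0])
        with pytest.raises(ValueError, match="cells"):
            subcluster(emb, base, cluster_id=some, k2=2)


class TestSnn:
    def test_two_disconnected_blobs_two_communities(self, rng):
        pts = np.vstack(
            [rng.normal(0, 1, (30, 5)), rng.normal(60, 1, (30, 5))]
        )
        a = snn_cluster(make_embedding(pts), k_neighbors=20)
        assert a.k == 2
        assert len(set(a.labels[:30])) == 1 and len(set(a.labels[30:])) == 1

    def test_uniform_cloud_single_community(self, rng):
        # one tight isotropic cloud: near-complete SNN graph, one community
        pts = rng.normal(0, 0.01, (25, 3))
        a = snn_cluster(make_embedding(pts), k_neighbors=24)
        assert a.k == 1

    def test_cell_order_invariance(self, rng):
        pts = np.vstack(
            [rng.normal(0, 1, (30, 4)), rng.normal(30, 1, (30, 4))]
        )
        perm = rng.permutation(60)
        a = snn_cluster(make_embedding(pts), k_neighbors=15)
        b = snn_cluster(make_embedding(pts[perm]), k_neighbors=15)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_invalid_k_neighbors(self, rng):
        emb = make_embedding(rng.normal(0, 1, (10, 2)))
        with pytest.raises(ValueError, match="k_neighbors"):
            snn_cluster(emb, k_neighbors=1)


class TestAnnotate:
    def _cluster_data(self, rng, fold=4.0):
        # two clusters; cluster 2 overexpresses the ILC2 set
        base = np.full((60, 6), 5.0)
        base[30:, :3] *= fold
        vals = rng.poisson(base)
        nm = make_nm(vals, gene_ids=[f"ilc2_g{i}" for i in range(3)]
                     + [f"other_g{i}" for i in range(3)])
        from cryptshift.dimred_cluster import ClusterAssignment

        assign = ClusterAssignment(
            labels=np.repeat([1, 2], 30), k=2, method="kmeans", seed=0
        )
        return nm, assign

    def test_overexpressed_set_wins(self, rng):
        nm, assign = self._cluster_data(rng)
        ref = GeneSetCollection(
            {"ILC2": [f"ilc2_g{i}" for i in range(3)],
             "Other": [f"other_g{i}" for i in range(3)]}
        )
        out = annotate_clusters(nm, assign, ref)
        assert out.annotation[2] == "ILC2"
        assert annotated_types(out)[-1] == "ILC2"

    def test_tie_breaks_lexicographically_and_flags(self, rng):
        nm, assign = self._cluster_data(rng, fold=1.0)
        # identical gene lists under two names: scores tie exactly
        genes = [f"ilc2_g{i}" for i in range(3)]
        ref = GeneSetCollection({"B_set": genes, "A_set": genes})
        out = annotate_clusters(nm, assign, ref)
        assert out.annotation[1] == "A_set"
        assert out.annotation_scores[1]["tie"]

    def test_single_reference_set_labels_everything(self, rng):
        nm, assign = self._cluster_data(rng)
        ref = GeneSetCollection({"Only": ["ilc2_g0", "other_g0"]})
        out = annotate_clusters(nm, assign, ref)
        assert set(out.annotation.values()) == {"Only"}

    def test_disjoint_reference_rejected(self, rng):
        nm, assign = self._cluster_data(rng)
        ref = GeneSetCollection({"X": ["nope1", "nope2", "nope3"]})
        with pytest.raises(ValueError, match="no reference gene"):
            annotate_clusters(nm, assign, ref)


class TestDensityShift:
    def test_identical_samples_null(self, rng):
        v = rng.normal(0, 1, 40)
        pts = np.concatenate([v, v])[:, None]
        emb = make_embedding(np.hstack([pts, np.zeros_like(pts)]))
        cond = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        ds = density_shift_1d(emb, axis=1, cell_mask=np.ones(80, bool),
                              condition_label=cond)
        assert ds.median_difference == 0.0
        assert ds.p_value == pytest.approx(1.0)

    def test_planted_shift_detected(self, rng):
        x = rng.normal(0, 1, 300)
        y = rng.normal(1, 1, 300)
        pts = np.concatenate([x, y])[:, None]
        emb = make_embedding(np.hstack([pts, np.zeros_like(pts)]))
        cond = np.array(["young"] * 300 + ["old"] * 300, dtype=object)
        ds = density_shift_1d(emb, axis=1, cell_mask=np.ones(600, bool),
                              condition_label=cond)
        assert ds.p_value < 0.01
        assert abs(ds.median_difference) == pytest.approx(1.0, abs=0.35)
        for dens in ds.densities.values():
            assert np.trapezoid(dens, ds.grid) == pytest.approx(1.0, abs=1e-3)

    def test_sparse_condition_rejected(self, rng):
        pts = rng.normal(0, 1, (15, 2))
        cond = np.array(["a"] * 9 + ["b"] * 6, dtype=object)
        with pytest.raises(ValueError, match="fewer than 10"):
            density_shift_1d(make_embedding(pts), axis=1,
                             cell_mask=np.ones(15, bool),
                             condition_label=cond)


def test_pipeline_pieces_compose(rng):
    """Normalization feeds PCA feeds clustering on a small simulated cohort."""
    from dataclasses import replace

    from cryptshift import make_preset, simulate_counts

    spec = replace(make_preset("organoid7"), n_cells_per_condition=150)
    m, truth = simulate_counts(spec, seed=21)
    nm = normalize_log(m)
    emb = run_pca(nm, n_components=10)
    a = kmeans_cluster(emb, k=7, seed=3)
    assert adjusted_rand_score(truth.cell_type, a.labels) >= 0.7
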