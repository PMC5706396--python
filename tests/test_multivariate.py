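import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans as SKKMeans
from sklearn.decomposition import PCA as SKPCA
from sklearn.metrics import adjusted_rand_score

import ramancell as rc
from ramancell.errors import DataError, DimensionError, ParameterError
from ramancell.synthetic_scene import REGION_CODES


def tiny_dataset(X, axis=None, map_id="m0", h=None, w=None):
    """Wrap a row matrix as a single-map PooledDataset."""
    X = np.asarray(X, float)
    n, b = X.shape
    if h is None:
        h, w = 1, n
    axis = axis or rc.WavenumberAxis(400.0 + 10.0 * np.arange(b))
    rr, cc = np.divmod(np.arange(n), w)
    return rc.PooledDataset(
        X=X,
        axis=axis,
        provenance=pd.DataFrame({"map_id": map_id, "row": rr, "col": cc}),
        map_info={map_id: rc.MapMetadata(map_id=map_id)},
        map_shapes={map_id: (h, w)},
    )


class TestPooling:
    def test_two_maps_pool_with_provenance(self):
        axis = rc.WavenumberAxis(np.array([400.0, 500.0]))
        maps = [
            rc.SpectralMap(axis, np.arange(8, dtype=float).reshape(2, 2, 2),
                           rc.MapMetadata(map_id=f"m{i}"))
            for i in range(2)
        ]
        ds = rc.pool_maps(maps)
        assert ds.n_rows == 8
        assert list(ds.provenance["map_id"].unique()) == ["m0", "m1"]
        # row-major provenance round trip
        first = ds.provenance.iloc[1]
        assert (first["row"], first["col"]) == (0, 1)
        assert np.array_equal(ds.X[ds.rows_of("m1")], maps[1].pixels())

    def test_single_map_is_its_pixel_list(self):
        axis = rc.WavenumberAxis(np.array([400.0, 500.0, 600.0]))
        m = rc.SpectralMap(axis, np.random.default_rng(0).normal(size=(3, 2, 3)))
        ds = rc.pool_maps([m])
        assert np.array_equal(ds.X, m.pixels())

    def test_axis_mismatch_names_offender(self):
        a1 = rc.WavenumberAxis(np.array([400.0, 500.0]))
        a2 = rc.WavenumberAxis(np.array([400.0, 501.0]))
        maps = [
            rc.SpectralMap(a1, np.zeros((1, 1, 2)), rc.MapMetadata(map_id="ok")),
            rc.SpectralMap(a2, np.zeros((1, 1, 2)), rc.MapMetadata(map_id="bad")),
        ]
        with pytest.raises(DimensionError, match="bad"):
            rc.pool_maps(maps)


class TestPCA:
    def test_diagonal_line_dataset_by_hand(self):
        """Rows (0,0),(1,1),(2,2): PC1 ∝ (1,1)/√2 carries all variance."""
        ds = tiny_dataset([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        model = rc.fit_pca(ds)
        assert np.allclose(np.abs(model.loadings[0]), 1 / np.sqrt(2))
        assert model.loadings[0][0] > 0  # sign convention
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)
        assert model.explained_variance[0] == pytest.approx(2.0)  # var of ±1·√2

    def test_constant_rows_degenerate(self):
        ds = tiny_dataset(np.ones((4, 3)))
        with pytest.warns(UserWarning, match="zero variance"):
            model = rc.fit_pca(ds)
        assert model.degenerate
        assert np.allclose(model.explained_variance, 0.0)

    def test_matches_dense_eigensolver_and_sklearn(self):
        """Loadings/variances agree with an independent covariance
        eigendecomposition and with sklearn's SVD-based PCA."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 20)) @ rng.normal(size=(20, 20))
        model = rc.fit_pca(tiny_dataset(X))
        cov = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        assert np.allclose(model.explained_variance, evals, rtol=1e-10)
        for i in range(20):
            cos = abs(model.loadings[i] @ evecs[:, i])
            assert cos > 1 - 1e-8
        sk = SKPCA(n_components=20).fit(X)
        assert np.allclose(model.explained_variance, sk.explained_variance_,
                           rtol=1e-8)
        # orthonormality and variance conservation
        gram = model.loadings @ model.loadings.T
        assert np.allclose(gram, np.eye(20), atol=1e-8)
        assert model.explained_variance.sum() == pytest.approx(
            np.trace(cov), rel=1e-10
        )

    def test_projection_centering_and_parseval(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 8))
        ds = tiny_dataset(X)
        model = rc.fit_pca(ds)
        assert np.allclose(
            rc.project(model.mean_spectrum[None, :], model, K=8), 0.0, atol=1e-9
        )
        scores = rc.project(ds, model, K=8)
        centered = X - model.mean_spectrum
        assert np.allclose(
            np.sum(scores**2, axis=1), np.sum(centered**2, axis=1), rtol=1e-10
        )
        with pytest.raises(ParameterError):
            rc.project(ds, model, K=9)

    def test_dna_rich_pixels_displaced_along_dna_loading(
        self, discrimination_analysis, components
    ):
        """Score scatter: nucleoid pixels sit high on the PC whose loading
        most resembles the DNA component spectrum."""
        ds = discrimination_analysis["dataset"]
        truths = discrimination_analysis["truths"]
        model = rc.fit_pca(ds)
        scores = rc.project(ds, model, K=6)
        dna = components["dna_rna"].evaluate(ds.axis)
        corr = [
            abs(np.corrcoef(model.loadings[i], dna)[0, 1]) for i in range(6)
        ]
        pc = int(np.argmax(corr))
        sign = np.sign(np.corrcoef(model.loadings[pc], dna)[0, 1])
        truth_all = np.concatenate([t.region_label.ravel() for t in truths])
        nuc = truth_all == REGION_CODES["nucleoid"]
        other = (truth_all != REGION_CODES["nucleoid"]) & (truth_all != 0)
        assert (sign * scores[nuc, pc]).mean() > (sign * scores[other, pc]).mean()


class TestKMeans:
    def test_two_well_separated_pairs_in_1d(self):
        """{0,1,10,11} with k=2: the optimum is {0,1}|{10,11}."""
        model = rc.fit_kmeans(np.array([0.0, 1.0, 10.0, 11.0]), k=2, seed=0)
        labels = model.labels
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert sorted(model.centroids.ravel()) == pytest.approx([0.5, 10.5])
        assert model.inertia == pytest.approx(1.0)  # 4 × 0.5²

    def test_k_equal_to_distinct_points_gives_zero_inertia(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5]])
        model = rc.fit_kmeans(pts, k=4, seed=1)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ParameterError):
            rc.fit_kmeans(np.zeros((3, 2)), k=4, seed=0)

    def test_planted_blobs_recovered_every_seed(self):
        """3 Gaussian blobs at 10σ mutual distance: ARI = 1 for 10 seeds."""
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
            truth = np.repeat([0, 1, 2], 40)
            pts = centers[truth] + rng.normal(0, 1.0, (120, 2))
            model = rc.fit_kmeans(pts, k=3, seed=seed, n_restarts=10)
            assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_inertia_monotone_and_best_of_restarts(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(200, 4))
        best = rc.fit_kmeans(pts, k=5, seed=0, n_restarts=15)
        assert all(
            b <= a + 1e-12
            for a, b in zip(best.inertia_history, best.inertia_history[1:])
        )
        # the first restart of the seed-s stream is a prefix of the
        # 15-restart run with the same seed, so best-of-restarts can only
        # improve on it
        for s in range(5):
            single = rc.fit_kmeans(pts, k=5, seed=s, n_restarts=1).inertia
            multi = rc.fit_kmeans(pts, k=5, seed=s, n_restarts=15).inertia
            assert multi <= single + 1e-9

    def test_matches_sklearn_inertia(self):
        """Independent cross-check: our best-of-restarts optimum is at
        least as good as sklearn's, and the two agree closely."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(300, 3))
        ours = rc.fit_kmeans(pts, k=4, seed=0, n_restarts=20)
        sk = SKKMeans(n_clusters=4, n_init=20, random_state=0).fit(pts)
        assert ours.inertia <= sk.inertia_ * (1 + 1e-9)
        assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-2)


class TestOutsideCluster:
    def test_noise_free_outside_recovery(self, quiet_scene_map):
        smap, scene = quiet_scene_map
        from conftest import analyze_experiment

        ds, km, summary, truths = analyze_experiment([(smap, scene)], seed=0)
        outside_pred = km.labels == km.outside_id
        outside_true = truths[0].region_label.ravel() == 0
        assert np.array_equal(outside_pred, outside_true)

    def test_all_cell_crop_warns_but_returns(self):
        rng = np.random.default_rng(9)
        X = 5.0 + rng.normal(0, 0.01, (40, 6))
        ds = tiny_dataset(X)
        model = rc.fit_kmeans(rng.normal(size=(40, 2)), k=2, seed=0)
        with pytest.warns(UserWarning, match="dim"):
            out = rc.identify_outside_cluster(model, ds)
        assert out in (0, 1)

    def test_exact_tie_is_pathological(self):
        X = np.ones((4, 3))
        X[:2] *= 2.0
        ds = tiny_dataset(np.vstack([X[:2], X[:2]]))
        model = rc.ClusterModel(
            k=2, centroids=np.zeros((2, 1)),
            labels=np.array([0, 0, 1, 1]), inertia=0.0, seed=0, n_restarts=1,
        )
        with pytest.raises(DataError, match="tie"):
            rc.identify_outside_cluster(model, ds)


class TestClusterOutputs:
    def test_cluster_map_provenance_round_trip(self, discrimination_analysis):
        ds = discrimination_analysis["dataset"]
        km = discrimination_analysis["kmeans"]
        map_id = next(iter(ds.map_shapes))
        _, labels = rc.make_cluster_map(km, ds, map_id)
        rows = ds.rows_of(map_id)
        prov = ds.provenance.iloc[rows]
        for i in (0, 57, 500):
            r, c = prov.iloc[i]["row"], prov.iloc[i]["col"]
            assert labels[r, c] == km.labels[rows[i]]

    def test_unknown_map_id_rejected(self, discrimination_analysis):
        with pytest.raises(DataError):
            rc.make_cluster_map(
                discrimination_analysis["kmeans"],
                discrimination_analysis["dataset"],
                "no_such_map",
            )

    def test_palette_must_be_injective(self, discrimination_analysis):
        ds = discrimination_analysis["dataset"]
        km = discrimination_analysis["kmeans"]
        map_id = next(iter(ds.map_shapes))
        palette = {j: (1.0, 0.0, 0.0) for j in range(km.k)}
        with pytest.raises(ParameterError):
            rc.make_cluster_map(km, ds, map_id, palette=palette)

    def test_color_assignment_covers_all_semantics(self, discrimination_analysis):
        colors = discrimination_analysis["summary"].colors
        assert sorted(colors.values()) == sorted(
            ["outside", "red", "dark_red", "yellow", "blue", "green", "dark_green"]
        )

    def test_red_cluster_overlaps_planted_nucleoids(self, discrimination_analysis):
        """Pixels of the red (DNA) cluster lie in nucleoid/rim regions with
        precision ≥ 0.8 on the iPSC-like maps."""
        ds = discrimination_analysis["dataset"]
        km = discrimination_analysis["kmeans"]
        colors = discrimination_analysis["summary"].colors
        red = next(j for j, c in colors.items() if c == "red")
        truths = discrimination_analysis["truths"]
        truth_all = np.concatenate([t.region_label.ravel() for t in truths])
        line_all = np.concatenate(
            [[ds.map_info[mid].line_label] * (s[0] * s[1])
             for mid, s in ds.map_shapes.items()]
        )
        sel = (km.labels == red) & (line_all == "hiPSC-like")
        assert sel.sum() > 0
        nuclear = np.isin(
            truth_all[sel],
            [REGION_CODES["nucleoid"], REGION_CODES["nucleoid_rim"]],
        )
        assert nuclear.mean() >= 0.8

    def test_red_cluster_mean_spectrum_has_dna_bands(self, discrimination_analysis):
        """The red cluster's mean spectrum dominates the others at the
        785 and 1575 cm⁻¹ nucleic-acid bands."""
        summary = discrimination_analysis["summary"]
        ds = discrimination_analysis["dataset"]
        red = next(j for j, c in summary.colors.items() if c == "red")
        for target in (785.0, 1575.0):
            band = int(np.argmin(np.abs(ds.axis.values - target)))
            others = [
                summary.spectra[j, band]
                for j in range(summary.spectra.shape[0])
                if j not in (red, summary.outside_id)
            ]
            assert summary.spectra[red, band] > max(others)

    def test_mean_spectra_definitions(self):
        X = np.array([[1.0, 3.0], [5.0, 7.0], [9.0, 11.0]])
        ds = tiny_dataset(X)
        model = rc.ClusterModel(
            k=2, centroids=np.zeros((2, 1)),
            labels=np.array([0, 1, 1]), inertia=0.0, seed=0, n_restarts=1,
        )
        means = rc.cluster_mean_spectra(model, ds)
        assert np.allclose(means[0], X[0])
        assert np.allclose(means[1], (X[1] + X[2]) / 2)


class TestPercentAreas:
    def test_hand_counted_percentages(self):
        X = np.ones((5, 2)) * np.arange(5)[:, None]
        ds = tiny_dataset(X)
        model = rc.ClusterModel(
            k=4, centroids=np.zeros((4, 1)),
            labels=np.array([3, 0, 0, 1, 2]), inertia=0.0, seed=0, n_restarts=1,
            outside_id=3,
        )
        areas = rc.percent_areas(model, ds)
        got = areas.set_index("cluster")["percent"]
        assert got[0] == pytest.approx(50.0)
        assert got[1] == pytest.approx(25.0)
        assert got[2] == pytest.approx(25.0)
        assert areas["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_per_map_percentages_sum_to_100(self, discrimination_analysis):
        areas = discrimination_analysis["summary"].areas
        sums = areas.groupby("map_id")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)
        counts = areas.groupby("map_id")["pixel_count"].sum()
        km = discrimination_analysis["kmeans"]
        ds = discrimination_analysis["dataset"]
        for mid, total in counts.items():
            rows = ds.rows_of(mid)
            in_cell = np.sum(km.labels[rows] != km.outside_id)
            assert total == in_cell


class TestGroupComparison:
    def test_textbook_pooled_t(self):
        """{10,12,11} vs {20,22,21}: t = −10/√(2/3) ≈ −12.247, df 4."""
        areas = pd.DataFrame(
            {
                "map_id": list("abcdef"),
                "line_label": ["A"] * 3 + ["B"] * 3,
                "cluster": 0,
                "pixel_count": 1,
                "percent": [10.0, 12.0, 11.0, 20.0, 22.0, 21.0],
            }
        )
        g = rc.compare_groups(areas, cluster=0)
        assert g.mean_a == pytest.approx(11.0)
        assert g.mean_b == pytest.approx(21.0)
        assert g.sem_a == pytest.approx(1.0 / np.sqrt(3))
        assert g.t_statistic == pytest.approx(-10.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert g.df == 4
        assert 0 < g.p_value < 1e-3

    def test_identical_groups_give_t_zero_p_one(self):
        areas = pd.DataFrame(
            {
                "map_id": list("abcd"),
                "line_label": ["A", "A", "B", "B"],
                "cluster": 0,
                "pixel_count": 1,
                "percent": [5.0, 7.0, 5.0, 7.0],
            }
        )
        g = rc.compare_groups(areas, cluster=0)
        assert g.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert g.p_value == pytest.approx(1.0)

    def test_single_map_group_rejected(self):
        areas = pd.DataFrame(
            {
                "map_id": list("abc"),
                "line_label": ["A", "B", "B"],
                "cluster": 0,
                "pixel_count": 1,
                "percent": [5.0, 6.0, 7.0],
            }
        )
        with pytest.raises(DataError):
            rc.compare_groups(areas, cluster=0)

    def test_bonferroni_column_bounded(self, discrimination_analysis):
        comp = rc.compare_all_clusters(discrimination_analysis["summary"].areas)
        assert (comp["p_bonferroni"] <= 1.0).all()
        assert (comp["p_bonferroni"] >= comp["p"] - 1e-15).all()
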