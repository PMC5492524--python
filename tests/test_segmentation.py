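import numpy as np
import pytest

from agaveseg.segmentation import (
    NODATA_LABEL,
    kmeans_fit,
    kmeans_predict,
    map_clusters_to_classes,
    segment_orthomosaic,
)


def brute_force_inertia(points: np.ndarray, k: int) -> float:
    """Exhaustive-assignment optimum: enumerate every labeling of n points.

    Independent of the Lloyd implementation; feasible for k**n up to ~1e5.
    """
    n = len(points)
    assignments = np.stack(
        np.meshgrid(*([np.arange(k)] * n), indexing="ij"), axis=-1
    ).reshape(-1, n)
    sq = np.sum(points**2, axis=1)
    best = np.inf
    for j in range(k):
        member = assignments == j  # (m, n)
        counts = member.sum(axis=1)
        sums = member @ points  # (m, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            within = member @ sq - np.where(
                counts > 0, np.sum(sums**2, axis=1) / counts, 0.0
            )
        if j == 0:
            totals = within
        else:
            totals = totals + within
    best = float(np.min(totals))
    return best


def make_blobs(rng, centers, n_per, sigma=1.0):
    centers = np.asarray(centers, dtype=float)
    points = np.concatenate(
        [c + sigma * rng.standard_normal((n_per, centers.shape[1])) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return points, labels


class TestKmeansFit:
    def test_k1_is_mean_and_variance(self, rng):
        pts = rng.normal(size=(200, 3))
        model = kmeans_fit(pts, 1, seed=0)
        assert np.allclose(model.centroids[0], pts.mean(axis=0), atol=1e-9)
        assert model.inertia == pytest.approx(
            np.sum((pts - pts.mean(axis=0)) ** 2), rel=1e-9
        )

    def test_replicated_distinct_values_recovered_exactly(self):
        values = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
        pts = np.repeat(values, 40, axis=0)
        model = kmeans_fit(pts, 3, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        recovered = model.centroids[np.lexsort(model.centroids.T)]
        assert np.allclose(recovered, values[np.lexsort(values.T)], atol=1e-9)

    def test_gaussian_blob_recovery(self, rng):
        """Well-separated blobs: centroids within 0.5, agreement >= 0.99."""
        centers = [[0, 0, 0], [25, 0, 0], [0, 25, 10]]
        pts, truth = make_blobs(rng, centers, 1000, sigma=1.0)
        model = kmeans_fit(pts, 3, seed=5)
        # match each true center to its nearest recovered centroid
        d = np.linalg.norm(
            np.asarray(centers, float)[:, None] - model.centroids[None], axis=-1
        )
        matching = np.argmin(d, axis=1)
        assert len(set(matching)) == 3
        assert np.all(d[np.arange(3), matching] < 0.5)
        pred = kmeans_predict(model, pts)
        agreement = np.mean(matching[truth] == pred)
        assert agreement >= 0.99

    def test_matches_exhaustive_optimum_small_instances(self, rng):
        """Restarted Lloyd lands within 5% of the enumerated global optimum."""
        for k, n in [(2, 10), (3, 10)]:
            pts = rng.uniform(0, 100, size=(n, 3))
            model = kmeans_fit(pts, k, seed=3, n_restarts=20)
            optimum = brute_force_inertia(pts, k)
            assert model.inertia <= optimum * 1.05 + 1e-9

    def test_lloyd_inertia_monotone(self, rng):
        pts = rng.normal(size=(500, 3)) * 10
        model = kmeans_fit(pts, 3, seed=0, n_restarts=1)
        history = np.array(model.inertia_history)
        assert np.all(np.diff(history) <= 1e-9)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(300, 3))
        a = kmeans_fit(pts, 3, seed=42)
        b = kmeans_fit(pts, 3, seed=42)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.inertia == b.inertia

    def test_agrees_with_sklearn_on_blobs(self, rng):
        """Independent reference implementation reaches the same solution."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        pts, _ = make_blobs(rng, [[0, 0, 0], [30, 0, 0], [0, 30, 0]], 500)
        model = kmeans_fit(pts, 3, seed=0)
        ref = sklearn_cluster.KMeans(n_clusters=3, n_init=10, random_state=0).fit(pts)
        ours = model.centroids[np.lexsort(model.centroids.T)]
        theirs = ref.cluster_centers_[np.lexsort(ref.cluster_centers_.T)]
        assert np.allclose(ours, theirs, atol=1e-6)
        assert model.inertia == pytest.approx(ref.inertia_, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kmeans_fit(np.empty((0, 3)), 2)
        with pytest.raises(ValueError, match="distinct"):
            kmeans_fit(np.zeros((10, 3)), 2)


class TestKmeansPredict:
    def test_centroids_predict_themselves(self, rng):
        model = kmeans_fit(rng.normal(size=(100, 3)) * 10, 3, seed=0)
        assert np.array_equal(
            kmeans_predict(model, model.centroids), np.arange(3)
        )

    def test_chunk_invariance(self, rng):
        model = kmeans_fit(rng.normal(size=(100, 3)) * 10, 3, seed=0)
        pts = rng.normal(size=(999, 3)) * 10
        whole = kmeans_predict(model, pts)
        pieces = np.concatenate(
            [kmeans_predict(model, chunk) for chunk in np.array_split(pts, 7)]
        )
        assert np.array_equal(whole, pieces)

    def test_matches_brute_force_nearest_centroid(self, rng):
        model = kmeans_fit(rng.normal(size=(200, 3)) * 10, 3, seed=1)
        pts = rng.normal(size=(1000, 3)) * 10
        pred = kmeans_predict(model, pts)
        expected = np.array(
            [
                int(np.argmin([np.sum((p - c) ** 2) for c in model.centroids]))
                for p in pts
            ]
        )
        assert np.array_equal(pred, expected)


class TestSegmentOrthomosaic:
    def test_uniform_raster_single_cluster(self):
        lab = np.tile([50.0, 5.0, 5.0], (8, 8, 1))
        segmap = segment_orthomosaic(lab, 1, seed=0)
        assert np.array_equal(segmap.labels, np.zeros((8, 8), dtype=np.uint8))

    def test_nodata_pixels_stay_nodata(self):
        lab = np.tile([50.0, 5.0, 5.0], (8, 8, 1))
        lab[0, 0] = np.nan
        segmap = segment_orthomosaic(lab, 1, seed=0)
        assert segmap.labels[0, 0] == NODATA_LABEL
        assert (segmap.labels != NODATA_LABEL).sum() == 63

    def test_three_material_scene_agreement(self, rng):
        colors = np.array([[70.0, 5.0, 15.0], [75.0, -12.0, -2.0], [76.0, -27.0, 27.0]])
        truth = rng.integers(0, 3, size=(60, 60))
        lab = colors[truth] + rng.normal(0, 0.5, size=(60, 60, 3))
        segmap = segment_orthomosaic(lab, 3, seed=0, sample_fraction=1.0)
        segmap.class_map = map_clusters_to_classes(
            segmap.model,
            "reference-colors",
            reference_colors={"other": colors[0], "agave": colors[1], "weed": colors[2]},
        )
        class_of_truth = np.array(["other", "agave", "weed"])[truth]
        assert np.mean(segmap.class_raster() == class_of_truth) >= 0.99

    def test_subsampling_stability(self, rng):
        colors = np.array([[70.0, 5.0, 15.0], [75.0, -12.0, -2.0], [76.0, -27.0, 27.0]])
        truth = rng.integers(0, 3, size=(80, 80))
        lab = colors[truth] + rng.normal(0, 0.5, size=(80, 80, 3))
        full = segment_orthomosaic(lab, 3, seed=9, sample_fraction=1.0)
        sub = segment_orthomosaic(lab, 3, seed=9, sample_fraction=0.1)
        a = full.model.centroids[np.lexsort(full.model.centroids.T)]
        b = sub.model.centroids[np.lexsort(sub.model.centroids.T)]
        assert np.max(np.linalg.norm(a - b, axis=1)) < 1.0

    def test_too_few_valid_pixels_rejected(self):
        lab = np.full((2, 2, 3), np.nan)
        lab[0, 0] = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="valid pixels"):
            segment_orthomosaic(lab, 3)


class TestMapClustersToClasses:
    def test_identity_when_centroids_equal_references(self, rng):
        refs = {"agave": [75.0, -12.0, -2.0], "weed": [76.0, -27.0, 27.0],
                "other": [70.0, 5.0, 15.0]}
        pts = np.repeat(np.asarray(list(refs.values())), 30, axis=0)
        model = kmeans_fit(pts, 3, seed=0)
        cmap = map_clusters_to_classes(model, "reference-colors", reference_colors=refs)
        for idx, cls in cmap.items():
            assert np.allclose(model.centroids[idx], refs[cls], atol=1e-9)

    def test_manual_map_applied_verbatim(self, rng):
        model = kmeans_fit(rng.normal(size=(100, 3)) * 10, 3, seed=0)
        manual = {0: "weed", 1: "agave", 2: "other"}
        assert map_clusters_to_classes(model, "manual", manual_map=manual) == manual

    def test_missing_config_rejected(self, rng):
        model = kmeans_fit(rng.normal(size=(100, 3)) * 10, 3, seed=0)
        with pytest.raises(ValueError, match="reference_colors"):
            map_clusters_to_classes(model, "reference-colors")
        with pytest.raises(ValueError, match="missing clusters"):
            map_clusters_to_classes(model, "manual", manual_map={0: "agave"})
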