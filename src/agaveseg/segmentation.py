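"""From-scratch k-means segmentation of L*a*b* pixel rasters.

Lloyd's algorithm with k-means++ seeding partitions the pixels of the
L*a*b* ortho-mosaic into k groups (k = 3 by default: agave, weed, and a
third "other" group collecting everything else).  Euclidean distance in
L*a*b* is the similarity criterion — the perceptual uniformity of the space
is what makes a plain distance criterion meaningful for vegetation
discrimination.  Clusters are then mapped to semantic classes either from
reference colors or from an explicit manual mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geospatial_io import GeoreferenceRecord

__all__ = [
    "ClusterModel",
    "SegmentationMap",
    "kmeans_fit",
    "kmeans_predict",
    "segment_orthomosaic",
    "map_clusters_to_classes",
    "NODATA_LABEL",
]

NODATA_LABEL = 255
CLASS_NAMES = ("agave", "weed", "other")


@dataclass
class ClusterModel:
    """A fitted k-means model in L*a*b* feature space."""

    k: int
    centroids: np.ndarray  # (k, 3)
    inertia: float
    n_iter: int
    seed: int
    converged: bool
    inertia_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")


@dataclass
class SegmentationMap:
    """Per-pixel cluster labels plus the cluster -> class semantic mapping."""

    labels: np.ndarray  # (H, W) uint8, NODATA_LABEL for no-data
    model: ClusterModel
    class_map: dict[int, str] | None = None
    georef: GeoreferenceRecord | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = self.labels[self.labels != NODATA_LABEL]
        if valid.size and valid.max() >= self.model.k:
            raise ValueError("label raster contains cluster indices >= k")

    def class_raster(self) -> np.ndarray:
        """Semantic class name per pixel ('' where no-data)."""
        if self.class_map is None:
            raise ValueError("no class_map assigned; run map_clusters_to_classes")
        out = np.full(self.labels.shape, "", dtype=object)
        for cluster, cls in self.class_map.items():
            out[self.labels == cluster] = cls
        return out

    def class_mask(self, class_name: str) -> np.ndarray:
        """Boolean mask of pixels mapped to ``class_name``."""
        if self.class_map is None:
            raise ValueError("no class_map assigned; run map_clusters_to_classes")
        mask = np.zeros(self.labels.shape, dtype=bool)
        for cluster, cls in self.class_map.items():
            if cls == class_name:
                mask |= self.labels == cluster
        return mask


def _assign(points: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # squared Euclidean distances; argmin breaks ties toward the lowest index
    d2 = (
        np.sum(points**2, axis=1)[:, None]
        - 2.0 * points @ centroids.T
        + np.sum(centroids**2, axis=1)[None, :]
    )
    labels = np.argmin(d2, axis=1)
    return labels, np.maximum(d2[np.arange(len(points)), labels], 0.0)


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(points)
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    d2 = np.sum((points - centroids[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[i] = points[rng.integers(n)]
            continue
        centroids[i] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((points - centroids[i]) ** 2, axis=1))
    return centroids


def _lloyd(
    points: np.ndarray,
    init: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    centroids = init.copy()
    k = len(centroids)
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        labels, d2 = _assign(points, centroids)
        history.append(float(d2.sum()))
        new_centroids = centroids.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centroids[j] = points[members].mean(axis=0)
            else:
                # re-seed an empty cluster from the worst-fit point
                new_centroids[j] = points[np.argmax(d2)]
                d2[np.argmax(d2)] = 0.0
        shift = float(np.max(np.linalg.norm(new_centroids - centroids, axis=1)))
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    labels, d2 = _assign(points, centroids)
    history.append(float(d2.sum()))
    return centroids, float(d2.sum()), n_iter, converged, history


def kmeans_fit(
    points,
    k: int,
    *,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 300,
    n_restarts: int = 10,
) -> ClusterModel:
    """Fit k-means by restarted Lloyd iterations with k-means++ seeding.

    Runs ``n_restarts`` independent seeded initializations and keeps the
    model with the lowest inertia (sum of squared distances to the assigned
    centroid).  Fully deterministic given ``seed``.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array of feature triples")
    if pts.size == 0:
        raise ValueError("cannot cluster an empty point set")
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(pts, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct points for k={k}")

    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(n_restarts):
        init = _kmeanspp_init(pts, k, rng)
        centroids, inertia, n_iter, converged, history = _lloyd(
            pts, init, tol, max_iter
        )
        if best is None or inertia < best.inertia:
            best = ClusterModel(
                k=k,
                centroids=centroids,
                inertia=inertia,
                n_iter=n_iter,
                seed=seed,
                converged=converged,
                inertia_history=tuple(history),
            )
    assert best is not None
    return best


def kmeans_predict(model: ClusterModel, points) -> np.ndarray:
    """Assign each point to its nearest centroid (lowest index wins ties)."""
    if model.centroids is None or len(model.centroids) != model.k:
        raise ValueError("model is not fitted")
    pts = np.asarray(points, dtype=np.float64)
    labels, _ = _assign(pts, model.centroids)
    return labels


def segment_orthomosaic(
    lab: np.ndarray,
    k: int = 3,
    *,
    seed: int = 0,
    sample_fraction: float = 0.1,
    georef: GeoreferenceRecord | None = None,
    chunk_rows: int = 512,
    **fit_kwargs,
) -> SegmentationMap:
    """Cluster an L*a*b* raster into a :class:`SegmentationMap`.

    The model is fitted on a seeded uniform sample of the valid (non-NaN)
    pixels and then predicts every valid pixel.  Prediction is chunked by
    rows purely for memory; being a pointwise function of the centroids it
    is independent of the chunking.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[-1] != 3:
        raise ValueError("lab raster must have shape (H, W, 3)")
    valid = np.isfinite(lab).all(axis=-1)
    flat = lab[valid]
    if len(flat) < k:
        raise ValueError(f"raster has {len(flat)} valid pixels; need >= k={k}")

    rng = np.random.default_rng(seed)
    n_sample = max(k, int(round(sample_fraction * len(flat))))
    if n_sample < len(flat):
        idx = rng.choice(len(flat), size=n_sample, replace=False)
        sample = flat[idx]
        if len(np.unique(sample, axis=0)) < k:
            sample = flat
    else:
        sample = flat
    model = kmeans_fit(sample, k, seed=seed, **fit_kwargs)

    labels = np.full(lab.shape[:2], NODATA_LABEL, dtype=np.uint8)
    for start in range(0, lab.shape[0], chunk_rows):
        sl = slice(start, start + chunk_rows)
        block_valid = valid[sl]
        if block_valid.any():
            labels[sl][block_valid] = kmeans_predict(model, lab[sl][block_valid])
    return SegmentationMap(
        labels=labels,
        model=model,
        georef=georef,
        provenance={
            "k": k,
            "seed": seed,
            "sample_fraction": sample_fraction,
            "n_fit_points": int(len(sample)),
            "inertia": model.inertia,
            "centroids": model.centroids.tolist(),
        },
    )


def map_clusters_to_classes(
    model: ClusterModel,
    strategy: str = "reference-colors",
    *,
    reference_colors: Mapping[str, Sequence[float]] | None = None,
    manual_map: Mapping[int, str] | None = None,
) -> dict[int, str]:
    """Assign a semantic class (agave | weed | other) to every cluster.

    ``reference-colors`` gives each cluster the class of the nearest
    user-provided reference L*a*b* color; ``manual`` applies an explicit
    cluster -> class mapping verbatim.
    """
    if model.k < 2:
        raise ValueError("class mapping needs a model with k >= 2")
    if strategy == "reference-colors":
        if not reference_colors:
            raise ValueError("reference-colors strategy requires reference_colors")
        names = list(reference_colors)
        refs = np.asarray([reference_colors[n] for n in names], dtype=np.float64)
        d2 = np.sum(
            (model.centroids[:, None, :] - refs[None, :, :]) ** 2, axis=-1
        )
        return {i: names[j] for i, j in enumerate(np.argmin(d2, axis=1))}
    if strategy == "manual":
        if manual_map is None:
            raise ValueError("manual strategy requires manual_map")
        missing = set(range(model.k)) - set(manual_map)
        if missing:
            raise ValueError(f"manual_map missing clusters {sorted(missing)}")
        return {i: manual_map[i] for i in range(model.k)}
    raise ValueError(f"unknown strategy {strategy!r}")
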