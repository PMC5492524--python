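"""End-to-end convenience pipeline: mosaic -> L*a*b* -> k-means -> evaluation.

Ties the stage modules together the way the tool is meant to be run on one
field: convert the RGB ortho-mosaic to L*a*b*, cluster with k = 3, map
clusters to semantic classes from reference colors, annex the source
georeference onto the label map, and (when ground truth is available) score
the result with the polygon-sampling protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import color_transform, evaluation, segmentation
from .geospatial_io import OrthoMosaic
from .segmentation import SegmentationMap
from .synthetic_data import SceneSpec, SceneTruth, make_scene, render_orthomosaic


@dataclass
class PipelineResult:
    segmentation: SegmentationMap
    metrics: evaluation.ConfusionMetrics | None
    samples: list[evaluation.ValidationSample] | None


def reference_lab_colors(spec: SceneSpec) -> dict[str, np.ndarray]:
    """Class reference colors of a scene, expressed in L*a*b*."""
    return {
        "other": color_transform.rgb_to_lab(np.asarray(spec.soil_rgb)),
        "agave": color_transform.rgb_to_lab(np.asarray(spec.agave_rgb)),
        "weed": color_transform.rgb_to_lab(np.asarray(spec.weed_rgb)),
    }


def segment_mosaic(
    mosaic: OrthoMosaic,
    reference_colors,
    *,
    k: int = 3,
    seed: int = 0,
    sample_fraction: float = 0.1,
) -> SegmentationMap:
    """RGB mosaic to a class-mapped, georeferenced segmentation."""
    lab = color_transform.rgb_to_lab(
        mosaic.pixels, nodata_mask=mosaic.nodata_mask() if mosaic.nodata is not None else None
    )
    segmap = segmentation.segment_orthomosaic(
        lab, k, seed=seed, sample_fraction=sample_fraction, georef=mosaic.georef
    )
    segmap.class_map = segmentation.map_clusters_to_classes(
        segmap.model, "reference-colors", reference_colors=reference_colors
    )
    return segmap


def run_synthetic_pipeline(
    spec: SceneSpec,
    *,
    n_agave_samples: int = 15,
    n_weed_samples: int = 10,
    polygon_size_px: int = 9,
    k: int = 3,
    seed: int = 0,
    sample_fraction: float = 0.1,
) -> PipelineResult:
    """Generate a scene, segment it, and score it against its own truth."""
    truth = make_scene(spec)
    mosaic = render_orthomosaic(truth)
    segmap = segment_mosaic(
        mosaic,
        reference_lab_colors(spec),
        k=k,
        seed=seed,
        sample_fraction=sample_fraction,
    )
    truth_raster = OrthoMosaic(pixels=truth.labels, georef=mosaic.georef)
    samples = evaluation.sample_validation_polygons(
        truth_raster,
        n_agave=n_agave_samples,
        n_weed=n_weed_samples,
        polygon_size_px=polygon_size_px,
        seed=seed,
    )
    metrics = evaluation.confusion_counts(segmap, samples)
    return PipelineResult(segmentation=segmap, metrics=metrics, samples=samples)
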