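"""Polygon-sampled validation of a segmentation against reference labels.

The protocol mirrors how UAV crop maps are verified in practice: a set of
validation polygons is drawn at different sites over the field — by default
15 over agave plants and 10 over weed patches — each lying wholly inside a
single-class region of the reference, and the segmentation is tallied
per pixel inside those polygons.

Metric definitions (the field reports rarely spell these out, so they are
fixed here): with agave as the positive class,

* precision = TP / (TP + FP) over polygon pixels,
* overall accuracy = correctly classified polygon pixels / all polygon
  pixels (a pixel is correct when its mapped semantic class equals its
  polygon's declared class; pixels classified "other" count as wrong).

A pixel belongs to a polygon when its *center* lies inside it, matching the
pixel-center map-coordinate convention used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import shapely
from scipy.ndimage import binary_erosion
from shapely.geometry import Polygon, box

from .geospatial_io import GeoreferenceRecord, OrthoMosaic, map_to_pixel, _pixel_corner
from .segmentation import SegmentationMap

__all__ = [
    "ValidationSample",
    "ConfusionMetrics",
    "sample_validation_polygons",
    "confusion_counts",
    "evaluation_report",
]

VALIDATION_CLASSES = ("agave", "weed")
_CLASS_IDS = {"agave": 1, "weed": 2}


@dataclass(frozen=True)
class ValidationSample:
    """One validation polygon with its declared reference class."""

    polygon: Polygon
    declared_class: str
    sample_id: int
    grid: GeoreferenceRecord | None = None

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise ValueError("validation polygon must have positive area")
        if self.declared_class not in VALIDATION_CLASSES:
            raise ValueError(
                f"declared_class must be one of {VALIDATION_CLASSES}, "
                f"got {self.declared_class!r}"
            )


@dataclass
class ConfusionMetrics:
    """Per-pixel confusion counts and summary scores (agave = positive)."""

    tp: int
    fp: int
    fn: int
    tn: int
    per_class_precision: dict[str, float] = field(default_factory=dict)
    n_correct: int | None = None
    n_total: int | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def overall_accuracy(self) -> float:
        """Fraction of polygon pixels whose mapped class equals the declared one.

        When the exact-match tally is unavailable (counts constructed by
        hand), falls back to the binary diagonal (TP + TN) / total.
        """
        if self.n_total is not None and self.n_correct is not None:
            return self.n_correct / self.n_total if self.n_total else float("nan")
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else float("nan")


def sample_validation_polygons(
    truth_labels: OrthoMosaic,
    n_agave: int = 15,
    n_weed: int = 10,
    polygon_size_px: int = 9,
    seed: int = 0,
) -> list[ValidationSample]:
    """Draw square validation polygons wholly inside single-class regions.

    Candidate polygon centers are the pixels whose surrounding
    ``polygon_size_px`` x ``polygon_size_px`` window is pure in the truth
    raster (found by binary erosion); the requested number per class is
    sampled uniformly without replacement.  Deterministic given ``seed``.
    """
    if truth_labels.georef is None:
        raise ValueError("truth raster must be georeferenced")
    if polygon_size_px < 1 or polygon_size_px % 2 == 0:
        raise ValueError("polygon_size_px must be a positive odd integer")
    record = truth_labels.georef
    rng = np.random.default_rng(seed)
    half = polygon_size_px // 2
    footprint = np.ones((polygon_size_px, polygon_size_px), dtype=bool)

    samples: list[ValidationSample] = []
    sample_id = 0
    for class_name, n_wanted in (("agave", n_agave), ("weed", n_weed)):
        if n_wanted == 0:
            continue
        mask = truth_labels.pixels == _CLASS_IDS[class_name]
        pure = binary_erosion(mask, structure=footprint, border_value=False)
        rows, cols = np.nonzero(pure)
        if len(rows) < n_wanted:
            raise ValueError(
                f"truth raster has only {len(rows)} candidate pure windows for "
                f"class {class_name!r}; {n_wanted} requested"
            )
        chosen = rng.choice(len(rows), size=n_wanted, replace=False)
        for idx in chosen:
            r, c = int(rows[idx]), int(cols[idx])
            x_ul, y_ul = _pixel_corner(record, c - half, r - half)
            x_lr, y_lr = _pixel_corner(record, c + half + 1, r + half + 1)
            samples.append(
                ValidationSample(
                    polygon=box(
                        min(x_ul, x_lr), min(y_ul, y_lr),
                        max(x_ul, x_lr), max(y_ul, y_lr),
                    ),
                    declared_class=class_name,
                    sample_id=sample_id,
                    grid=record,
                )
            )
            sample_id += 1
    return samples


def _polygon_pixels(
    record: GeoreferenceRecord, polygon: Polygon, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels whose centers fall inside the polygon."""
    xmin, ymin, xmax, ymax = polygon.bounds
    corners_c, corners_r = map_to_pixel(
        record, np.array([xmin, xmax, xmin, xmax]), np.array([ymin, ymin, ymax, ymax])
    )
    c0 = max(int(np.floor(corners_c.min())), 0)
    c1 = min(int(np.ceil(corners_c.max())) + 1, shape[1])
    r0 = max(int(np.floor(corners_r.min())), 0)
    r1 = min(int(np.ceil(corners_r.max())) + 1, shape[0])
    if c0 >= c1 or r0 >= r1:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    x0, dx, rx, y0, ry, dy = record.geotransform
    cx = x0 + dx * (cc + 0.5) + rx * (rr + 0.5)
    cy = y0 + ry * (cc + 0.5) + dy * (rr + 0.5)
    inside = shapely.contains_xy(polygon, cx.ravel(), cy.ravel()).reshape(rr.shape)
    return rr[inside], cc[inside]


def confusion_counts(
    predicted: SegmentationMap, samples: list[ValidationSample]
) -> ConfusionMetrics:
    """Tally the segmentation against declared classes inside the polygons.

    Pixels outside every polygon are ignored.  The predicted raster must be
    georeferenced on the same grid the samples were drawn from.
    """
    if predicted.georef is None:
        raise ValueError("predicted segmentation must be georeferenced")
    for s in samples:
        if s.grid is not None and (
            s.grid.geotransform != predicted.georef.geotransform
            or s.grid.crs_id != predicted.georef.crs_id
        ):
            raise ValueError(
                f"sample {s.sample_id} was drawn on a different grid than the "
                "predicted segmentation"
            )
    class_raster = predicted.class_raster()
    tp = fp = fn = tn = 0
    n_correct = n_total = 0
    predicted_count: dict[str, int] = {}
    correct_count: dict[str, int] = {}
    for s in samples:
        rows, cols = _polygon_pixels(predicted.georef, s.polygon, class_raster.shape)
        pred = class_raster[rows, cols]
        pred_agave = pred == "agave"
        if s.declared_class == "agave":
            tp += int(pred_agave.sum())
            fn += int((~pred_agave).sum())
        else:
            fp += int(pred_agave.sum())
            tn += int((~pred_agave).sum())
        n_correct += int((pred == s.declared_class).sum())
        n_total += len(pred)
        for cls in np.unique(pred):
            n = int((pred == cls).sum())
            predicted_count[cls] = predicted_count.get(cls, 0) + n
            if cls == s.declared_class:
                correct_count[cls] = correct_count.get(cls, 0) + n
    per_class = {
        cls: correct_count.get(cls, 0) / n
        for cls, n in predicted_count.items()
        if n > 0
    }
    return ConfusionMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn, per_class_precision=per_class,
        n_correct=n_correct, n_total=n_total,
    )


def evaluation_report(metrics_per_area: dict[str, ConfusionMetrics]) -> str:
    """Tabulate precision and overall accuracy per study area, 5 decimals."""
    if not metrics_per_area:
        raise ValueError("at least one area is required")
    out = StringIO()
    out.write("Study Areas\tPrecision\tOverall Accuracy\n")
    for area, m in metrics_per_area.items():
        out.write(f"{area}\t{m.precision:.5f}\t{m.overall_accuracy:.5f}\n")
    return out.getvalue()


def evaluation_report_csv(metrics_per_area: dict[str, ConfusionMetrics]) -> str:
    """CSV variant of :func:`evaluation_report`."""
    if not metrics_per_area:
        raise ValueError("at least one area is required")
    lines = ["study_area,precision,overall_accuracy"]
    for area, m in metrics_per_area.items():
        lines.append(f"{area},{m.precision:.5f},{m.overall_accuracy:.5f}")
    return "\n".join(lines) + "\n"
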