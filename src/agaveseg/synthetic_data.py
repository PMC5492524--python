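"""Synthetic georeferenced agave-field ortho-mosaics with known ground truth.

No field imagery ships with the package, so every pipeline stage is
exercised on generated scenes that emulate the structure a UAV ortho-mosaic
of an agave plantation exposes to a color-based classifier: a textured
soil background, agave plants as compact glaucous (blue-green) rosettes of
roughly uniform size, and weeds as irregular brighter-green patches.  Each
scene comes with a paired per-pixel ground-truth label raster, so accuracy
statements downstream are exact.

Geometry and rendering are fully determined by the :class:`SceneSpec`
(including its seed): the same spec reproduces every output byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .geospatial_io import (
    GeoreferenceRecord,
    OrthoMosaic,
    raster_to_polygons,
    write_label_raster,
    write_raster,
)

__all__ = ["SceneSpec", "SceneTruth", "make_scene", "render_orthomosaic", "write_fixture"]

SOIL, AGAVE, WEED = 0, 1, 2


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic agave scene.

    Defaults mirror the flight configuration the pipeline targets: a GSD of
    2.6 cm/px (60 m flight height with the reference camera) and mature
    rosettes of ~1 m mean radius.  The palette is synthetic, not measured:
    it separates the three covers along the L* and a* axes the way real
    agave fields separate glaucous crop, green weed and bare soil.
    """

    width_px: int = 2000
    height_px: int = 2000
    gsd_cm: float = 2.6
    n_agave_plants: int = 50
    agave_radius_mean_m: float = 1.0
    agave_radius_sd_m: float = 0.15
    weed_coverage_fraction: float = 0.2
    soil_rgb: tuple[float, float, float] = (0.55, 0.44, 0.32)
    agave_rgb: tuple[float, float, float] = (0.35, 0.52, 0.50)
    weed_rgb: tuple[float, float, float] = (0.33, 0.58, 0.25)
    noise_sd: float = 0.02
    illumination_amplitude: float = 0.05
    seed: int = 0
    utm_origin: tuple[float, float] = (500000.0, 2300000.0)
    crs_id: str = "EPSG:32613"

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("scene dimensions must be positive")
        if not 0 <= self.weed_coverage_fraction < 1:
            raise ValueError("weed_coverage_fraction must be in [0, 1)")
        for name in ("soil_rgb", "agave_rgb", "weed_rgb"):
            color = getattr(self, name)
            if len(color) != 3 or any(not 0 <= c <= 1 for c in color):
                raise ValueError(f"{name} must be an RGB triple in [0, 1]^3")
        if self.gsd_cm <= 0:
            raise ValueError("gsd_cm must be positive")
        if self.n_agave_plants < 0:
            raise ValueError("n_agave_plants must be non-negative")

    @property
    def pixel_size_m(self) -> float:
        return self.gsd_cm / 100.0

    def georeference(self) -> GeoreferenceRecord:
        e0, n0 = self.utm_origin
        p = self.pixel_size_m
        return GeoreferenceRecord(
            geotransform=(e0, p, 0.0, n0, 0.0, -p), crs_id=self.crs_id
        )


@dataclass
class SceneTruth:
    """Ground truth for one scene: labels plus the generating geometry.

    ``plant_centers`` rows are (easting, northing, radius_m); rosette spike
    phases and counts are retained so rendering reproduces the exact discs
    that were labeled.
    """

    labels: np.ndarray  # (H, W) uint8: 0 soil, 1 agave, 2 weed
    plant_centers: np.ndarray  # (n, 3): easting, northing, radius_m
    plant_pixel_geometry: np.ndarray  # (n, 5): col, row, radius_px, n_leaves, phase
    spec: SceneSpec

    def class_fraction(self, class_id: int) -> float:
        return float(np.mean(self.labels == class_id))

    def weed_polygons(self):
        """Weed patches traced as map-coordinate polygons (computed on demand)."""
        raster = OrthoMosaic(pixels=self.labels, georef=self.spec.georeference())
        return raster_to_polygons(raster, WEED)


def _rosette_mask(
    h: int, w: int, col: float, row: float, radius_px: float,
    n_leaves: int, phase: float,
) -> tuple[slice, slice, np.ndarray]:
    """Boolean mask of a radially spiked disc, within its bounding window."""
    reach = radius_px * 1.25
    r0 = max(int(np.floor(row - reach)), 0)
    r1 = min(int(np.ceil(row + reach)) + 1, h)
    c0 = max(int(np.floor(col - reach)), 0)
    c1 = min(int(np.ceil(col + reach)) + 1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr + 0.5 - row
    dx = cc + 0.5 - col
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    # leaves modulate the disc boundary radially
    boundary = radius_px * (1.0 + 0.18 * np.cos(n_leaves * theta + phase))
    return slice(r0, r1), slice(c0, c1), dist <= boundary


def make_scene(spec: SceneSpec, *, max_attempts_per_plant: int = 1000) -> SceneTruth:
    """Generate scene geometry and the ground-truth label raster.

    Plants are placed by seeded rejection sampling as non-overlapping
    rosettes whose radii are drawn from N(mean, sd) clipped positive; weed
    patches are the upper quantile of a smoothed random field restricted to
    soil pixels, which yields irregular blobs at exactly the requested
    coverage (up to the pixel count rounding).
    """
    h, w = spec.height_px, spec.width_px
    geometry_seed, _ = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(geometry_seed)
    labels = np.zeros((h, w), dtype=np.uint8)

    px = spec.pixel_size_m
    placed: list[tuple[float, float, float]] = []  # col, row, reach_px
    pixel_geometry = []
    centers = []
    for i in range(spec.n_agave_plants):
        for _ in range(max_attempts_per_plant):
            radius_m = rng.normal(spec.agave_radius_mean_m, spec.agave_radius_sd_m)
            if radius_m <= 0:
                continue
            radius_px = radius_m / px
            reach = radius_px * 1.25
            if 2 * reach >= min(h, w):
                continue
            col = rng.uniform(reach, w - reach)
            row = rng.uniform(reach, h - reach)
            if all(
                np.hypot(col - c, row - r) > reach + other_reach + 2.0
                for c, r, other_reach in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place plant {i + 1}/{spec.n_agave_plants} after "
                f"{max_attempts_per_plant} attempts; scene too crowded"
            )
        placed.append((col, row, reach))
        n_leaves = int(rng.integers(9, 16))
        phase = float(rng.uniform(0, 2 * np.pi))
        rs, cs, mask = _rosette_mask(h, w, col, row, radius_px, n_leaves, phase)
        labels[rs, cs][mask] = AGAVE
        pixel_geometry.append((col, row, radius_px, n_leaves, phase))
        record = spec.georeference()
        x0, dx, rx, y0, ry, dy = record.geotransform
        centers.append((x0 + dx * col, y0 + dy * row, radius_m))

    n_weed = int(round(spec.weed_coverage_fraction * h * w))
    if n_weed > 0:
        soil = labels == SOIL
        if soil.sum() < n_weed:
            raise RuntimeError("not enough soil left for the requested weed coverage")
        field = gaussian_filter(rng.standard_normal((h, w)), sigma=12.0)
        field[~soil] = -np.inf
        flat_order = np.argsort(field, axis=None)[::-1][:n_weed]
        labels.flat[flat_order] = WEED

    return SceneTruth(
        labels=labels,
        plant_centers=np.asarray(centers, dtype=float).reshape(-1, 3),
        plant_pixel_geometry=np.asarray(pixel_geometry, dtype=float).reshape(-1, 5),
        spec=spec,
    )


def render_orthomosaic(truth: SceneTruth, spec: SceneSpec | None = None) -> OrthoMosaic:
    """Render the RGB ortho-mosaic for a generated scene.

    Each class is painted its mean color, a scene-wide multiplicative
    illumination ramp along a seeded random direction is applied, then
    i.i.d. Gaussian channel noise is added and the result clipped to
    [0, 1].  Pixels are float32 in [0, 1]; the georeference comes from the
    scene's UTM origin and GSD.
    """
    spec = truth.spec if spec is None else spec
    h, w = truth.labels.shape
    _, render_seed = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(render_seed)

    palette = np.asarray([spec.soil_rgb, spec.agave_rgb, spec.weed_rgb])
    img = palette[truth.labels]

    if spec.illumination_amplitude > 0:
        angle = rng.uniform(0, 2 * np.pi)
        rr, cc = np.mgrid[0:h, 0:w]
        ramp = (np.cos(angle) * cc / max(w - 1, 1)
                + np.sin(angle) * rr / max(h - 1, 1))
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
        img = img * (1.0 + spec.illumination_amplitude * (2.0 * ramp - 1.0))[..., None]

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return OrthoMosaic(pixels=img, georef=spec.georeference())


def write_fixture(truth: SceneTruth, mosaic: OrthoMosaic, directory) -> dict[str, Path]:
    """Write the fixture triple: mosaic GeoTIFF, truth GeoTIFF, spec manifest."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "mosaic": write_raster(directory / "mosaic.tif", mosaic),
            "truth": write_label_raster(
                directory / "truth.tif", truth.labels, mosaic.georef
            ),
        }
        manifest = directory / "scene.json"
        manifest.write_text(json.dumps(asdict(truth.spec), indent=2))
        paths["manifest"] = manifest
    except OSError as exc:
        raise IOError(f"cannot write fixture to {directory}: {exc}") from exc
    return paths


def load_scene_spec(path) -> SceneSpec:
    """Re-load a :class:`SceneSpec` from a fixture manifest."""
    data = json.loads(Path(path).read_text())
    for key in ("soil_rgb", "agave_rgb", "weed_rgb", "utm_origin"):
        if key in data:
            data[key] = tuple(data[key])
    return SceneSpec(**data)
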