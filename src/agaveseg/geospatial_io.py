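"""Georeferenced raster I/O and georeference annexation.

Reads and writes GeoTIFF files through :mod:`tifffile`, carrying the
georeference as the standard GeoTIFF tags (ModelPixelScale + ModelTiepoint,
or ModelTransformation when the geotransform has rotation terms, plus a
GeoKeyDirectory holding the EPSG code).  The central operation the pipeline
needs is *annexation*: copying the geotransform and CRS of the source
ortho-mosaic verbatim onto a derived product such as a k-means label map,
so the segmentation can be overlaid on the source in any GIS.

Conventions (used consistently by the evaluation module):

* pixels are indexed (col, row), 0-based, row-major storage;
* the geotransform is the 6-term affine in GDAL order
  ``(x0, dx, rx, y0, ry, dy)`` mapping the *top-left corner* of pixel
  (0, 0) to ``(x0, y0)``;
* :func:`pixel_to_map` evaluates the affine at the pixel *center*
  ``(col + 0.5, row + 0.5)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage.measure import label as cc_label

__all__ = [
    "GeoreferenceRecord",
    "OrthoMosaic",
    "MissingCrsWarning",
    "read_orthomosaic",
    "write_raster",
    "copy_georeference",
    "pixel_to_map",
    "map_to_pixel",
    "raster_to_polygons",
]

# GeoTIFF / GDAL tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_MODEL_TRANSFORMATION = 34264
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024
_GT_RASTER_TYPE = 1025
_GEOGRAPHIC_TYPE = 2048
_PROJECTED_CS_TYPE = 3072


class MissingCrsWarning(UserWarning):
    """Raster carries no coordinate reference system tags."""


@dataclass(frozen=True)
class GeoreferenceRecord:
    """Standalone georeference: 6-term affine geotransform plus a CRS id.

    ``crs_id`` is handled as an opaque ``"EPSG:<code>"`` identifier; no
    reprojection is ever performed.
    """

    geotransform: tuple[float, float, float, float, float, float]
    crs_id: str | None

    def __post_init__(self) -> None:
        gt = tuple(float(v) for v in self.geotransform)
        if len(gt) != 6:
            raise ValueError("geotransform must have 6 terms")
        if gt[1] == 0.0 or gt[5] == 0.0:
            raise ValueError("geotransform pixel sizes must be non-zero")
        object.__setattr__(self, "geotransform", gt)

    @property
    def is_referenced(self) -> bool:
        return self.crs_id is not None

    @property
    def pixel_area(self) -> float:
        gt = self.geotransform
        return abs(gt[1] * gt[5] - gt[2] * gt[4])


@dataclass
class OrthoMosaic:
    """A raster with optional georeference.

    ``pixels`` has shape (height, width) for single-band products or
    (height, width, bands) with bands last; input ortho-mosaics carry 3
    bands (R, G, B).
    """

    pixels: np.ndarray
    georef: GeoreferenceRecord | None = None
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be (H, W) or (H, W, bands)")
        if self.height < 1 or self.width < 1:
            raise ValueError("raster dimensions must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def band_count(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def nodata_mask(self) -> np.ndarray:
        """Boolean (H, W) mask of no-data pixels."""
        if self.nodata is None:
            return np.zeros(self.pixels.shape[:2], dtype=bool)
        m = self.pixels == self.nodata
        return m if self.pixels.ndim == 2 else m.all(axis=-1)


def _epsg_code(crs_id: str) -> int:
    try:
        authority, code = crs_id.split(":")
        if authority.upper() != "EPSG":
            raise ValueError
        return int(code)
    except ValueError:
        raise ValueError(
            f"CRS id must look like 'EPSG:<code>', got {crs_id!r}"
        ) from None


def _geokey_directory(crs_id: str) -> tuple[int, ...]:
    code = _epsg_code(crs_id)
    geographic = 4000 <= code < 5000
    keys = [
        (_GT_MODEL_TYPE, 0, 1, 2 if geographic else 1),
        (_GT_RASTER_TYPE, 0, 1, 1),  # PixelIsArea
        (_GEOGRAPHIC_TYPE if geographic else _PROJECTED_CS_TYPE, 0, 1, code),
    ]
    directory = [1, 1, 0, len(keys)]
    for entry in keys:
        directory.extend(entry)
    return tuple(directory)


def _crs_from_geokeys(directory) -> str | None:
    vals = list(directory)
    n_keys = vals[3]
    for i in range(n_keys):
        key_id, location, count, value = vals[4 + 4 * i : 8 + 4 * i]
        if key_id in (_PROJECTED_CS_TYPE, _GEOGRAPHIC_TYPE) and location == 0:
            return f"EPSG:{value}"
    return None


def _georef_tags(record: GeoreferenceRecord) -> list[tuple]:
    x0, dx, rx, y0, ry, dy = record.geotransform
    tags: list[tuple] = []
    if rx == 0.0 and ry == 0.0:
        # north-up: pixel scale stores |dy| positive by convention
        tags.append((_MODEL_PIXEL_SCALE, "d", 3, (dx, abs(dy), 0.0)))
        tags.append((_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)))
    else:
        transform = (
            dx, rx, 0.0, x0,
            ry, dy, 0.0, y0,
            0.0, 0.0, 0.0, 0.0,
            0.0, 0.0, 0.0, 1.0,
        )
        tags.append((_MODEL_TRANSFORMATION, "d", 16, transform))
    if record.crs_id is not None:
        directory = _geokey_directory(record.crs_id)
        tags.append((_GEO_KEY_DIRECTORY, "H", len(directory), directory))
    return tags


def write_raster(path, mosaic: OrthoMosaic) -> Path:
    """Write an :class:`OrthoMosaic` as a (Geo)TIFF, dtype preserved."""
    path = Path(path)
    extratags = _georef_tags(mosaic.georef) if mosaic.georef is not None else []
    if mosaic.nodata is not None:
        nd = str(mosaic.nodata)
        extratags.append((_GDAL_NODATA, "s", len(nd), nd))
    photometric = "rgb" if mosaic.band_count == 3 and mosaic.pixels.dtype == np.uint8 else "minisblack"
    tifffile.imwrite(
        path,
        mosaic.pixels,
        photometric=photometric,
        planarconfig="contig" if mosaic.pixels.ndim == 3 else None,
        extratags=extratags,
    )
    return path


def _read_georef(page) -> GeoreferenceRecord | None:
    tags = page.tags
    transform_tag = tags.get(_MODEL_TRANSFORMATION)
    if transform_tag is not None:
        t = transform_tag.value
        gt = (t[3], t[0], t[1], t[7], t[4], t[5])
    else:
        scale_tag = tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = tags.get(_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            return None
        sx, sy = scale_tag.value[0], scale_tag.value[1]
        tie = tie_tag.value
        # tiepoint maps raster (i, j) to model (x, y); shift to pixel (0, 0)
        x0 = tie[3] - tie[0] * sx
        y0 = tie[4] + tie[1] * sy
        gt = (x0, sx, 0.0, y0, 0.0, -sy)
    keys_tag = tags.get(_GEO_KEY_DIRECTORY)
    crs_id = _crs_from_geokeys(keys_tag.value) if keys_tag is not None else None
    return GeoreferenceRecord(geotransform=gt, crs_id=crs_id)


def read_orthomosaic(path, *, min_bands: int = 3) -> OrthoMosaic:
    """Read a GeoTIFF ortho-mosaic (>= ``min_bands`` bands required).

    A file without georeference tags is readable but triggers a
    :class:`MissingCrsWarning` and yields ``georef=None``; a file with a
    geotransform but no CRS keys yields a record with ``crs_id=None``.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            pixels = page.asarray()
            georef = _read_georef(page)
            nodata_tag = page.tags.get(_GDAL_NODATA)
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise IOError(f"cannot read GeoTIFF {path}: {exc}") from exc
    bands = 1 if pixels.ndim == 2 else pixels.shape[2]
    if bands < min_bands:
        raise IOError(f"{path} has {bands} band(s); at least {min_bands} required")
    if georef is None or georef.crs_id is None:
        warnings.warn(
            f"{path} carries no CRS; products will be unreferenced",
            MissingCrsWarning,
            stacklevel=2,
        )
    nodata = None
    if nodata_tag is not None:
        raw = nodata_tag.value
        nodata = float(raw) if "." in str(raw) or "e" in str(raw) else int(raw)
    return OrthoMosaic(pixels=pixels, georef=georef, nodata=nodata)


def read_label_raster(path) -> OrthoMosaic:
    """Read a single-band label raster written by :func:`write_label_raster`."""
    return read_orthomosaic(path, min_bands=1)


def write_label_raster(path, labels: np.ndarray, georef: GeoreferenceRecord | None,
                       nodata: int = 255) -> Path:
    """Write an integer label raster as single-band 8-bit GeoTIFF, nodata 255."""
    return write_raster(
        path,
        OrthoMosaic(pixels=np.asarray(labels, dtype=np.uint8), georef=georef,
                    nodata=nodata),
    )


def copy_georeference(source: OrthoMosaic, labels) -> OrthoMosaic:
    """Annex the source ortho-mosaic's georeference onto a derived raster.

    The derived raster must share the source's width and height; its pixel
    values are passed through untouched, and the returned product carries
    the source geotransform and CRS verbatim.
    """
    arr = labels.pixels if isinstance(labels, OrthoMosaic) else np.asarray(labels)
    nodata = labels.nodata if isinstance(labels, OrthoMosaic) else None
    if arr.shape[:2] != source.pixels.shape[:2]:
        raise ValueError(
            f"shape mismatch: labels {arr.shape[:2]} vs source "
            f"{source.pixels.shape[:2]}"
        )
    return OrthoMosaic(pixels=arr, georef=source.georef, nodata=nodata)


def pixel_to_map(record: GeoreferenceRecord, col, row):
    """Map coordinates of the center of pixel (col, row).

    Returns ``(easting, northing, referenced)`` where ``referenced`` is
    False when the record has no CRS.
    """
    x0, dx, rx, y0, ry, dy = record.geotransform
    c = np.asarray(col, dtype=float) + 0.5
    r = np.asarray(row, dtype=float) + 0.5
    return x0 + dx * c + rx * r, y0 + ry * c + dy * r, record.is_referenced


def map_to_pixel(record: GeoreferenceRecord, easting, northing):
    """Inverse of :func:`pixel_to_map`: continuous (col, row) of a map point."""
    x0, dx, rx, y0, ry, dy = record.geotransform
    det = dx * dy - rx * ry
    ex = np.asarray(easting, dtype=float) - x0
    ny = np.asarray(northing, dtype=float) - y0
    c = (dy * ex - rx * ny) / det - 0.5
    r = (dx * ny - ry * ex) / det - 0.5
    return c, r


def _pixel_corner(record: GeoreferenceRecord, col, row):
    x0, dx, rx, y0, ry, dy = record.geotransform
    return x0 + dx * col + rx * row, y0 + ry * col + dy * row


def raster_to_polygons(labels: OrthoMosaic, class_id: int) -> list[Polygon]:
    """Trace connected components of ``class_id`` into map-coordinate polygons.

    Components use 4-connectivity; each polygon is the union of its pixel
    footprints, so total polygon area equals pixel count times pixel area.
    An absent class yields an empty list.
    """
    if labels.georef is None:
        raise ValueError("label raster must be georeferenced")
    gt = labels.georef.geotransform
    if gt[2] != 0.0 or gt[4] != 0.0:
        raise NotImplementedError("polygonization requires an axis-aligned grid")
    mask = labels.pixels == class_id
    if not mask.any():
        return []
    record = labels.georef
    components = cc_label(mask, connectivity=1)
    polygons = []
    for comp_id in range(1, components.max() + 1):
        rows, cols = np.nonzero(components == comp_id)
        x_ul, y_ul = _pixel_corner(record, cols, rows)
        x_lr, y_lr = _pixel_corner(record, cols + 1, rows + 1)
        boxes = shapely.box(
            np.minimum(x_ul, x_lr), np.minimum(y_ul, y_lr),
            np.maximum(x_ul, x_lr), np.maximum(y_ul, y_lr),
        )
        polygons.append(unary_union(boxes.tolist()))
    return polygons


def polygons_to_geojson(polygons, properties=None) -> str:
    """Serialize polygons (with optional per-feature properties) as GeoJSON."""
    features = []
    for i, poly in enumerate(polygons):
        props = properties[i] if properties is not None else {}
        features.append(
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(poly)),
                "properties": props,
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": features})
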