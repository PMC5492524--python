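"""RGB to CIE L*a*b* conversion for ortho-mosaic rasters.

Pixels are first mapped to tristimulus XYZ by a fixed 3x3 linear transform
(D65-referred primaries), then to L*a*b* by pure cube-root formulas

    L* = 116 (Y/Y0)^(1/3) - 16
    a* = 500 [(X/X0)^(1/3) - (Y/Y0)^(1/3)]
    b* = 200 [(Y/Y0)^(1/3) - (Z/Z0)^(1/3)]

where (X0, Y0, Z0) is the reference white, defined as the transform of the
RGB vector (1, 1, 1).  Two deliberate departures from the CIE standard are
the defaults here: no sRGB gamma linearization is applied before the linear
transform, and the cube root is used on the whole domain (no linear segment
near zero, so black maps to L* = -16).  Both standard behaviours are
available behind flags for users who want colorimetric fidelity instead.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "rgb_to_xyz",
    "reference_white",
    "xyz_to_lab",
    "rgb_to_lab",
    "scale_to_unit",
]

#: D65-referred linear RGB -> XYZ transform.
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4125, 0.3576, 0.1804],
        [0.2125, 0.7154, 0.0721],
        [0.0193, 0.1192, 0.9502],
    ]
)

# CIE constants for the optional piecewise f(); delta = 6/29
_DELTA3 = (6.0 / 29.0) ** 3
_SLOPE = (29.0 / 6.0) ** 2 / 3.0


def scale_to_unit(raster: np.ndarray) -> np.ndarray:
    """Scale integer imagery to [0, 1] floats (8-bit by 255, 16-bit by 65535)."""
    if raster.dtype == np.uint8:
        return raster.astype(np.float64) / 255.0
    if raster.dtype == np.uint16:
        return raster.astype(np.float64) / 65535.0
    return np.asarray(raster, dtype=np.float64)


def _srgb_linearize(rgb: np.ndarray) -> np.ndarray:
    return np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)


def rgb_to_xyz(rgb, *, linearize_srgb: bool = False) -> np.ndarray:
    """Map [0,1] RGB to tristimulus XYZ by the fixed linear transform.

    ``rgb`` may be a single triple or an array whose last axis is (R, G, B).
    NaN channels (no-data) propagate.  With ``linearize_srgb`` the sRGB
    companding is removed first; off by default.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError(f"last axis must hold (R, G, B), got shape {arr.shape}")
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("RGB channels must lie in [0, 1]; scale inputs first")
    if linearize_srgb:
        arr = _srgb_linearize(arr)
    return arr @ RGB_TO_XYZ_MATRIX.T


def reference_white() -> np.ndarray:
    """XYZ of the reference white: the transform applied to RGB (1, 1, 1)."""
    return _REFERENCE_WHITE.copy()


_REFERENCE_WHITE = rgb_to_xyz(np.ones(3))


def _f_cbrt(t: np.ndarray) -> np.ndarray:
    return np.cbrt(t)


def _f_cie(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA3, np.cbrt(t), _SLOPE * t + 4.0 / 29.0)


def xyz_to_lab(xyz, white=None, *, cie_piecewise: bool = False) -> np.ndarray:
    """Map XYZ to L*a*b* relative to ``white`` (default: :func:`reference_white`).

    The default transfer function is the pure cube root on the whole domain;
    ``cie_piecewise`` switches to the standard CIE function with its linear
    segment below (6/29)^3.
    """
    arr = np.asarray(xyz, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError(f"last axis must hold (X, Y, Z), got shape {arr.shape}")
    w = _REFERENCE_WHITE if white is None else np.asarray(white, dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("white point components must be strictly positive")
    finite = arr[np.isfinite(arr)]
    if finite.size and finite.min() < 0:
        raise ValueError("XYZ components must be non-negative")
    f = _f_cie if cie_piecewise else _f_cbrt
    fx, fy, fz = (f(arr[..., i] / w[i]) for i in range(3))
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def rgb_to_lab(
    raster,
    *,
    linearize_srgb: bool = False,
    cie_piecewise: bool = False,
    nodata_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Convert an RGB raster (..., 3) to an L*a*b* raster of the same shape.

    No-data pixels — those flagged in ``nodata_mask`` or carrying NaN in any
    channel — come out as NaN triples.
    """
    arr = scale_to_unit(np.asarray(raster))
    if nodata_mask is not None:
        arr = arr.copy()
        arr[np.asarray(nodata_mask, dtype=bool)] = np.nan
    lab = xyz_to_lab(
        rgb_to_xyz(arr, linearize_srgb=linearize_srgb), cie_piecewise=cie_piecewise
    )
    bad = ~np.isfinite(lab).all(axis=-1)
    if bad.any():
        lab[bad] = np.nan
    return lab
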