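"""Flight geometry: ground sample distance and lens distortion.

The ground sample distance (GSD) of a nadir aerial image is the ground
distance between the centers of two adjacent pixels,

    GSD [cm/px] = Sw * H * 100 / (Fr * imW)

with sensor width ``Sw`` in millimeters, flight height ``H`` in meters,
real focal length ``Fr`` in millimeters and image width ``imW`` in pixels.
Lens distortion is modeled as Brown-Conrady with two radial and two
tangential coefficients, the parameterization produced by chessboard
calibration toolboxes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "FlightParams",
    "CameraCalibration",
    "FlightEnvelopeWarning",
    "compute_gsd",
    "gsd_profile",
    "pixel_pitch",
    "distort_point",
    "undistort_point",
    "load_camera_config",
]

#: Flight-height envelope (meters) over which detection quality was vetted;
#: heights outside it are allowed but trigger a warning.
TESTED_HEIGHT_RANGE_M = (40.0, 80.0)


class FlightEnvelopeWarning(UserWarning):
    """Flight height outside the vetted altitude envelope."""


def _require_positive(**params: float) -> None:
    for name, value in params.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class CameraModel:
    """Physical sensor geometry of the UAV camera.

    Parameters
    ----------
    sensor_width_mm : float
        Width of the sensor (``Sw``), millimeters.
    real_focal_length_mm : float
        Real (not 35 mm equivalent) focal length (``Fr``), millimeters.
    image_width_px : int
        Image width (``imW``), pixels.
    image_height_px : int
        Image height, pixels.
    pixel_pitch_um : float, optional
        Physical pixel pitch in micrometers.  Derivable as
        ``sensor_width_mm * 1000 / image_width_px``; if given it must agree
        with the derived value.
    """

    sensor_width_mm: float
    real_focal_length_mm: float
    image_width_px: int
    image_height_px: int = 3000
    pixel_pitch_um: float | None = None

    def __post_init__(self) -> None:
        _require_positive(
            sensor_width_mm=self.sensor_width_mm,
            real_focal_length_mm=self.real_focal_length_mm,
            image_width_px=self.image_width_px,
            image_height_px=self.image_height_px,
        )
        if self.pixel_pitch_um is not None:
            derived = self.sensor_width_mm * 1000.0 / self.image_width_px
            if not math.isclose(self.pixel_pitch_um, derived, rel_tol=1e-9):
                raise ValueError(
                    f"pixel_pitch_um={self.pixel_pitch_um} inconsistent with "
                    f"sensor_width_mm/image_width_px (expected {derived})"
                )


@dataclass(frozen=True)
class FlightParams:
    """UAV flight parameters; ``flight_height_m`` is ``H`` in the GSD formula."""

    flight_height_m: float

    def __post_init__(self) -> None:
        _require_positive(flight_height_m=self.flight_height_m)
        lo, hi = TESTED_HEIGHT_RANGE_M
        if not lo <= self.flight_height_m <= hi:
            warnings.warn(
                f"flight height {self.flight_height_m} m is outside the vetted "
                f"envelope [{lo}, {hi}] m",
                FlightEnvelopeWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class CameraCalibration:
    """Intrinsics and Brown-Conrady distortion coefficients.

    Focal length and principal point are in pixels; ``radial_coeffs`` are
    (k1, k2) and ``tangential_coeffs`` are (p1, p2).
    """

    focal_length_px: tuple[float, float]
    principal_point_px: tuple[float, float]
    skew: float = 0.0
    radial_coeffs: tuple[float, float] = (0.0, 0.0)
    tangential_coeffs: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.focal_length_px) != 2 or any(f <= 0 for f in self.focal_length_px):
            raise ValueError("focal_length_px must be a positive pair")
        if len(self.radial_coeffs) != 2:
            raise ValueError("exactly 2 radial coefficients expected")
        if len(self.tangential_coeffs) != 2:
            raise ValueError("exactly 2 tangential coefficients expected")


def compute_gsd(camera: CameraModel, flight: FlightParams) -> float:
    """Ground sample distance in cm/pixel, unrounded.

    Display rounding (the conventional 2-decimal presentation) is left to
    :func:`round` at report time; all internal consumers use the full value.
    """
    return (
        camera.sensor_width_mm
        * flight.flight_height_m
        * 100.0
        / (camera.real_focal_length_mm * camera.image_width_px)
    )


def gsd_profile(
    camera: CameraModel, h_min_m: float, h_max_m: float, step_m: float
) -> list[tuple[float, float]]:
    """Table of (flight height, GSD) rows over an altitude range.

    Endpoints are always included; heights advance by ``step_m``.
    """
    if h_min_m > h_max_m:
        raise ValueError(f"inverted range: h_min {h_min_m} > h_max {h_max_m}")
    _require_positive(step_m=step_m, h_min_m=h_min_m)
    heights = list(np.arange(h_min_m, h_max_m, step_m))
    if not heights or not math.isclose(heights[-1], h_max_m):
        heights.append(h_max_m)
    return [
        (float(h), compute_gsd(camera, FlightParams(float(h)))) for h in heights
    ]


def pixel_pitch(camera: CameraModel) -> float:
    """Physical pixel pitch in micrometers: sensor width / image width."""
    return camera.sensor_width_mm * 1000.0 / camera.image_width_px


def _normalize(calib: CameraCalibration, point_px: np.ndarray) -> np.ndarray:
    fx, fy = calib.focal_length_px
    cx, cy = calib.principal_point_px
    y = (point_px[..., 1] - cy) / fy
    x = (point_px[..., 0] - cx - calib.skew * y) / fx
    return np.stack([x, y], axis=-1)

def _denormalize(calib: CameraCalibration, point_n: np.ndarray) -> np.ndarray:
    fx, fy = calib.focal_length_px
    cx, cy = calib.principal_point_px
    x, y = point_n[..., 0], point_n[..., 1]
    return np.stack([fx * x + calib.skew * y + cx, fy * y + cy], axis=-1)

def _apply_distortion(calib: CameraCalibration, xy: np.ndarray) -> np.ndarray:
    # Brown-Conrady forward model in normalized image coordinates
    k1, k2 = calib.radial_coeffs
    p1, p2 = calib.tangential_coeffs
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 * r2
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def distort_point(calib: CameraCalibration, point_px) -> np.ndarray:
    """Apply the forward Brown-Conrady model to ideal pixel coordinates."""
    p = np.asarray(point_px, dtype=float)
    return _denormalize(calib, _apply_distortion(calib, _normalize(calib, p)))


def undistort_point(
    calib: CameraCalibration,
    point_px,
    *,
    tol_px: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Invert the Brown-Conrady model by fixed-point iteration.

    Starting from the distorted normalized coordinates, iterate
    ``x <- (xd - dx(x)) / radial(x)`` until the forward-projected residual
    drops below ``tol_px`` pixels.

    Raises
    ------
    RuntimeError
        If the residual still exceeds ``tol_px`` after ``max_iter``
        iterations; the message reports the achieved residual.
    """
    p = np.asarray(point_px, dtype=float)
    fx, fy = calib.focal_length_px
    cx, cy = calib.principal_point_px
    diag = math.hypot(2 * cx, 2 * cy) or 1.0
    if np.any(np.abs(p[..., 0] - cx) > 4 * diag) or np.any(
        np.abs(p[..., 1] - cy) > 4 * diag
    ):
        raise ValueError("point implausibly far outside the image frame")

    k1, k2 = calib.radial_coeffs
    p1, p2 = calib.tangential_coeffs
    target = _normalize(calib, p)
    xy = target.copy()
    for _ in range(max_iter):
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2 * r2
        dx = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        xy = np.stack(
            [(target[..., 0] - dx) / radial, (target[..., 1] - dy) / radial],
            axis=-1,
        )
        residual = np.max(
            np.abs(_denormalize(calib, _apply_distortion(calib, xy)) - p)
        )
        if residual <= tol_px:
            return _denormalize(calib, xy)
    raise RuntimeError(
        f"undistortion did not converge below {tol_px} px in {max_iter} "
        f"iterations (residual {residual:.3e} px)"
    )


def load_camera_config(path=None) -> tuple[CameraModel, CameraCalibration, dict]:
    """Load a camera/calibration config; defaults to the bundled Phantom 4.

    Returns (camera, calibration, raw config dict).
    """
    import yaml

    if path is None:
        from importlib.resources import files

        text = files("agaveseg.data").joinpath("phantom4_camera.yaml").read_text()
    else:
        from pathlib import Path

        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    cam = cfg["camera"]
    camera = CameraModel(
        sensor_width_mm=cam["sensor_width_mm"],
        real_focal_length_mm=cam["real_focal_length_mm"],
        image_width_px=cam["image_width_px"],
        image_height_px=cam.get("image_height_px", 3000),
        pixel_pitch_um=cam.get("pixel_pitch_um"),
    )
    cal = cfg.get("calibration", {})
    calibration = CameraCalibration(
        focal_length_px=tuple(cal.get("focal_length_px", (1.0, 1.0))),
        principal_point_px=tuple(cal.get("principal_point_px", (0.0, 0.0))),
        skew=cal.get("skew", 0.0),
        radial_coeffs=tuple(cal.get("radial_coeffs", (0.0, 0.0))),
        tangential_coeffs=tuple(cal.get("tangential_coeffs", (0.0, 0.0))),
    )
    return camera, calibration, cfg

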