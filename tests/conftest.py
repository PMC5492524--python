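import numpy as np
import pytest

from agaveseg.flight_geometry import CameraCalibration, CameraModel, load_camera_config
from agaveseg.geospatial_io import GeoreferenceRecord, OrthoMosaic
from agaveseg.synthetic_data import SceneSpec, make_scene, render_orthomosaic


@pytest.fixture(scope="session")
def reference_camera() -> CameraModel:
    """The bundled reference camera (6.25 mm sensor, 3.6 mm focal, 4000 px)."""
    camera, _, _ = load_camera_config()
    return camera


@pytest.fixture(scope="session")
def reference_calibration() -> CameraCalibration:
    _, calibration, _ = load_camera_config()
    return calibration


@pytest.fixture(scope="session")
def utm_georef() -> GeoreferenceRecord:
    return GeoreferenceRecord(
        geotransform=(500000.0, 0.026, 0.0, 2300000.0, 0.0, -0.026),
        crs_id="EPSG:32613",
    )


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    """A small but fully featured scene: quick enough for per-test reuse."""
    return SceneSpec(width_px=400, height_px=400, n_agave_plants=6, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return make_scene(small_spec)


@pytest.fixture(scope="session")
def small_mosaic(small_truth):
    return render_orthomosaic(small_truth)


@pytest.fixture(scope="session")
def small_truth_raster(small_truth, small_mosaic) -> OrthoMosaic:
    return OrthoMosaic(pixels=small_truth.labels, georef=small_mosaic.georef)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
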