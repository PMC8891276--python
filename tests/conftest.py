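import numpy as np
import pytest

from noisescore import RawImage, simulate_sensor
from noisescore.calibration import NoiseModel
from noisescore.phantoms import make_annotations, make_microsphere_scene


@pytest.fixture(scope="session")
def model() -> NoiseModel:
    """Reference sensor: gain 2 ADU/e-, offset 100 ADU, read noise 3 ADU."""
    return NoiseModel(gain=2.0, offset=100.0, read_noise=3.0,
                      valid_range=(100.0, 2100.0))


@pytest.fixture(scope="session")
def small_sphere_scene():
    """256x256 microsphere scene used by segmentation-level tests."""
    return make_microsphere_scene(n=80, radius_px=4, size=(256, 256), seed=2)


@pytest.fixture(scope="session")
def small_sphere_raw(small_sphere_scene, model) -> RawImage:
    return RawImage(simulate_sensor(small_sphere_scene.flux, model, seed=11))


@pytest.fixture(scope="session")
def small_sphere_annotations(small_sphere_scene):
    return make_annotations(small_sphere_scene, fraction=0.05, seed=4)


@pytest.fixture(scope="session")
def flat_image(model) -> np.ndarray:
    """Flat 300-ADU field (flux 100 e-) rendered through the sensor."""
    return simulate_sensor(np.full((128, 128), 100.0), model, seed=21)
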