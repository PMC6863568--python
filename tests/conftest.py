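import numpy as np
import pytest

from polirkit.optics import OpticsModel

#: miniature sensor at the native 29.42 um/pixel pitch — one strip fits in frame
SMALL_SENSOR = (328, 248)
SMALL_FOV = (9.65, 7.2965)


@pytest.fixture(scope="session")
def small_optics() -> OpticsModel:
    return OpticsModel(sensor_px=SMALL_SENSOR, fov_mm=SMALL_FOV)


@pytest.fixture(scope="session")
def small_center() -> tuple[float, float]:
    return (SMALL_FOV[0] / 2, SMALL_FOV[1] / 2)


@pytest.fixture(scope="session")
def dish_optics() -> OpticsModel:
    return OpticsModel(sensor_px=(656, 496), fov_mm=(19.3, 14.593))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
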