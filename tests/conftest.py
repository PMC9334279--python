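import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from tfus.sonication import WATER_24C, PulseTrain
from tfus.transducer import TransducerGeometry
from tfus.volume import Volume


@pytest.fixture(scope="session")
def water():
    return WATER_24C


@pytest.fixture(scope="session")
def bowl():
    """The 28 mm aperture / 22 mm curvature focused bowl."""
    return TransducerGeometry()


@pytest.fixture(scope="session")
def pulse_10pct():
    """100 ms pulses at 1 Hz (10% duty cycle), 30 min, I_SPTA 0.5 W/cm^2."""
    return PulseTrain(
        fundamental_frequency=200e3,
        pulse_duration=0.1,
        pulse_repetition_frequency=1.0,
        sonication_duration=1800.0,
        amplitude=0.5,
        amplitude_kind="ispta_w_cm2",
    )


def gaussian_beam_volume(
    sigma_lateral=2e-3,
    sigma_axial=8e-3,
    center=(0.0, 0.0, 16e-3),
    spacing=0.5e-3,
    shape=(41, 41, 101),
    origin=(-10e-3, -10e-3, -4e-3),
    axis=(0.0, 0.0, 1.0),
):
    """Separable Gaussian pressure beam along an arbitrary axis."""
    ax = np.asarray(axis, dtype=float)
    ax /= np.linalg.norm(ax)
    grids = np.meshgrid(
        *[origin[i] + spacing * np.arange(shape[i]) for i in range(3)], indexing="ij"
    )
    rel = np.stack(grids, axis=-1) - np.asarray(center)
    s = rel @ ax
    r2 = np.sum(rel**2, axis=-1) - s**2
    data = np.exp(-(s**2) / (2 * sigma_axial**2)) * np.exp(-r2 / (2 * sigma_lateral**2))
    return Volume(data=data, spacing=(spacing,) * 3, origin=origin)


@pytest.fixture(scope="session")
def gaussian_beam():
    return gaussian_beam_volume
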