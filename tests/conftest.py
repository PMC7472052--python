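import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stripescope import filtering, optics, synth

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def proto():
    """Laboratory prototype optics: 45/18 mm lenses at 4f, 1.44 mm / 1280-column sensor."""
    return optics.PROTOTYPE


@pytest.fixture(scope="session")
def full_mask():
    """Default 20-300 px annular mask for full-size (720 x 1280) frames."""
    return filtering.build_mask((720, 1280), filtering.BandpassSpec())


@pytest.fixture(scope="session")
def default_scene():
    return synth.SceneConfig()


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, baseline-free scene: the stripe texture alone."""
    return synth.SceneConfig(
        noise_sigma=0.0,
        baseline=synth.BaselineModel(poly={(0, 0): 0.0}, blob_amplitude=0.0),
    )


@pytest.fixture(scope="session")
def clean_center_frame(proto, clean_scene):
    """Noiseless, baseline-free frame with the stripe at the sensor centre (column 640)."""
    return synth.render_frame(proto, clean_scene, 45.0)


def spectral_radius_grid(shape):
    rows, cols = shape
    v = np.fft.fftshift(np.fft.fftfreq(rows)) * rows
    u = np.fft.fftshift(np.fft.fftfreq(cols)) * cols
    uu, vv = np.meshgrid(u, v)
    return np.hypot(uu, vv)
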