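import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from preyjnd.spectral_io import Spectrum
from preyjnd.vision_model import VisualSystem, bluetit_d65

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def viewer_and_light():
    """The packaged synthetic blue tit viewer and daylight illuminant."""
    return bluetit_d65()


@pytest.fixture(scope="session")
def coarse_grid():
    """A small 5 nm grid for fast unit tests."""
    return np.arange(300.0, 751.0, 5.0)


@pytest.fixture(scope="session")
def toy_viewer(coarse_grid):
    """A fast 4-channel viewer with Gaussian sensitivities on the coarse grid."""
    w = coarse_grid

    def gauss(peak, sd):
        v = np.exp(-0.5 * ((w - peak) / sd) ** 2)
        return Spectrum(w, v, label=f"g{peak:.0f}", role="sensitivity")

    sens = [gauss(370, 25), gauss(450, 30), gauss(505, 32), gauss(563, 35)]
    double = gauss(560, 70)
    return VisualSystem(sens, double, np.array([1.0, 1.92, 2.68, 2.7]),
                        weber_ref=0.05, weber_double=0.05, name="toy")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
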