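import pytest
from hypothesis import HealthCheck, settings

from pocenmr.synthdata import AcquisitionParams
from pocenmr.windows import default_windows, window_map

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def windows():
    return default_windows()


@pytest.fixture(scope="session")
def wm(windows):
    return window_map(windows)


@pytest.fixture(scope="session")
def desk_acq():
    """Noise-free 1H window (-0.4..4.6 ppm) at the default grid density.

    Covers every metabolite window at the same 0.00122 ppm spacing as the
    full 20 ppm axis, at a quarter of the cost.
    """
    return AcquisitionParams(spectral_width=5.0, ppm_start=-0.4,
                             n_points=4096, noise_sd=0.0)
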