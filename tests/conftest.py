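import pytest

from protonfsf import BeamGeometry, SpotFluenceParams


@pytest.fixture
def parallel_geom():
    return BeamGeometry.parallel(spot_spacing_mm=5.0)


@pytest.fixture
def diverging_geom():
    return BeamGeometry(vsad_x_mm=2000.0, vsad_y_mm=2500.0, spot_spacing_mm=5.0)


@pytest.fixture
def rs_params():
    """Typical range-shifter-broadened spot: wide core and a pronounced halo."""
    return SpotFluenceParams(sigma1_mm=7.0, sigma2_mm=20.0, w2=0.1)
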