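import numpy as np
import pytest

from tacsloop.montage import MontageConfig, build_dual_site_montage
from tacsloop.schedule import build_run_schedule, tile_trials
from tacsloop.simulate import NuisanceModel, SurfaceModel


@pytest.fixture
def default_montage():
    return build_dual_site_montage()


@pytest.fixture
def anti_montage():
    return build_dual_site_montage(MontageConfig(phase_condition="anti_phase"))


@pytest.fixture
def standard_run():
    """One training/test run: 15 x (20 s + 10 s) blocks, 4-s trials, TR 2."""
    return tile_trials(build_run_schedule())


@pytest.fixture
def clean_surface():
    """Coupling surface with no measurement noise (sampling noise remains)."""
    return SurfaceModel(noise_sd=0.0)


@pytest.fixture
def no_nuisance():
    return NuisanceModel.none()


@pytest.fixture
def flat_montage():
    """Idealized mirror-symmetric flat montage on the z = 0 plane: sites at
    x = -65 and +65 mm, returns 30 mm from their center along the axes."""
    positions = {}
    for prefix, x0 in (("F", -65.0), ("P", 65.0)):
        positions[prefix + "4"] = (x0, 0.0, 0.0)
        positions[f"R_{prefix}1"] = (x0 + 30.0, 0.0, 0.0)
        positions[f"R_{prefix}2"] = (x0 - 30.0, 0.0, 0.0)
        positions[f"R_{prefix}3"] = (x0, 30.0, 0.0)
        positions[f"R_{prefix}4"] = (x0, -30.0, 0.0)
    return MontageConfig(positions=positions)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
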