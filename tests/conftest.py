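import numpy as np
import pytest

from zmwell import (
    ALEXA488,
    NanowellGeometry,
    SimConfig,
    make_cell_movie,
    make_layout,
    simulate_nanowell_diffusion,
)


@pytest.fixture(scope="session")
def alexa():
    return ALEXA488


@pytest.fixture(scope="session")
def well_geometry():
    """Reference pore for diffusion runs: d = 200 nm, h = 200 nm."""
    return NanowellGeometry(diameter=200.0, overmill_depth=200.0)


@pytest.fixture(scope="session")
def short_run(well_geometry):
    """One short Brownian run shared by cheap FCS/trace tests."""
    cfg = SimConfig(seed=11, duration_s=0.4)
    return simulate_nanowell_diffusion(well_geometry, cfg)


@pytest.fixture(scope="session")
def default_movie():
    """One default pore-array movie shared by imaging tests."""
    layout = make_layout()
    cfg = SimConfig(seed=5)
    return make_cell_movie(layout, cfg, n_frames=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
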