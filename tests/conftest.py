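import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """60 mm water box at 3 mm spacing with an 18 mm target cube and a distal OAR."""
    from scenariofree import OarSpec, make_box_phantom

    return make_box_phantom(
        dims_mm=(60.0, 60.0, 60.0),
        spacing_mm=3.0,
        target_halfwidth_mm=9.0,
        oar_spec=OarSpec(offset_mm=(18.0, 0.0, 0.0), halfwidth_mm=6.0),
    )


@pytest.fixture(scope="session")
def small_engine(small_phantom):
    """Single 0-degree proton beam with a small beamlet lattice."""
    from scenariofree import Beam, PencilBeamEngine

    grid, _ = small_phantom
    iso = tuple(d * s / 2.0 for d, s in zip(grid.dims, grid.spacing))
    beam = Beam("proton", 0.0, iso, beamlet_spacing=6.0, field_halfwidth=9.0)
    return PencilBeamEngine([small_phantom], [beam], reference_phase=0)


def toy_influences(rng, n_scen=3, nvox=5, nb=2, weights=(0.5, 0.3, 0.2)):
    """Random nonnegative sparse influence matrices with importance weights."""
    from scipy import sparse

    assert len(weights) == n_scen
    mats = [sparse.csr_matrix(rng.uniform(0.0, 1.0, size=(nvox, nb)))
            for _ in range(n_scen)]
    return list(zip(mats, weights))
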