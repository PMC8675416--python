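import numpy as np
import pytest

from shapemeta.synthetic_cohort import make_structure_mesh, make_template


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Unit-radius cylinder of length 6 along z (the tubular test shape)."""
    rng = np.random.default_rng(0)
    return make_structure_mesh("cylinder", 350, rng, radius=1.0, length=6.0)


@pytest.fixture(scope="session")
def toy_atlas():
    """Small two-structure atlas (ellipsoids, ~120 vertices each)."""
    return make_template("ellipsoid", 120, seed=5,
                         structures=("hippocampus", "amygdala"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
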