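import numpy as np
import pytest

from earlyfold.early_stage import EllipseSpec
from earlyfold.synthetic_data import build_backbone


@pytest.fixture(scope="session")
def ellipse() -> EllipseSpec:
    """A Ramachandran-like path: tilted so the major axis runs from the
    upper-left (beta) toward the lower-right quadrant."""
    return EllipseSpec(center=(0.0, 0.0), semi_axes=(130.0, 70.0), tilt=120.0)


@pytest.fixture
def helix_domain():
    """Ideal 10-residue right-handed helix backbone."""
    torsions = np.tile([-57.0, -47.0], (10, 1))
    return build_backbone(torsions, domain_id="helix10")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
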