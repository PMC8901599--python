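import numpy as np
import pytest

from borutafc.connectome import RoiAtlas, SubjectTimeSeries
from borutafc.simulate import generate_atlas


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_atlas():
    """12-ROI atlas, two ROIs per network."""
    return generate_atlas(12, {n: 2 for n in ("DMN", "FPN", "CON", "SMN", "ON", "CN")}, seed=0)


@pytest.fixture
def tiny_atlas():
    """4-ROI atlas over two networks, hand-built for exact-count tests."""
    return RoiAtlas(
        names=("dmn_a", "dmn_b", "fpn_a", "fpn_b"),
        networks=("DMN", "DMN", "FPN", "FPN"),
        mni_xyz=np.zeros((4, 3)),
    )


@pytest.fixture
def toy_timeseries(rng):
    return SubjectTimeSeries(subject_id="s1", data=rng.normal(size=(50, 6)))
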