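import numpy as np
import pytest

from wbcseg import SceneSpec, SegmentationParams, make_smear


@pytest.fixture
def params():
    """Default thresholds at working scale (synthetic scenes are generated
    at working resolution, so no resize)."""
    return SegmentationParams(resize_factor=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def simple_scene():
    """One deterministic 5-cell isolated scene shared across tests."""
    spec = SceneSpec(n_wbc=5, n_rbc=20, overlap_fraction=0.0, seed=7,
                     lobes_per_nucleus=(1, 3))
    return make_smear(spec)


@pytest.fixture(scope="session")
def empty_scene():
    """Background and RBCs only — no WBC anywhere."""
    spec = SceneSpec(n_wbc=0, n_rbc=25, seed=11)
    return make_smear(spec)
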