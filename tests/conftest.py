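import numpy as np
import pytest

from protosym.config import AnalysisConfig
from protosym.synthetic import BundleSpec, make_pseudo_symmetric_domain


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def parallel_domain():
    """Noise-free parallel-topology 3TMH x 2 domain with ground truth."""
    return make_pseudo_symmetric_domain(BundleSpec(seed=11))


@pytest.fixture(scope="session")
def inverted_domain():
    """Noise-free inverted-topology 3TMH x 2 domain with ground truth."""
    return make_pseudo_symmetric_domain(
        BundleSpec(symmetry_mode="inverted", seed=12)
    )


@pytest.fixture(scope="session")
def linker_domain():
    """Noise-free parallel domain with a TM4-like linker helix (7 helices)."""
    return make_pseudo_symmetric_domain(BundleSpec(linker_helix=True, seed=13))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
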