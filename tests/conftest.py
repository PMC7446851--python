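import numpy as np
import pytest

from rnaflex import FeatureConfig, GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_gen_config():
    """A small, fast synthetic dataset configuration shared across tests."""
    return GeneratorConfig(n_chains=4, nucleotides_range=(8, 14), seed=11)


@pytest.fixture(scope="session")
def small_structures(small_gen_config):
    return generate_dataset(small_gen_config)


@pytest.fixture(scope="session")
def small_feature_config():
    # E=8 Å, F=4 Å, f=0.5 Å -> N=8, p = 4 elements * 2 dims * 8 = 64
    return FeatureConfig(cutoff=8.0, fe_ratio=0.5, bin_size=0.5)


@pytest.fixture(scope="session")
def small_dataset(small_structures, small_feature_config):
    from rnaflex import build_dataset

    return build_dataset(small_structures, small_feature_config)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
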