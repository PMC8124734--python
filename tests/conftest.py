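import numpy as np
import pytest

import mscdunet as M


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Smallest legal network: 1 modality, width 4, 16^3 patches."""
    return M.NetworkConfig(n_modalities=1, base_width=4, patch_size=16, seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_net_cfg):
    return M.build_model(tiny_net_cfg).eval()


@pytest.fixture(scope="session")
def small_phantom():
    """One 3-modality phantom subject (64^3) with default conditions."""
    spec = M.PhantomSpec(seed=11)
    vols, labels = M.generate_phantom(spec)
    return spec, vols, labels


@pytest.fixture(scope="session")
def normalized_subject(small_phantom):
    _, vols, labels = small_phantom
    return [M.normalize_volume(v) for v in vols], labels
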