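import numpy as np
import pytest

from speckgen.gan.config import GanConfig
from speckgen.synthesis import (
    ArteryMaskSpec,
    PhantomTextureSpec,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def smoke_config():
    """Small 64x64 architecture used by training tests."""
    return GanConfig(
        image_size=64,
        gen_channels=(16, 8),
        disc_channels=(8, 16, 32),
        spade_hidden=8,
        d_init_range=(12.0, 28.0),
        batch_size=2,
        epochs=2,
        fid_interval=2,
        lr_init=3e-4,
        lr_final=1e-4,
        lr_disc_scale=0.25,
        lr_milestones=(20, 40),
        seed=0,
    )


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """Eight 64x64 (phantom, mask) pairs on disk."""
    out = tmp_path_factory.mktemp("pairs64")
    mask_spec = ArteryMaskSpec.scaled(64, seed=11)
    tex_spec = PhantomTextureSpec(window_sizes=(24.0, 10.0, 14.0), seed=11)
    generate_dataset(8, mask_spec, tex_spec, out)
    return out


@pytest.fixture
def square_mask():
    mask = np.full((64, 64), 2, dtype=np.int64)
    mask[16:48, 16:48] = 1
    mask[26:38, 26:38] = 0
    return mask
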