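import numpy as np
import pytest

from masegnet.model import ModelConfig, build_model
from masegnet.synth import SynthConfig, generate_fundus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """A small but structurally complete network (depth 2, 16-filter
    bottleneck) for fast training tests."""
    return ModelConfig(base_filters=4, depth=2, bottleneck_filters=16,
                       reduction_ratio=2, seed=3)


@pytest.fixture
def tiny_model(tiny_model_config):
    return build_model(tiny_model_config)


@pytest.fixture(scope="session")
def small_fundus():
    """One deterministic 128x128 synthetic fundus image with its mask."""
    cfg = SynthConfig(image_size=128, n_lesions=(4, 8),
                      lesion_radius=(1.5, 3.0), seed=11)
    return generate_fundus(cfg)


def lesion_patches(n: int, patch: int = 64, image_size: int = 256,
                   base_seed: int = 0):
    """Collect n patch/mask pairs that contain lesion pixels, from
    preprocessed synthetic images."""
    from masegnet.preprocess import (PreprocessConfig, extract_patches,
                                     preprocess, preprocess_mask)

    cfg_pre = PreprocessConfig(target_size=image_size)
    patches, masks = [], []
    seed = base_seed
    while len(patches) < n:
        img, mask = generate_fundus(
            SynthConfig(image_size=image_size, seed=seed))
        gray = preprocess(img, cfg_pre)
        msk = preprocess_mask(mask, cfg_pre, crop_like=img)
        gp, mp = extract_patches(gray, patch), extract_patches(msk, patch)
        order = np.argsort([m.sum() for m in mp.patches])[::-1]
        for k in order:
            if mp.patches[k].sum() >= 5 and len(patches) < n:
                patches.append(gp.patches[k])
                masks.append(mp.patches[k])
        seed += 1
    return patches, masks
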