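import numpy as np
import pytest

import fpsiam as fp


TINY_PYRAMID = fp.PyramidConfig(d=16, n_levels=3)
TINY_HEADS = fp.HeadConfig(proj_in=16, proj_hidden=64, proj_out=32,
                           pred_hidden=8)


def tiny_augment(crop_size: int = 64) -> fp.AugmentationConfig:
    return fp.AugmentationConfig(crop_size=crop_size,
                                 crop_scale_range=(0.2, 1.0))


def make_tiny_model(frames, seed: int = 0, epochs: int = 200,
                    batch_size: int = 32, stop_gradient: bool = True,
                    **kwargs) -> fp.FPSiamModel:
    """The desk-scale fixture: 3-stage <=32-channel backbone on 64x64."""
    return fp.FPSiamModel(
        frames,
        backbone_spec=fp.tiny_backbone_spec(seed=seed),
        augment_config=tiny_augment(),
        pyramid_config=fp.PyramidConfig(d=16, n_levels=3),
        head_config=fp.HeadConfig(proj_in=16, proj_hidden=64, proj_out=32,
                                  pred_hidden=8),
        train_config=fp.TrainConfig(batch_size=batch_size, epochs=epochs,
                                    seed=seed),
        stop_gradient=stop_gradient, **kwargs)


@pytest.fixture(scope="session")
def small_corpus() -> np.ndarray:
    """64 synthetic 64x64 frames (2 sequences)."""
    return fp.make_corpus(64, frame_size=64, seq_len=32, seed=11)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
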