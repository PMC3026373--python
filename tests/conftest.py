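import sys
from pathlib import Path

import numpy as np
import pytest

from dermseg import RasterImage, SynthConfig, generate_lesion

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(20261)


@pytest.fixture
def easy_lesion():
    """One easy-preset synthetic lesion image with its exact truth mask."""
    return generate_lesion(SynthConfig(seed=7))


@pytest.fixture
def two_tone_image():
    """Crisp dark disc on light skin: no softness, no noise, no hairs."""
    cfg = SynthConfig(
        seed=3, boundary_irregularity=0.0, edge_softness=0.0, noise_sd=0.0, n_hairs=0
    )
    return generate_lesion(cfg)


def random_rgb(rng, h=16, w=16) -> RasterImage:
    return RasterImage(rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8))
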