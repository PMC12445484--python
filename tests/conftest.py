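import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_boxes(rng, n, span=20.0, min_side=0.5, max_side=8.0):
    """Random (xc, yc, w, h) boxes as an (n, 4) array."""
    xy = rng.uniform(0, span, (n, 2))
    wh = rng.uniform(min_side, max_side, (n, 2))
    return np.concatenate([xy, wh], axis=1)


@pytest.fixture
def micro_scene():
    from canedet.train import micro_scene_config
    return micro_scene_config(seed=3, image_size=128)
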