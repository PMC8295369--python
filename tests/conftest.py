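import numpy as np
import pytest

from qushab.segmentation import Plane
from qushab.synthetic import (
    SyntheticMapConfig,
    generate_label_field,
    generate_multichannel_maps,
)


@pytest.fixture(scope="session")
def default_map():
    """One default-config synthetic map with its generating labels."""
    cfg = SyntheticMapConfig(seed=7)
    labels = generate_label_field(cfg)
    maps = generate_multichannel_maps(labels, cfg)
    return cfg, labels, maps


@pytest.fixture(scope="session")
def training_planes():
    """Five default-config synthetic planes with generating labels."""
    out = []
    for s in range(5):
        cfg = SyntheticMapConfig(seed=50 + s)
        labels = generate_label_field(cfg)
        maps = generate_multichannel_maps(labels, cfg)
        out.append((labels, Plane.from_maps(maps)))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
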