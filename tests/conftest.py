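import numpy as np
import pytest

import lynodet as L


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_dataset():
    """Small in-memory two-class fixture set with a hold-out split applied."""
    cfg = L.easy_two_class_config(n_images=60, image_size=64, seed=7)
    records, images = L.generate_records(cfg)
    manifest = L.split_holdout([r.image_id for r in records], seed=7,
                               key_by={r.image_id: r.first_class
                                       for r in records})
    for r in records:
        r.split = manifest.assignment[r.image_id]
    return cfg, records, images, manifest


@pytest.fixture(scope="session")
def tiny_model():
    spec = L.make_arch_spec("baseline", input_size=64, num_classes=2,
                            width_mult=0.25)
    return L.DetectorNet(spec, seed=0)
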