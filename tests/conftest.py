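import numpy as np
import pytest

from leafseg import ModelConfig, simple_scene, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small model config usable on 32-128 px inputs."""
    return ModelConfig(n_classes=4, seed=0)


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight 64 px lab-style scenes with two lesion classes."""
    scene = simple_scene(size=64, seed=11)
    samples, manifest = generate_dataset(scene, 8)
    return scene, samples, manifest


@pytest.fixture(scope="session")
def rand_mask_pairs(rng):
    """Random mask pairs of varying size/cardinality for metric property tests."""
    pairs = []
    for _ in range(200):
        shape = (int(rng.integers(4, 24)), int(rng.integers(4, 24)))
        k = int(rng.integers(2, 5))
        pairs.append((rng.integers(0, k, size=shape), rng.integers(0, k, size=shape)))
    return pairs
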