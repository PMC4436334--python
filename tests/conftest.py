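import numpy as np
import pytest

from ovicount import (
    FeatureConfig,
    LoocvConfig,
    SceneParams,
    compute_feature_stack,
    generate_dataset,
    generate_vial_image,
)


@pytest.fixture(scope="session")
def small_scene():
    """One 280x280 translucent vial image with 60 eggs and its annotation."""
    return generate_vial_image(SceneParams(image_shape=(280, 280), n_eggs=60, seed=123))


@pytest.fixture(scope="session")
def small_dataset():
    """Five 280x280 translucent images, counts 10-70, with annotations."""
    template = SceneParams(image_shape=(280, 280))
    scenes, manifest = generate_dataset(5, (10, 70), template, master_seed=99)
    images = [s[0] for s in scenes]
    annotations = [s[1] for s in scenes]
    return images, annotations, manifest


@pytest.fixture(scope="session")
def small_stacks(small_dataset):
    """Feature stacks for the small dataset (shared; they are deterministic)."""
    images, _, _ = small_dataset
    cfg = FeatureConfig()
    return [compute_feature_stack(img, cfg, dtype=np.float32) for img in images]


@pytest.fixture(scope="session")
def quick_loocv_cfg():
    return LoocvConfig(n_replicates=2, master_seed=7, max_train_pixels=20_000)
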