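import numpy as np
import pytest

from tarsus import imgseg, phantom, qc


@pytest.fixture(scope="session")
def unfused_atlas():
    return phantom.build_bone_atlas("unfused")


@pytest.fixture(scope="session")
def fused_atlas():
    return phantom.build_bone_atlas("fused")


@pytest.fixture(scope="session")
def truth_labels(unfused_atlas):
    return unfused_atlas.rasterize_labels()


@pytest.fixture(scope="session")
def noisy_image(unfused_atlas):
    return phantom.render_image(unfused_atlas, rng_seed=11)


@pytest.fixture(scope="session")
def default_segmentation(noisy_image):
    """One full default segmentation, shared by many tests."""
    return imgseg.segment_hindpaw(noisy_image)


@pytest.fixture(scope="session")
def default_dice(default_segmentation, truth_labels):
    return qc.per_bone_dice(default_segmentation.label_map, truth_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
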