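import numpy as np
import pytest

from mr2sct import phantom, preprocess
from mr2sct.volume import BodyMask, ImageVolume


@pytest.fixture(scope="session")
def head_phantom():
    """One seeded noisy phantom subject shared by read-only tests."""
    contrast = phantom.ContrastModel(
        noise_sigma={"t1": 10.0, "t2": 10.0, "flair": 10.0}, bias_amplitude=0.1
    )
    labels, ct = phantom.generate_head_phantom(
        shape=(12, 64, 64), spacing=(2.5, 1.0, 1.0), contrast=contrast, seed=11
    )
    mr = phantom.simulate_mr(labels, contrast, seed=12)
    mask = BodyMask(labels.labels > 0, labels.spacing)
    return {"labels": labels, "ct": ct, "mr": mr, "mask": mask, "contrast": contrast}


@pytest.fixture()
def vol():
    """Factory for quick ImageVolumes with unit spacing."""

    def make(arr, spacing=(1.0, 1.0, 1.0)):
        return ImageVolume(np.asarray(arr, dtype=float), spacing)

    return make


@pytest.fixture()
def full_mask():
    def make(shape, spacing=(1.0, 1.0, 1.0)):
        return BodyMask(np.ones(shape, dtype=bool), spacing)

    return make
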