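import numpy as np
import pytest

from admil_cyto import (ExtractionConfig, build_bags, extract_instances,
                        generate_dataset, small_profile)


@pytest.fixture(scope="session")
def tiny_dataset():
    """8-case small-profile synthetic dataset (4 benign / 4 malignant)."""
    return generate_dataset(small_profile(n_cases=8, images_per_case=(2, 2), seed=11))


@pytest.fixture(scope="session")
def tiny_bags(tiny_dataset):
    by_image = {im.image_id: extract_instances(im, ExtractionConfig())
                for im in tiny_dataset.images}
    return build_bags(by_image, tiny_dataset.manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
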