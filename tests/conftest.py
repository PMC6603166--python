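import numpy as np
import pytest

from histostyle import (
    BackboneSpec,
    CLESynthParams,
    Image,
    build_test_backbone,
    make_cle_image,
    make_he_style_image,
)


@pytest.fixture(scope="session")
def test_backbone():
    return build_test_backbone(seed=0)


@pytest.fixture(scope="session")
def spec():
    return BackboneSpec()


@pytest.fixture(scope="session")
def cle_image():
    img, _ = make_cle_image(CLESynthParams(size=64, seed=0))
    return img


@pytest.fixture(scope="session")
def he_image():
    img, _ = make_he_style_image(size=64, seed=1)
    return img


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_image(rng, h=16, w=16) -> Image:
    return Image(pixels=rng.uniform(0.0, 1.0, size=(h, w, 3)))
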