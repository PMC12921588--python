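import numpy as np
import pytest

from haquant import PhantomSpec, SectionImage, Stage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_image(pixels, stage=Stage.FI, thickness_um=5.0, pixel_size_um=1.0, section_id="t"):
    return SectionImage(
        pixels=np.asarray(pixels, dtype=float),
        stage=stage,
        thickness_um=thickness_um,
        pixel_size_um=pixel_size_um,
        section_id=section_id,
    )


@pytest.fixture
def small_phantom_spec():
    """Compact phantom for fast end-to-end tests."""
    return PhantomSpec(shape=(96, 96), seed=7)
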