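import numpy as np
import pytest
from hypothesis import settings

from pmfcount.preprocessing import SectionImage
from pmfcount.synthetic_data import SyntheticSpec, generate_slide

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_slide():
    """One small synthetic slide (2 sections) with its ground truth."""
    spec = SyntheticSpec(
        slide_w=512,
        slide_h=512,
        n_sections=2,
        follicles_per_section=(3, 6),
        distractors_per_section=(4, 8),
        section_ax_a=(90, 115),
        section_ax_b=(80, 105),
        seed=11,
    )
    return generate_slide(spec)


@pytest.fixture()
def flat_section():
    """A uniform mid-gray section for geometry-only tests."""
    pixels = np.full((200, 240), 150, dtype=np.uint8)
    return SectionImage(pixels=pixels, offset_x=0, offset_y=0,
                        section_id=0, slide_id="flat")


@pytest.fixture(scope="session")
def toy_patchset():
    """Trivially separable patches: bright disc-on-dark vs pure noise."""
    from pmfcount.dataset_builder import (
        LABEL_BACKGROUND,
        LABEL_FOLLICLE,
        LabeledPatch,
        PatchDataset,
    )

    rng = np.random.default_rng(5)
    patches = []
    for i in range(10):
        dark = rng.integers(0, 40, (48, 48)).astype(np.uint8)
        yy, xx = np.mgrid[0:48, 0:48]
        disc = (xx - 24) ** 2 + (yy - 24) ** 2 <= 100
        bright = dark.copy()
        bright[disc] = 230
        patches.append(LabeledPatch(bright, LABEL_FOLLICLE, ("toy", 0, 24, 24)))
        patches.append(LabeledPatch(dark, LABEL_BACKGROUND, ("toy", 0, 24, 24)))
    return PatchDataset.from_patches(patches, seed=5)
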