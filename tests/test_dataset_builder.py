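import numpy as np
import pytest
from hypothesis import given, strategies as st

from pmfcount.dataset_builder import (
    DIHEDRAL_OPS,
    LABEL_BACKGROUND,
    LABEL_FOLLICLE,
    LabeledPatch,
    augment_patch,
    augment_positives,
    balance_and_split,
    extract_positive_patches,
    load_dataset,
    sample_negative_patches,
    save_dataset,
)
from pmfcount.errors import SamplingError, ValidationError
from pmfcount.imaging_io import Annotation
from pmfcount.preprocessing import SectionImage


def _section(h=200, w=240, slide_id="flat", fill=150):
    return SectionImage(np.full((h, w), fill, np.uint8), 0, 0, 0, slide_id)


def _ann(x, y, slide_id="flat", cls="primordial"):
    return Annotation(slide_id, x, y, cls)


class TestExtractPositives:
    def test_patch_centered_on_click(self, flat_section):
        [p] = extract_positive_patches(flat_section, [_ann(120, 100)], 64)
        assert p.frame_size == 64
        assert p.source == ("flat", 0, 120, 100)
        assert p.label == LABEL_FOLLICLE

    def test_one_patch_per_selected_annotation(self, flat_section):
        anns = [_ann(60, 60), _ann(100, 100), _ann(150, 120), _ann(80, 80, cls="primary")]
        patches = extract_positive_patches(flat_section, anns, 64)
        assert len(patches) == 3  # primary is not a positive class

    def test_border_patch_is_padded_to_size(self):
        sec = _section()
        sec.pixels[:, :] = 100
        [p] = extract_positive_patches(sec, [_ann(5, 100)], 64)
        assert p.pixels.shape == (64, 64)
        # left region beyond the section is median-padded
        assert (p.pixels[:, :20] == 100).all()

    def test_every_positive_contains_its_click(self, small_slide):
        from pmfcount.preprocessing import isolate_sections

        slide, anns = small_slide
        for sec in isolate_sections(slide):
            for p in extract_positive_patches(sec, anns, 48):
                _, _, x, y = p.source
                # click sits at the patch center by construction
                assert 0 <= x < sec.width and 0 <= y < sec.height

    def test_frame_larger_than_section(self):
        with pytest.raises(ValidationError):
            extract_positive_patches(_section(40, 40), [_ann(10, 10)], 64)

    def test_odd_frame_rejected(self, flat_section):
        with pytest.raises(ValidationError):
            extract_positive_patches(flat_section, [], 63)


class TestSampleNegatives:
    def test_zero_requested(self, flat_section):
        assert sample_negative_patches(flat_section, [], 48, n=0) == []

    def test_seed_determinism(self, flat_section):
        a = sample_negative_patches(flat_section, [_ann(50, 50)], 48, n=5, seed=9)
        b = sample_negative_patches(flat_section, [_ann(50, 50)], 48, n=5, seed=9)
        assert [p.source for p in a] == [p.source for p in b]

    def test_min_dist_respected(self, flat_section):
        anns = [_ann(120, 100)]
        patches = sample_negative_patches(
            flat_section, anns, 48, n=20, min_dist=60, seed=1
        )
        for p in patches:
            _, _, x, y = p.source
            assert np.hypot(x - 120, y - 100) >= 60
            assert p.label == LABEL_BACKGROUND

    def test_infeasible_region_raises_with_achieved_count(self, flat_section):
        with pytest.raises(SamplingError) as exc:
            sample_negative_patches(
                flat_section, [_ann(100, 100)], 48, n=3,
                min_dist=1000, seed=0, max_tries=50,
            )
        assert exc.value.achieved == 0


class TestAugmentation:
    @pytest.fixture()
    def patch(self):
        rng = np.random.default_rng(2)
        return LabeledPatch(
            rng.integers(0, 255, (48, 48)).astype(np.uint8),
            LABEL_FOLLICLE, ("s", 0, 100, 100),
        )

    @pytest.mark.parametrize("op", ["rot180", "flip_h", "flip_v"])
    def test_involutions(self, patch, op):
        twice = augment_patch(augment_patch(patch, op), op)
        assert np.array_equal(twice.pixels, patch.pixels)

    def test_rot90_four_times_is_identity(self, patch):
        out = patch
        for _ in range(4):
            out = augment_patch(out, "rot90")
        assert np.array_equal(out.pixels, patch.pixels)

    @pytest.mark.parametrize("op", DIHEDRAL_OPS)
    def test_dihedral_preserves_label_and_size(self, patch, op):
        out = augment_patch(patch, op)
        assert out.label == patch.label
        assert out.frame_size == patch.frame_size
        assert out.augmentation_tag == op

    def test_translate_recrops_from_section(self):
        rng = np.random.default_rng(7)
        sec = SectionImage(rng.integers(0, 255, (200, 200)).astype(np.uint8),
                           0, 0, 0, "s")
        [p] = extract_positive_patches(sec, [_ann(100, 100, "s")], 48)
        shifted = augment_patch(p, ("translate", 5, -3), section=sec, max_shift=12)
        expected = sec.pixels[100 - 3 - 24 : 100 - 3 + 24, 100 + 5 - 24 : 100 + 5 + 24]
        assert np.array_equal(shifted.pixels, expected)

    def test_translate_beyond_max_shift(self, patch):
        with pytest.raises(ValidationError):
            augment_patch(patch, ("translate", 40, 0), max_shift=10)

    def test_augment_positives_multiplier(self, patch):
        out = augment_positives([patch], seed=0, n_translations=2)
        assert len(out) == 1 + 7 + 2


class TestBalanceAndSplit:
    def _patches(self, n, label, slide_id="a"):
        return [
            LabeledPatch(np.zeros((8, 8), np.uint8), label, (slide_id, 0, i, i))
            for i in range(n)
        ]

    def test_ratio_arithmetic(self):
        train, _ = balance_and_split(
            self._patches(100, LABEL_FOLLICLE),
            self._patches(1000, LABEL_BACKGROUND),
            neg_pos_ratio=1.0, seed=0,
        )
        assert train.positives == 100
        assert train.negatives == 100

    def test_holdout_goes_entirely_to_test(self):
        pos = self._patches(10, LABEL_FOLLICLE, "a") + self._patches(5, LABEL_FOLLICLE, "b")
        neg = self._patches(20, LABEL_BACKGROUND, "a") + self._patches(7, LABEL_BACKGROUND, "b")
        train, test = balance_and_split(pos, neg, holdout_ovary_ids={"b"}, seed=0)
        assert all(p.source[0] == "a" for p in train.patches)
        assert all(p.source[0] == "b" for p in test.patches)
        assert len(test) == 12

    def test_holdout_everything_is_an_error(self):
        with pytest.raises(ValidationError):
            balance_and_split(
                self._patches(5, LABEL_FOLLICLE),
                self._patches(5, LABEL_BACKGROUND),
                holdout_ovary_ids={"a"}, seed=0,
            )

    def test_unknown_holdout_id(self):
        with pytest.raises(ValidationError):
            balance_and_split(
                self._patches(5, LABEL_FOLLICLE), [], holdout_ovary_ids={"zz"},
            )

    def test_subsample_determinism(self):
        pos = self._patches(10, LABEL_FOLLICLE)
        neg = self._patches(100, LABEL_BACKGROUND)
        a, _ = balance_and_split(pos, neg, seed=42)
        b, _ = balance_and_split(pos, neg, seed=42)
        assert [p.source for p in a.patches] == [p.source for p in b.patches]


@given(st.integers(0, 6))
def test_dihedral_group_closure_on_random_patch(k):
    """Composing any dihedral op with itself 4x returns to start or identity."""
    rng = np.random.default_rng(k)
    patch = LabeledPatch(rng.integers(0, 255, (16, 16)).astype(np.uint8),
                         LABEL_FOLLICLE, ("s", 0, 8, 8))
    op = DIHEDRAL_OPS[k]
    out = patch
    for _ in range(4):
        out = augment_patch(out, op)
    assert np.array_equal(out.pixels, patch.pixels)


def test_save_and_load_round_trip(tmp_path, toy_patchset):
    save_dataset(toy_patchset, tmp_path)
    loaded = load_dataset(tmp_path)
    assert loaded.positives == toy_patchset.positives
    assert loaded.negatives == toy_patchset.negatives
    for a, b in zip(toy_patchset.patches, loaded.patches):
        assert np.array_equal(a.pixels, b.pixels)
        assert a.label == b.label
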