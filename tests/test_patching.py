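import numpy as np
import pytest

from reeffusion.datamodel import PointAnnotation, RegisteredPair
from reeffusion.patching import (
    CROP_SIZE,
    D4_TAGS,
    PatchTensor,
    PointOnInvalidPixelError,
    augment,
    crop_patch,
    dihedral,
    extract_dataset,
    resize_patch,
    slice_modality,
)


def _big_pair(rng) -> RegisteredPair:
    ref = rng.uniform(0, 1, (512, 512, 3))
    flr = rng.uniform(0, 1, (512, 512, 2))
    return RegisteredPair("big", ref, flr)


class TestCropPatch:
    def test_interior_crop_is_plain_slice(self, rng):
        pair = _big_pair(rng)
        p = PointAnnotation("big", 256, 256, "Acropora")
        crop = crop_patch(pair, p, "ref")
        np.testing.assert_array_equal(
            crop, pair.reflectance[192:320, 192:320, :]
        )
        assert crop.shape == (128, 128, 3)

    def test_corner_crop_matches_pad_then_slice_oracle(self, rng):
        pair = _big_pair(rng)
        p = PointAnnotation("big", 0, 0, "Acropora")
        crop = crop_patch(pair, p, "five")
        padded = np.pad(
            pair.stacked(), ((64, 64), (64, 64), (0, 0)), mode="reflect"
        )
        np.testing.assert_array_equal(crop, padded[0:128, 0:128, :])

    def test_constant_image_gives_constant_patch_anywhere(self):
        pair = RegisteredPair(
            "c", np.full((200, 200, 3), 0.3), np.full((200, 200, 2), 0.6)
        )
        for r, c in [(0, 0), (5, 199), (100, 100)]:
            crop = crop_patch(pair, PointAnnotation("c", r, c, "unknown"), "five")
            assert (crop[..., :3] == 0.3).all() and (crop[..., 3:] == 0.6).all()

    def test_invalid_warp_pixel_raises(self, rng):
        pair = _big_pair(rng)
        pair.valid_mask[10, 10] = False
        with pytest.raises(PointOnInvalidPixelError):
            crop_patch(pair, PointAnnotation("big", 10, 10, "unknown"), "flr")


class TestResizePatch:
    def test_constant_preserved(self):
        out = resize_patch(np.full((128, 128, 2), 0.42))
        np.testing.assert_allclose(out, 0.42, atol=1e-12)
        assert out.shape == (32, 32, 2)

    def test_checkerboard_mean_preserved(self):
        rr, cc = np.indices((128, 128))
        board = (((rr // 2) + (cc // 2)) % 2).astype(float)[..., None]
        out = resize_patch(board)
        assert abs(out.mean() - board.mean()) < 1e-6

    def test_linear_ramp_stays_linear(self):
        rr, cc = np.indices((128, 128))
        ramp = (0.3 * rr / 127 + 0.5 * cc / 127)[..., None]
        out = resize_patch(ramp)[..., 0]
        # fit an affine field to the output; residual should vanish
        rr32, cc32 = np.indices((32, 32))
        design = np.column_stack(
            [rr32.ravel(), cc32.ravel(), np.ones(32 * 32)]
        )
        coef, *_ = np.linalg.lstsq(design, out.ravel(), rcond=None)
        resid = out.ravel() - design @ coef
        assert np.abs(resid).max() < 1e-3

    def test_values_stay_within_input_range(self, rng):
        patch = rng.uniform(0.2, 0.8, (128, 128, 5))
        out = resize_patch(patch)
        assert out.min() >= patch.min() - 1e-12
        assert out.max() <= patch.max() + 1e-12

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            resize_patch(np.zeros((64, 64, 3)))


class TestAugment:
    def _patch(self, rng) -> PatchTensor:
        return PatchTensor(rng.uniform(0, 1, (32, 32, 3)), "Acropora", ("p", 1, 2))

    def test_exactly_eight_outputs_with_tags(self, rng):
        orbit = augment(self._patch(rng))
        assert len(orbit) == 8
        assert tuple(p.augmentation_tag for p in orbit) == D4_TAGS

    def test_constant_patch_gives_identical_arrays(self):
        patch = PatchTensor(np.full((32, 32, 2), 0.5), "unknown", ("p", 0, 0))
        orbit = augment(patch)
        for member in orbit:
            np.testing.assert_array_equal(member.pixels, patch.pixels)

    def test_asymmetric_patch_gives_eight_distinct_members(self, rng):
        orbit = augment(self._patch(rng))
        keys = {member.pixels.tobytes() for member in orbit}
        assert len(keys) == 8

    def test_orbit_closed_under_all_64_compositions(self, rng):
        patch = self._patch(rng)
        orbit = {m.pixels.tobytes() for m in augment(patch)}
        for member in augment(patch):
            for tag in D4_TAGS:
                composed = dihedral(member.pixels, tag)
                assert composed.tobytes() in orbit

    def test_group_action_permutes_orbit(self, rng):
        # applying one element to every member is a bijection of the orbit
        patch = self._patch(rng)
        orbit = [m.pixels for m in augment(patch)]
        for tag in D4_TAGS:
            mapped = {dihedral(px, tag).tobytes() for px in orbit}
            assert mapped == {px.tobytes() for px in orbit}


class TestDatasetAssembly:
    def test_augmented_dataset_has_8n_patches(self, small_pair, rng):
        points = [
            PointAnnotation("pair-0", int(rng.integers(64)), int(rng.integers(64)), "Faviidae")
            for _ in range(7)
        ]
        plain = extract_dataset({"pair-0": small_pair}, points, "five")
        augmented = extract_dataset(
            {"pair-0": small_pair}, points, "five", augment_patches=True
        )
        assert len(plain) == 7
        assert len(augmented) == 56

    def test_patch_dataset_roundtrip(self, small_pair, rng, tmp_path):
        from reeffusion.patching import load_patch_dataset, save_patch_dataset

        points = [
            PointAnnotation("pair-0", int(rng.integers(64)), int(rng.integers(64)), "Platygyra")
            for _ in range(3)
        ]
        patches = extract_dataset(
            {"pair-0": small_pair}, points, "flr", augment_patches=True
        )
        save_patch_dataset(tmp_path / "ds", patches)
        back = load_patch_dataset(tmp_path / "ds")
        assert len(back) == len(patches)
        for a, b in zip(patches, back):
            np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-6)
            assert (a.label, a.source, a.augmentation_tag) == (
                b.label, b.source, b.augmentation_tag
            )

    def test_modality_slices_match_five_channel_stack(self, small_pair):
        point = PointAnnotation("pair-0", 32, 32, "Acropora")
        five = extract_dataset({"pair-0": small_pair}, [point], "five")[0]
        ref = extract_dataset({"pair-0": small_pair}, [point], "ref")[0]
        flr = extract_dataset({"pair-0": small_pair}, [point], "flr")[0]
        np.testing.assert_array_equal(slice_modality(five, "ref").pixels, ref.pixels)
        np.testing.assert_array_equal(slice_modality(five, "flr").pixels, flr.pixels)
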