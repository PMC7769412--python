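"""Simulator tests: phantom construction, artifact injection, warping, datasets."""

import numpy as np
import pytest

from cxct.metrics import mae
from cxct.phantom_sim import (
    ArtifactSpec,
    DeformationSpec,
    PhantomSpec,
    artifact_field,
    corrupt,
    deform,
    displacement_field,
    generate_phantom,
    make_dataset,
)


class TestPhantom:
    def test_roi_values_are_the_configured_hu(self):
        spec = PhantomSpec(size=64, seed=3)
        img, body, rois = generate_phantom(spec)
        assert np.all(img[rois["bone_marrow"]] == spec.tissue_hu["bone_marrow"])
        assert np.all(img[rois["skin"]] == spec.tissue_hu["skin"])
        assert np.all(img[~body] == spec.tissue_hu["air"])

    def test_determinism_and_seed_variation(self):
        a, _, _ = generate_phantom(PhantomSpec(seed=5))
        b, _, _ = generate_phantom(PhantomSpec(seed=5))
        c, _, _ = generate_phantom(PhantomSpec(seed=6))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_hu_ordering_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(tissue_hu={"air": 0.0, "soft": -10.0, "skin": -140.0,
                                   "bone_marrow": 200.0, "bone_cortical": 700.0})

    def test_oversized_body_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(body_half_axes=(0.55, 0.3))


class TestCorruption:
    def test_zero_amplitudes_are_bit_exact_identity(self):
        img, body, _ = generate_phantom(PhantomSpec(seed=1))
        out = corrupt(img, body, ArtifactSpec(cupping_amplitude=0, n_streaks=0,
                                              streak_amplitude=0, noise_sigma=0))
        np.testing.assert_array_equal(out, img)

    def test_outside_body_unchanged(self):
        img, body, _ = generate_phantom(PhantomSpec(seed=2))
        out = corrupt(img, body, ArtifactSpec(seed=4))
        np.testing.assert_array_equal(out[~body], img[~body])

    def test_cupping_depresses_the_centre_by_its_amplitude(self):
        # odd size puts the body centre on an integer pixel
        spec = PhantomSpec(size=65, seed=0)
        img, body, _ = generate_phantom(spec)
        out = corrupt(img, body, ArtifactSpec(cupping_amplitude=80.0, n_streaks=0,
                                              noise_sigma=0))
        assert img[32, 32] - out[32, 32] == pytest.approx(80.0, abs=1e-9)
        # outermost body pixels barely move
        from scipy.ndimage import binary_erosion

        edge = body & ~binary_erosion(body)
        assert np.abs(out[edge] - img[edge]).max() < 8.0

    def test_injected_field_mae_matches_direct_summation(self):
        img, body, _ = generate_phantom(PhantomSpec(seed=7))
        spec = ArtifactSpec(seed=9)
        out = corrupt(img, body, spec)
        field = artifact_field(img.shape, body, spec)
        direct = np.abs(field[body]).sum() / body.sum()
        assert mae(img, out, mask=body) == pytest.approx(direct, abs=1e-9)

    def test_determinism(self):
        img, body, _ = generate_phantom(PhantomSpec(seed=1))
        a = corrupt(img, body, ArtifactSpec(seed=3))
        b = corrupt(img, body, ArtifactSpec(seed=3))
        np.testing.assert_array_equal(a, b)


class TestDeformation:
    def test_zero_displacement_is_identity(self):
        img, _, _ = generate_phantom(PhantomSpec(seed=1))
        np.testing.assert_array_equal(deform(img, DeformationSpec(max_displacement=0)), img)

    @pytest.mark.parametrize("seed", range(20))
    def test_field_respects_the_component_bound(self, seed):
        spec = DeformationSpec(max_displacement=4.0, seed=seed)
        disp = displacement_field((64, 64), spec)
        assert np.abs(disp).max() <= 4.0 + 1e-12

    def test_warp_determinism(self):
        img, _, _ = generate_phantom(PhantomSpec(seed=1))
        spec = DeformationSpec(max_displacement=4.0, seed=5)
        np.testing.assert_array_equal(deform(img, spec), deform(img, spec))

    def test_body_contours_stay_within_the_bound(self):
        from scipy.spatial.distance import directed_hausdorff

        img, body, _ = generate_phantom(PhantomSpec(seed=2))
        spec = DeformationSpec(max_displacement=4.0, seed=8)
        warped_mask = deform(body, spec, is_mask=True)
        a = np.argwhere(body ^ warped_mask)  # noqa: F841 sanity container
        pa = np.argwhere(body)
        pb = np.argwhere(warped_mask)
        h = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
        assert h <= 4.0 + 1.0  # bound + interpolation slack


class TestDataset:
    def test_split_arithmetic(self):
        ds = make_dataset(10, split=(0.8, 0.1, 0.1), master_seed=1)
        assert (len(ds.train), len(ds.val), len(ds.test)) == (8, 1, 1)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(3, split=(0.8, 0.1, 0.1), master_seed=1)

    def test_per_slice_structure(self):
        ds = make_dataset(4, split=(0.5, 0.25, 0.25),
                          deformation=DeformationSpec(max_displacement=3.0),
                          master_seed=2)
        for s in ds:
            assert not np.array_equal(s.input_image, s.clean_truth)  # artifacts present
            assert not np.array_equal(s.label_image, s.clean_truth)  # warp present
            # label differs from truth only through the warp: same value range
            assert s.label_image.min() >= s.clean_truth.min() - 1e-9
            assert s.label_image.max() <= s.clean_truth.max() + 1e-9

    def test_no_deformation_makes_label_equal_truth(self):
        ds = make_dataset(2, split=(0.5, 0.0, 0.5),
                          deformation=DeformationSpec(max_displacement=0.0),
                          master_seed=3)
        for s in ds:
            np.testing.assert_array_equal(s.label_image, s.clean_truth)
            assert mae(s.input_image, s.label_image) == pytest.approx(
                mae(s.input_image, s.clean_truth))

    def test_byte_identical_reruns(self):
        a = make_dataset(3, split=(1 / 3, 1 / 3, 1 / 3), master_seed=4)
        b = make_dataset(3, split=(1 / 3, 1 / 3, 1 / 3), master_seed=4)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.input_image, sb.input_image)
            np.testing.assert_array_equal(sa.label_image, sb.label_image)

    def test_rotation_augmentation_expands_train_only(self):
        ds = make_dataset(4, split=(0.5, 0.25, 0.25), augment_rotations=(90.0,),
                          master_seed=5)
        assert len(ds.train) == 4  # 2 originals + 2 rotated copies
        assert len(ds.val) == 1 and len(ds.test) == 1
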