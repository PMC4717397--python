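"""Voxel-fraction model, cartilage thresholding and volume computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synovol.imaging import (
    EstimationError,
    ImageVolume,
    IntensityModel,
    InvalidModelError,
    ShapeMismatchError,
    VoxelMask,
    cartilage_mask,
    compute_volumes,
    estimate_intensity_means,
    read_mask,
    read_volume,
    voxel_fraction,
    write_mask,
    write_report,
    write_volume,
)
from synovol.phantom import PhantomSpec, generate_phantom


@pytest.mark.parametrize(
    "intensity, expected",
    [
        (100.0, 0.0),  # I = m_f: pure fluid
        (300.0, 1.0),  # I = m_s: pure tissue
        (200.0, 0.5),  # midpoint of the linear mixture
        (310.0, 1.0),  # brighter than tissue: truncated
        (-50.0, 0.0),  # darker than fluid: truncated
    ],
)
def test_voxel_fraction_anchors_and_truncation(intensity, expected, default_model):
    assert voxel_fraction(intensity, default_model) == expected


def test_voxel_fraction_vectorized(default_model):
    grid = np.array([[[100.0, 200.0], [300.0, 400.0]]])
    np.testing.assert_allclose(
        voxel_fraction(grid, default_model), [[[0.0, 0.5], [1.0, 1.0]]]
    )


@given(st.floats(-1e6, 1e6))
@settings(max_examples=50, deadline=None)
def test_voxel_fraction_always_in_unit_interval(intensity):
    model = IntensityModel(m_f=100.0, m_s=300.0)
    assert 0.0 <= voxel_fraction(intensity, model) <= 1.0


def test_degenerate_model_rejected():
    with pytest.raises(InvalidModelError):
        IntensityModel(m_f=300.0, m_s=100.0)
    with pytest.raises(InvalidModelError):
        IntensityModel(m_f=100.0, m_s=100.0)


class TestCartilageMask:
    def test_plate_recovered_exactly_with_fixed_threshold(self, clean_phantom):
        post, pre, seg, truth = clean_phantom
        cart, thr = cartilage_mask(pre, seg, threshold=120.0)
        np.testing.assert_array_equal(cart.mask, truth.labels == 3)
        assert thr == 120.0

    def test_uniform_precontrast_gives_empty_mask(self):
        pre = ImageVolume(np.full((4, 4, 4), 40.0), (1, 1, 1))
        seg = VoxelMask(np.ones((4, 4, 4), bool))
        cart, _ = cartilage_mask(pre, seg, threshold=120.0)
        assert cart.count() == 0
        # auto threshold on a uniform region also yields no cartilage
        cart, _ = cartilage_mask(pre, seg, threshold=None)
        assert cart.count() == 0

    def test_otsu_misclassification_below_1pct_at_6sd_separation(self):
        # cartilage 200 vs soft 50 with noise SD 25: 6 SDs of separation
        post, pre, seg, truth = generate_phantom(
            PhantomSpec(pre_noise_sd=25.0, seed=4)
        )
        cart, thr = cartilage_mask(pre, seg)
        mis = np.sum(cart.mask != (truth.labels == 3)) / seg.count()
        assert 50.0 < thr < 200.0
        assert mis < 0.01

    def test_shape_mismatch_and_empty_segmentation(self):
        pre = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ShapeMismatchError):
            cartilage_mask(pre, VoxelMask(np.ones((3, 4, 4), bool)))
        with pytest.raises(ValueError):
            cartilage_mask(pre, VoxelMask(np.zeros((4, 4, 4), bool)))


class TestComputeVolumes:
    def _uniform(self, value, shape=(10, 10, 10)):
        return ImageVolume(np.full(shape, float(value)), (1.0, 1.0, 1.0))

    def test_all_tissue(self, default_model):
        seg = VoxelMask(np.ones((10, 10, 10), bool))
        cart = VoxelMask(np.zeros((10, 10, 10), bool))
        vols = compute_volumes(self._uniform(300), seg, cart, default_model)
        assert vols.stv_mm3 == pytest.approx(1000.0)
        assert vols.fluid_mm3 == pytest.approx(0.0)

    def test_half_fluid_exact_partition(self, default_model):
        grid = np.full((10, 10, 10), 300.0)
        grid[:5] = 100.0
        vols = compute_volumes(
            ImageVolume(grid, (1, 1, 1)),
            VoxelMask(np.ones((10, 10, 10), bool)),
            VoxelMask(np.zeros((10, 10, 10), bool)),
            default_model,
        )
        assert vols.stv_mm3 == pytest.approx(500.0)
        assert vols.fluid_mm3 == pytest.approx(500.0)

    def test_voxel_volume_uses_spacing(self, default_model):
        vol = ImageVolume(np.full((4, 4, 4), 300.0), (0.5, 0.5, 2.0))
        seg = VoxelMask(np.ones((4, 4, 4), bool))
        cart = VoxelMask(np.zeros((4, 4, 4), bool))
        vols = compute_volumes(vol, seg, cart, default_model)
        assert vols.stv_mm3 == pytest.approx(64 * 0.5)

    def test_cartilage_subset_enforced(self, default_model):
        vol = self._uniform(300, (4, 4, 4))
        seg = VoxelMask(np.zeros((4, 4, 4), bool))
        cart = VoxelMask(np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError, match="subset"):
            compute_volumes(vol, seg, cart, default_model)

    def test_monotone_in_intensity(self, noisy_phantom, default_model):
        post, pre, seg, truth = noisy_phantom
        cart = VoxelMask(truth.labels == 3)
        base = compute_volumes(post, seg, cart, default_model)
        brighter = ImageVolume(post.voxels + 15.0, post.spacing)
        up = compute_volumes(brighter, seg, cart, default_model)
        assert up.stv_mm3 >= base.stv_mm3

    @pytest.mark.parametrize("a, c", [(2.0, 0.0), (0.5, 100.0), (3.0, -40.0)])
    def test_affine_intensity_rescaling_invariance(self, noisy_phantom, default_model, a, c):
        post, pre, seg, truth = noisy_phantom
        cart = VoxelMask(truth.labels == 3)
        ref = compute_volumes(post, seg, cart, default_model)
        scaled = ImageVolume(a * post.voxels + c, post.spacing)
        model = IntensityModel(a * default_model.m_f + c, a * default_model.m_s + c)
        out = compute_volumes(scaled, seg, cart, model)
        assert out.stv_mm3 == pytest.approx(ref.stv_mm3, rel=1e-10)
        assert out.fluid_mm3 == pytest.approx(ref.fluid_mm3, rel=1e-10)


class TestEstimateIntensityMeans:
    def test_two_population_recovery_within_5_units(self):
        post, pre, seg, truth = generate_phantom(PhantomSpec(post_noise_sd=15.0, seed=3))
        cart = VoxelMask(truth.labels == 3)
        model = estimate_intensity_means(post, seg, cart)
        assert model.m_f == pytest.approx(100.0, abs=5.0)
        assert model.m_s == pytest.approx(300.0, abs=5.0)

    def test_user_model_passthrough(self, clean_phantom, default_model):
        post, pre, seg, truth = clean_phantom
        assert estimate_intensity_means(post, seg, model=default_model) is default_model

    def test_degenerate_region_raises(self):
        vol = ImageVolume(np.full((6, 6, 6), 42.0), (1, 1, 1))
        seg = VoxelMask(np.ones((6, 6, 6), bool))
        with pytest.raises(EstimationError):
            estimate_intensity_means(vol, seg)


class TestNiftiIO:
    def test_round_trip_preserves_shape_spacing_values(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.normal(100, 10, (6, 7, 8)).astype(np.float32),
                          (0.5, 0.5, 1.5))
        write_volume(vol, tmp_path / "v.nii.gz")
        back = read_volume(tmp_path / "v.nii.gz")
        assert back.shape == (6, 7, 8)
        assert back.spacing == pytest.approx(vol.spacing)
        np.testing.assert_allclose(back.voxels, vol.voxels, rtol=1e-6)

    def test_float_mask_loads_as_boolean(self, tmp_path):
        mask = VoxelMask(np.random.default_rng(1).random((5, 5, 5)) > 0.5)
        write_mask(mask, tmp_path / "m.nii.gz")
        back = read_mask(tmp_path / "m.nii.gz")
        assert back.mask.dtype == bool
        np.testing.assert_array_equal(back.mask, mask.mask)

    def test_2d_input_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((5, 5)), np.eye(4)), tmp_path / "flat.nii.gz")
        with pytest.raises(ValueError, match="3-D"):
            read_volume(tmp_path / "flat.nii.gz")

    def test_report_written(self, tmp_path, clean_phantom, default_model):
        import csv

        post, pre, seg, truth = clean_phantom
        cart = VoxelMask(truth.labels == 3)
        vols = compute_volumes(post, seg, cart, default_model)
        write_report(vols, tmp_path / "r.csv", scan_id="p0", model=default_model)
        with open(tmp_path / "r.csv") as fh:
            rows = list(csv.DictReader(fh))
        assert rows[0]["scan_id"] == "p0"
        assert float(rows[0]["stv_mm3"]) == pytest.approx(vols.stv_mm3)
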