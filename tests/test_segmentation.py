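"""Mask pipeline: MIP, pre-filter, histogram k-means, hole fill,
component selection and the composed 2D/3D segmentation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheromet.segmentation import (SegmentationParams, SpheroidNotFoundError,
                                    fill_holes, gaussian_prefilter,
                                    hkmeans_threshold, keep_largest_component,
                                    max_project, segment_spheroid)
from spheromet.stack import ChannelStack

from conftest import dice


def exhaustive_two_class_threshold(image):
    """Oracle: optimal 1D two-class split by exhaustive threshold search
    (minimum within-class sum of squares over all cut points)."""
    vals = np.sort(np.unique(image.ravel()))
    best, best_sse = None, np.inf
    flat = image.ravel()
    for cut in (vals[:-1] + vals[1:]) / 2.0:
        lo, hi = flat[flat <= cut], flat[flat > cut]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse:
            best, best_sse = cut, sse
    return best


class TestMaxProject:
    def test_single_slice_is_identity(self):
        img = np.random.default_rng(0).uniform(size=(1, 8, 9))
        stack = ChannelStack({"dapi": img}, (1, 1, 1))
        assert np.array_equal(max_project(stack, "dapi"), img[0])

    def test_single_hot_voxel_projects_through(self):
        vol = np.zeros((5, 6, 7))
        vol[3, 2, 4] = 8.5
        stack = ChannelStack({"dapi": vol}, (1, 1, 1))
        mip = max_project(stack, "dapi")
        assert mip[2, 4] == 8.5 and mip.sum() == 8.5

    def test_invariant_to_slice_permutation(self):
        vol = np.random.default_rng(1).uniform(size=(6, 10, 10))
        stack = ChannelStack({"dapi": vol}, (1, 1, 1))
        shuffled = ChannelStack({"dapi": vol[[4, 0, 5, 2, 1, 3]]}, (1, 1, 1))
        assert np.array_equal(max_project(stack, "dapi"),
                              max_project(shuffled, "dapi"))

    def test_unknown_channel_raises(self):
        stack = ChannelStack({"dapi": np.zeros((2, 3, 3))}, (1, 1, 1))
        with pytest.raises(KeyError, match="actin"):
            max_project(stack, "actin")


class TestGaussianPrefilter:
    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(2).uniform(size=(16, 16))
        assert np.array_equal(gaussian_prefilter(img, 0.0), img)

    def test_constant_image_preserved(self):
        img = np.full((32, 32), 7.25)
        assert np.allclose(gaussian_prefilter(img, 4.0), 7.25)

    def test_impulse_response_is_normalised_gaussian(self):
        img = np.zeros((101, 101))
        img[50, 50] = 3.0
        out = gaussian_prefilter(img, 3.0)
        assert out.sum() == pytest.approx(3.0, rel=1e-6)
        yy, xx = np.mgrid[:101, :101]
        kernel = np.exp(-((yy - 50) ** 2 + (xx - 50) ** 2) / (2 * 3.0**2))
        kernel = 3.0 * kernel / kernel.sum()
        # scipy truncates the kernel at 4 sigma; tolerance sits above the
        # analytic tail value at that radius (~2e-5)
        assert np.allclose(out, kernel, atol=5e-5)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_prefilter(np.zeros((4, 4)), -1.0)


class TestHKMeans:
    def test_two_valued_image_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        img = np.full((300, 300), 10.0)
        img[50:200, 50:200] = 200.0
        mask, info = hkmeans_threshold(img, 2, 10_000)
        oracle_cut = exhaustive_two_class_threshold(img)
        # same partition as the optimal split, threshold between the modes
        assert np.array_equal(mask, img > oracle_cut)
        assert 10.0 < info["threshold"] < 200.0

    def test_three_level_image_matches_oracle_partition(self):
        # k-means with 2 classes on three intensity levels: compare the
        # foreground partition against the exhaustive-search optimum
        img = np.concatenate([np.full(4000, 5.0), np.full(2000, 90.0),
                              np.full(2500, 110.0)]).reshape(100, 85)
        mask, _ = hkmeans_threshold(img, 2, 0)
        cut = exhaustive_two_class_threshold(img)
        assert np.array_equal(mask, img > cut)

    def test_min_size_filter_removes_small_object(self):
        img = np.full((300, 300), 10.0)
        img[10:81, 10:81] = 200.0  # 5,041 px < 10,000
        mask, _ = hkmeans_threshold(img, 2, 10_000)
        assert not mask.any()

    def test_min_size_zero_preserves_binary_foreground(self):
        rng = np.random.default_rng(4)
        binary = rng.uniform(size=(64, 64)) > 0.7
        binary[0, 0] = True  # ensure both classes present
        binary[1, 1] = False
        mask, _ = hkmeans_threshold(binary.astype(float), 2, 0)
        assert np.array_equal(mask, binary)

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="contrast"):
            mask, info = hkmeans_threshold(np.full((50, 50), 3.0), 2, 0)
        assert not mask.any() and info["threshold"] is None

    @pytest.mark.parametrize("factor", [0.5, 3.0, 1000.0])
    def test_foreground_invariant_to_intensity_scaling(self, factor):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 10, size=(80, 80))
        img[20:60, 20:60] += 100.0
        m1, _ = hkmeans_threshold(img, 2, 0)
        m2, _ = hkmeans_threshold(img * factor, 2, 0)
        assert np.array_equal(m1, m2)


class TestFillHoles:
    def test_solid_disk_unchanged(self):
        yy, xx = np.mgrid[:64, :64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        assert np.array_equal(fill_holes(disk), disk)

    def test_annulus_becomes_solid_disk(self):
        yy, xx = np.mgrid[:64, :64]
        r2 = (yy - 32) ** 2 + (xx - 32) ** 2
        annulus = (r2 <= 20**2) & (r2 >= 10**2)
        disk = r2 <= 20**2
        assert np.array_equal(fill_holes(annulus), disk)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_foreground_never_shrinks(self, seed):
        mask = np.random.default_rng(seed).uniform(size=(24, 24)) > 0.5
        filled = fill_holes(mask)
        assert filled.sum() >= mask.sum()
        assert (filled | mask == filled).all()


class TestKeepLargest:
    def test_largest_of_two_disks_kept(self):
        mask = np.zeros((60, 120), bool)
        yy, xx = np.mgrid[:60, :120]
        big = (yy - 30) ** 2 + (xx - 30) ** 2 <= 13**2  # ~530 px
        small = (yy - 30) ** 2 + (xx - 90) ** 2 <= 11**2  # ~380 px
        out = keep_largest_component(big | small)
        assert np.array_equal(out, big)

    def test_single_component_unchanged(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        assert np.array_equal(keep_largest_component(mask), mask)

    def test_equal_area_tie_breaks_to_first_in_scan_order(self):
        mask = np.zeros((10, 30), bool)
        mask[2:5, 2:5] = True
        mask[2:5, 20:23] = True
        out1 = keep_largest_component(mask)
        out2 = keep_largest_component(mask.copy())
        expected = np.zeros_like(mask)
        expected[2:5, 2:5] = True
        assert np.array_equal(out1, expected)
        assert np.array_equal(out1, out2)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            out = keep_largest_component(np.zeros((5, 5), bool))
        assert not out.any()


class TestSegmentSpheroid:
    def test_3d_dice_on_noiseless_sphere(self, noiseless_sphere):
        _, stack, truth = noiseless_sphere
        mask = segment_spheroid(stack, "dapi", SegmentationParams(mode="3d"))
        assert dice(mask.data, truth.occupancy) >= 0.95

    def test_2d_dice_at_default_noise(self, default_sphere):
        _, stack, truth = default_sphere
        mask = segment_spheroid(stack, "dapi", SegmentationParams(mode="2d"))
        assert dice(mask.data, truth.occupancy.any(axis=0)) >= 0.90

    def test_speckle_background_reports_no_spheroid(self):
        # bright specks only: every thresholded component is far below the
        # 10,000 px floor, so the size filter must empty the mask
        rng = np.random.default_rng(6)
        vol = np.zeros((20, 256, 256))
        hot = rng.integers(0, 256, size=(40, 2))
        vol[rng.integers(0, 20, 40), hot[:, 0], hot[:, 1]] = 200.0
        stack = ChannelStack({"dapi": vol}, (2.0, 0.5, 0.5))
        with pytest.raises(SpheroidNotFoundError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                segment_spheroid(stack, "dapi", SegmentationParams(mode="2d"))

    def test_idempotent_on_own_output(self, default_sphere):
        _, stack, _ = default_sphere
        params = SegmentationParams(mode="2d")
        mask = segment_spheroid(stack, "dapi", params)
        binary_stack = ChannelStack(
            {"dapi": mask.data[None].astype(float)},
            (1.0, *mask.spacing))
        again = segment_spheroid(binary_stack, "dapi",
                                 SegmentationParams(mode="2d", sigma=0.0))
        assert np.array_equal(again.data, mask.data)

    def test_provenance_is_populated(self, sphere_mask3d):
        prov = sphere_mask3d.provenance
        for key in ("sigma", "method", "threshold", "min_object_size",
                    "holes_filled"):
            assert key in prov
        assert prov["threshold"] is not None

    def test_raising_min_size_never_adds_foreground(self):
        img = np.full((300, 300), 10.0)
        img[50:200, 50:200] = 200.0
        img[250:260, 250:260] = 200.0
        m_lo, _ = hkmeans_threshold(img, 2, 50)
        m_hi, _ = hkmeans_threshold(img, 2, 10_000)
        assert (m_hi & ~m_lo).sum() == 0
        assert m_hi.sum() <= m_lo.sum()
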