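"""Image features against analytic and brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import disk_image, full_mask
from _oracles import glcm_stats_bruteforce

from ifcgate.features import (
    EventImage,
    Mask,
    channel_intensity,
    compute_mask,
    extract_features,
    gradient_rms,
    haralick_stats,
    major_axis_intensity,
    shape_features,
)


class TestComputeMask:
    def test_disk_recovered_within_boundary_tolerance(self):
        img = disk_image(radius=10)
        mask = compute_mask(img, "x", dark_foreground=False)
        true = disk_image(radius=10).channel("x") > 100
        # differ only at the digitized rim: one-pixel dilation of the
        # boundary must cover every disagreement
        disagreement = mask.pixels ^ true
        rim = ndimage.binary_dilation(true, iterations=1) & ~ndimage.binary_erosion(
            true, iterations=1
        )
        assert disagreement.sum() <= rim.sum()
        assert (disagreement & ~rim).sum() == 0

    def test_uniform_image_empty_mask(self):
        img = EventImage(channels={"x": np.full((32, 32), 7.0)})
        assert compute_mask(img, "x").n_pixels == 0

    def test_morphology_combined_hole_filling_idempotent(self):
        img = disk_image(radius=12)
        arr = img.channel("x")
        arr[24, 24] = 10.0  # poke a hole
        img2 = EventImage(channels={"x": arr})
        mask = compute_mask(img2, "x", "morphology_combined", dark_foreground=False)
        refilled = ndimage.binary_fill_holes(mask.pixels)
        assert np.array_equal(refilled, mask.pixels)

    def test_brightfield_polarity_autodetected(self):
        # dark object on bright background
        rr, cc = np.mgrid[0:48, 0:48]
        disk = (rr - 24) ** 2 + (cc - 24) ** 2 <= 100
        img = EventImage(channels={"bf": np.where(disk, 50.0, 220.0)})
        mask = compute_mask(img, "bf")
        assert mask.pixels[24, 24] and not mask.pixels[0, 0]


class TestGradientRms:
    def test_constant_image_zero(self):
        img = EventImage(channels={"x": np.full((20, 20), 5.0)})
        assert gradient_rms(img, "x", full_mask((20, 20))) == 0.0

    def test_blur_strictly_reduces_sharpness(self):
        sharp = disk_image(radius=8)
        blurred = EventImage(
            channels={"x": ndimage.gaussian_filter(sharp.channel("x"), 3.0)}
        )
        mask = full_mask((48, 48))
        assert gradient_rms(sharp, "x", mask) > gradient_rms(blurred, "x", mask)

    def test_invariant_under_intensity_scaling(self):
        img = disk_image(radius=8)
        scaled = EventImage(channels={"x": img.channel("x") * 10.0})
        mask = full_mask((48, 48))
        assert gradient_rms(img, "x", mask) == pytest.approx(
            gradient_rms(scaled, "x", mask), rel=1e-12
        )

    def test_empty_mask_sentinel(self):
        img = disk_image()
        assert np.isnan(gradient_rms(img, "x", Mask(np.zeros((48, 48), bool))))


class TestShapeFeatures:
    def test_solid_square(self):
        mask = Mask(np.pad(np.ones((10, 10), bool), 5))
        area, aspect, _ = shape_features(mask, pixel_size_um=1.0)
        assert area == 100.0
        assert aspect == pytest.approx(1.0)

    def test_digitized_ellipse_aspect(self):
        rr, cc = np.mgrid[0:60, 0:60]
        ellipse = ((cc - 30) / 20.0) ** 2 + ((rr - 30) / 5.0) ** 2 <= 1.0
        area, aspect, major = shape_features(Mask(ellipse), 1.0)
        assert aspect == pytest.approx(0.25, abs=0.05)
        assert major == pytest.approx(40.0, rel=0.1)  # 2a for semi-axis a=20

    def test_aspect_invariant_under_rotation(self):
        rr, cc = np.mgrid[0:80, 0:80]
        theta = np.deg2rad(37.0)
        u = (cc - 40) * np.cos(theta) + (rr - 40) * np.sin(theta)
        v = -(cc - 40) * np.sin(theta) + (rr - 40) * np.cos(theta)
        rotated = (u / 20.0) ** 2 + (v / 5.0) ** 2 <= 1.0
        _, aspect, _ = shape_features(Mask(rotated), 1.0)
        assert aspect == pytest.approx(0.25, abs=0.05)

    def test_empty_mask_sentinel(self):
        out = shape_features(Mask(np.zeros((8, 8), bool)), 1.0)
        assert all(np.isnan(v) for v in out)


class TestHaralick:
    def test_constant_image(self):
        img = EventImage(channels={"x": np.full((12, 12), 4.0)})
        e_mean, e_std, h_mean, h_std = haralick_stats(img, "x", full_mask((12, 12)), 1, 8)
        assert (e_mean, e_std, h_mean, h_std) == (0.0, 0.0, 1.0, 0.0)

    def test_checkerboard_matches_hand_computation(self):
        """4x4 checkerboard, g=1, levels=2: axial GLCMs are pure
        disagreement (entropy 1, homogeneity 1/2), diagonal GLCMs pure
        agreement at 10:8 (entropy ~0.9911, homogeneity 1)."""
        cb = (np.indices((4, 4)).sum(0) % 2).astype(float)
        img = EventImage(channels={"x": cb})
        e_mean, e_std, h_mean, h_std = haralick_stats(img, "x", full_mask((4, 4)), 1, 2)
        p = np.array([10, 8]) / 18.0
        ent_diag = -(p * np.log2(p)).sum()
        ents = [1.0, ent_diag, 1.0, ent_diag]
        homs = [0.5, 1.0, 0.5, 1.0]
        assert e_mean == pytest.approx(np.mean(ents))
        assert e_std == pytest.approx(np.std(ents))
        assert h_mean == pytest.approx(np.mean(homs))
        assert h_std == pytest.approx(np.std(homs))

    @pytest.mark.parametrize("g", [1, 2, 3])
    @pytest.mark.parametrize("levels", [2, 4, 8])
    def test_matches_bruteforce_on_random_images(self, g, levels):
        rng = np.random.default_rng(g * 100 + levels)
        for _ in range(10):
            arr = rng.random((9, 9)) * 50
            mask = rng.random((9, 9)) > 0.25
            if mask.sum() < 2:
                continue
            img = EventImage(channels={"x": arr})
            got = haralick_stats(img, "x", Mask(mask), g, levels)
            want = glcm_stats_bruteforce(arr, mask, g, levels)
            if want is None:
                assert all(np.isnan(v) for v in got)
            else:
                np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_skimage_cross_check_full_mask_g1(self):
        """At g=1 with a full mask our matrices coincide with skimage's
        graycomatrix convention; entropy computed from its matrices must
        agree."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(0)
        arr = rng.integers(0, 8, (16, 16))
        img = EventImage(channels={"x": arr * (7.0 / 7.0)})
        e_mean, _, _, _ = haralick_stats(img, "x", full_mask((16, 16)), 1, 8)
        glcm = graycomatrix(
            arr.astype(np.uint8),
            [1],
            [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=8,
            symmetric=True,
            normed=True,
        )
        ents = []
        for k in range(4):
            p = glcm[:, :, 0, k]
            nz = p[p > 0]
            ents.append(-(nz * np.log2(nz)).sum())
        assert e_mean == pytest.approx(np.mean(ents), rel=1e-10)

    def test_noise_increases_entropy_on_average(self):
        rng = np.random.default_rng(3)
        deltas = []
        for i in range(100):
            base = ndimage.gaussian_filter(rng.random((24, 24)), 2.0) * 100
            noisy = base + rng.normal(0, 10, base.shape)
            mask = full_mask((24, 24))
            e0 = haralick_stats(EventImage(channels={"x": base}), "x", mask, 1, 16)[0]
            e1 = haralick_stats(EventImage(channels={"x": noisy}), "x", mask, 1, 16)[0]
            deltas.append(e1 - e0)
        assert np.mean(deltas) > 0

    def test_offset_larger_than_mask_sentinel(self):
        img = EventImage(channels={"x": np.random.default_rng(0).random((6, 6))})
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        out = haralick_stats(img, "x", Mask(mask), granularity=5, levels=4)
        assert all(np.isnan(v) for v in out)


class TestIntensityFeatures:
    def test_uniform_weights_equal_shape_major_axis(self):
        img = disk_image(radius=9)
        mask = Mask(img.channel("x") > 100)
        _, _, major_shape = shape_features(mask, 1.0)
        major_int = major_axis_intensity(
            EventImage(channels={"x": np.where(mask.pixels, 3.0, 0.0)}), "x", mask, 1.0
        )
        assert major_int == pytest.approx(major_shape, rel=1e-6)

    def test_end_loaded_rod_longer_than_uniform(self):
        rod = np.zeros((20, 40), bool)
        rod[8:12, 5:35] = True
        uniform = np.where(rod, 1.0, 0.0)
        loaded = uniform.copy()
        loaded[:, 5:10] *= 10.0
        loaded[:, 30:35] *= 10.0
        m = Mask(rod)
        a = major_axis_intensity(EventImage(channels={"x": uniform}), "x", m, 1.0)
        b = major_axis_intensity(EventImage(channels={"x": loaded}), "x", m, 1.0)
        assert b > a

    def test_invariant_under_intensity_scaling(self):
        img = disk_image(radius=8)
        mask = Mask(img.channel("x") > 100)
        scaled = EventImage(channels={"x": img.channel("x") * 7.0})
        assert major_axis_intensity(img, "x", mask, 1.0) == pytest.approx(
            major_axis_intensity(scaled, "x", mask, 1.0), rel=1e-12
        )

    def test_channel_intensity_zero_cases(self):
        zero = EventImage(channels={"x": np.zeros((16, 16))})
        assert channel_intensity(zero, "x", full_mask((16, 16))) == 0.0
        img = disk_image()
        assert channel_intensity(img, "x", Mask(np.zeros((48, 48), bool))) == 0.0

    def test_additive_offset_cancelled_by_background_subtraction(self):
        img = disk_image(radius=8)
        mask = Mask(img.channel("x") > 100)
        shifted = EventImage(channels={"x": img.channel("x") + 37.0})
        assert channel_intensity(img, "x", mask) == pytest.approx(
            channel_intensity(shifted, "x", mask), rel=1e-9
        )


def test_extract_features_returns_canonical_columns():
    from ifcgate.synthetic_data import render_event_image

    record = dict(
        true_label="active", rsg_intensity=1200.0, pi_intensity=4.0,
        area_um2=1.1, aspect_ratio=0.95,
    )
    fv = extract_features(render_event_image(record, seed=1))
    row = fv.as_row()
    for col in ("gradient_rms", "area_um2", "aspect_ratio",
                "h_entropy_std_bf_9", "h_entropy_std_bf_11",
                "h_homogeneity_std_bf_11", "h_entropy_std_rsg_9",
                "major_axis_intensity_um"):
        assert col in row and np.isfinite(row[col])
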