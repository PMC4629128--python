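"""Segmentation methods and marker strategies."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from netextract.errors import DegenerateMarkerError, ParameterError
from netextract.segmentation import (
    SURE_BG,
    SURE_FG,
    adaptive_threshold,
    external_binary,
    grabcut,
    marker_adaptive,
    marker_distance_transform,
    marker_erosion,
    otsu,
    watershed,
)
from netextract import generate_truth_graph, render_graph

from conftest import render_stroke


def _brute_force_otsu_mask(gray):
    """Maximize between-class variance by exhaustive threshold search."""
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    levels = np.arange(256)
    best_t, best_var = 0, -1.0
    for t in range(255):
        w0 = p[: t + 1].sum()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[: t + 1] * p[: t + 1]).sum() / w0
        mu1 = (levels[t + 1 :] * p[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return gray > best_t


class TestOtsu:
    def test_bimodal_exact_split(self):
        img = np.full((10, 10), 20, np.uint8)
        img[3:7, 3:7] = 220
        assert np.array_equal(otsu(img), img == 220)

    def test_constant_image_empty_foreground(self):
        assert not otsu(np.full((8, 8), 130, np.uint8)).any()

    def test_two_level_histogram_matches_brute_force(self):
        # 100 pixels at 20, 50 pixels at 220
        gray = np.concatenate([np.full(100, 20), np.full(50, 220)])
        gray = np.pad(gray, (0, 6), constant_values=20).reshape(12, 13).astype(np.uint8)
        assert np.array_equal(otsu(gray), _brute_force_otsu_mask(gray))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_images_match_brute_force(self, seed):
        gray = np.random.default_rng(seed).integers(0, 256, (24, 24), np.uint8)
        assert np.array_equal(otsu(gray), _brute_force_otsu_mask(gray))

    def test_invert_flag(self):
        img = np.full((8, 8), 200, np.uint8)
        img[2:5, 2:5] = 15  # dark structure on light background
        assert np.array_equal(otsu(img, invert=True), img == 15)


class TestAdaptive:
    def test_linear_ramp_invariance(self):
        """The foreground mask is unchanged by an additive background ramp
        (pixelwise, away from a one-block border of the structure)."""
        base = render_stroke((96, 96), (10, 48), (86, 48), 5)
        ramp = np.broadcast_to(np.linspace(0, 30, 96), (96, 96))
        ramped = np.clip(base.astype(float) + ramp, 0, 255).astype(np.uint8)
        a = adaptive_threshold(base, block=31, offset=4)
        b = adaptive_threshold(ramped, block=31, offset=4)
        # compare on rows well inside the image
        assert np.array_equal(a[33:63], b[33:63])

    def test_constant_image_is_empty(self):
        assert not adaptive_threshold(np.full((32, 32), 99, np.uint8), block=11, offset=2).any()

    def test_single_bright_line_recovered(self):
        img = render_stroke((64, 64), (5, 32), (58, 32), 3)
        mask = adaptive_threshold(img, block=21, offset=4)
        truth = otsu(img)
        assert (mask & truth).sum() / truth.sum() > 0.99

    def test_block_validation(self):
        img = np.zeros((16, 16), np.uint8)
        with pytest.raises(ParameterError):
            adaptive_threshold(img, block=8)
        with pytest.raises(ParameterError):
            adaptive_threshold(img, block=99)


class TestMarkers:
    def test_erosion_of_solid_square(self):
        guess = np.zeros((30, 30), bool)
        guess[5:25, 5:25] = True  # 20x20 square
        marker = marker_erosion(guess, iterations=1)
        fg = marker == SURE_FG
        assert fg.sum() == 18 * 18
        assert fg[6:24, 6:24].all()
        assert (marker[guess] != SURE_BG).all()

    def test_distance_transform_disk(self):
        yy, xx = np.ogrid[:40, :40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
        marker = marker_distance_transform(disk, fraction=0.5)
        fg = marker == SURE_FG
        # exact EDT of a disk: the half-max region is a concentric disk of
        # roughly half the radius
        dist_from_center = np.hypot(yy - 20, xx - 20)
        assert fg[dist_from_center <= 4].all()
        assert not fg[(dist_from_center > 7) & disk].any()

    def test_single_pixel_guess_degenerates(self):
        guess = np.zeros((16, 16), bool)
        guess[8, 8] = True
        with pytest.raises(DegenerateMarkerError, match="iterations=1"):
            marker_erosion(guess, iterations=1)

    def test_adaptive_marker_matches_composition(self):
        img = render_stroke((64, 64), (5, 30), (58, 34), 7)
        direct = marker_adaptive(img, block=21, offset=4, iterations=1)
        composed = marker_erosion(adaptive_threshold(img, block=21, offset=4), 1)
        assert np.array_equal(direct, composed)


class TestWatershed:
    def test_ideal_render_matches_otsu_within_one_pixel(self):
        img = render_stroke((96, 96), (10, 40), (86, 56), 7)
        truth = otsu(img)
        mask = watershed(img, marker_erosion(truth, 1))
        grown = ndi.binary_dilation(truth, np.ones((3, 3), bool))
        shrunk = ndi.binary_erosion(truth, np.ones((3, 3), bool))
        assert (mask | grown).sum() == grown.sum()  # mask within truth+1px
        assert (mask & shrunk).sum() == shrunk.sum()  # covers truth-1px

    def test_all_foreground_marker(self):
        img = np.full((32, 32), 128, np.uint8)
        marker = np.full((32, 32), SURE_FG, np.int8)
        marker[0, 0] = SURE_BG
        mask = watershed(img, marker)
        assert mask.sum() >= 32 * 32 - 1

    def test_two_blobs_both_recovered(self):
        img = np.full((64, 64), 20, np.uint8)
        img[10:25, 10:25] = 220
        img[40:55, 40:55] = 220
        marker = marker_erosion(otsu(img), 1)
        mask = watershed(img, marker)
        _, n = ndi.label(mask)
        assert n == 2

    def test_missing_seed_class_rejected(self):
        img = np.zeros((16, 16), np.uint8)
        with pytest.raises(DegenerateMarkerError):
            watershed(img, np.zeros((16, 16), np.int8))


@pytest.fixture(scope="module")
def small_render():
    g = generate_truth_graph(
        n_vertices=5, shape=(96, 96), margin=16, min_separation=28,
        width_range=(3, 7), seed=5,
    )
    return render_graph(g, shape=(96, 96))


class TestGrabCut:
    def test_high_contrast_render_matches_otsu(self, small_render):
        truth = otsu(small_render)
        mask = grabcut(small_render, marker_erosion(truth, 1), iterations=2)
        grown = ndi.binary_dilation(truth, np.ones((3, 3), bool))
        assert (mask & truth).sum() / truth.sum() > 0.99
        assert (mask & ~grown).sum() <= 0.01 * truth.sum()

    def test_all_pinned_returns_marker(self, small_render):
        truth = otsu(small_render)
        marker = np.where(truth, SURE_FG, SURE_BG).astype(np.int8)
        assert np.array_equal(grabcut(small_render, marker, iterations=1), truth)

    def test_blurred_render_widens_foreground(self, small_render):
        from netextract import condition_blur

        truth = otsu(small_render)
        blurred = condition_blur(small_render, sigma=2.0)
        mask = grabcut(blurred, marker_erosion(otsu(blurred), 1), iterations=2)
        # blurring makes the strokes appear wider
        assert ndi.distance_transform_edt(mask).max() > ndi.distance_transform_edt(truth).max()
        assert mask.sum() > truth.sum()

    def test_iterations_validated(self, small_render):
        with pytest.raises(ParameterError):
            grabcut(small_render, marker_erosion(otsu(small_render), 1), iterations=0)


def test_external_binary_passthrough():
    img = np.zeros((8, 8), np.uint8)
    img[1:3] = 255
    assert np.array_equal(external_binary(img), img == 255)


def test_near_ceiling_pixel_recovery_on_ideal_render():
    """All methods except the distance-transform watershed recover at
    least 99% of the stroke pixels of a clean render."""
    g = generate_truth_graph(
        n_vertices=5, shape=(96, 96), margin=16, min_separation=28,
        width_range=(3, 7), seed=7,
    )
    img = render_graph(g, shape=(96, 96))
    truth = otsu(img)
    masks = {
        "otsu": truth,
        "adaptive": adaptive_threshold(img, block=31, offset=4),
        "watershed_de": watershed(img, marker_erosion(truth, 1)),
        "watershed_ad": watershed(img, marker_adaptive(img, 31, 4, 1)),
        "grabcut_de": grabcut(img, marker_erosion(truth, 1), iterations=2),
    }
    for name, mask in masks.items():
        recovery = (mask & truth).sum() / truth.sum()
        assert recovery >= 0.99, f"{name}: {recovery:.4f}"


def test_segmentation_is_deterministic():
    img = render_stroke((64, 64), (6, 20), (58, 44), 5)
    for fn in (
        lambda: otsu(img),
        lambda: adaptive_threshold(img, 21, 4),
        lambda: watershed(img, marker_erosion(otsu(img), 1)),
        lambda: grabcut(img, marker_erosion(otsu(img), 1), iterations=2),
    ):
        assert np.array_equal(fn(), fn())
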