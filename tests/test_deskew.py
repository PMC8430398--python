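"""Enhancement and deskew: enlarge, adaptive threshold, key line, rotate/crop."""

import math

import numpy as np
import pytest

from pumpscribe import (
    DeskewParams,
    LineFit,
    PixelRect,
    adaptive_mean_binarize,
    enlarge,
    find_key_line,
    locate_display,
    rotate_and_crop,
)
from pumpscribe.errors import DegenerateCrop, InvalidParameter, KeyLineNotFound
from pumpscribe.synthetic import DisplaySpec, render_frame


def brute_force_binarize(img: np.ndarray, p: DeskewParams) -> np.ndarray:
    """Independent per-pixel oracle: explicit neighbourhood loop, replicate border."""
    h, w = img.shape
    r = p.block_size // 2
    out = np.empty((h, w), dtype=np.uint8)
    n = p.block_size * p.block_size
    for y in range(h):
        for x in range(w):
            s = 0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    s += int(img[yy, xx])
            if p.polarity == "dark-on-light":
                text = n * (float(img[y, x]) + p.offset_c) < s
            else:
                text = n * (float(img[y, x]) - p.offset_c) > s
            out[y, x] = 0 if text else 255
    return out


class TestEnlarge:
    def test_factor_one_is_byte_identity(self, rng):
        img = rng.integers(0, 256, size=(20, 30)).astype(np.uint8)
        assert (enlarge(img, 1) == img).all()

    def test_dimensions_scale_and_round(self):
        img = np.zeros((80, 100), dtype=np.uint8)
        assert enlarge(img, 2).shape == (160, 200)
        assert enlarge(img, 1.5).shape == (120, 150)

    def test_constant_image_stays_constant(self):
        img = np.full((10, 10), 77, dtype=np.uint8)
        assert (enlarge(img, 3) == 77).all()

    def test_factor_below_one_is_rejected(self):
        with pytest.raises(InvalidParameter):
            enlarge(np.zeros((5, 5), dtype=np.uint8), 0.5)


class TestAdaptiveMeanBinarize:
    def test_constant_image_is_uniform_background(self):
        p = DeskewParams()
        out = adaptive_mean_binarize(np.full((40, 40), 99, dtype=np.uint8), p)
        assert (out == 255).all()

    def test_dark_glyph_on_bright_field(self):
        p = DeskewParams(block_size=9, offset_c=5)
        img = np.full((30, 30), 220, dtype=np.uint8)
        img[10:20, 12:18] = 30
        out = adaptive_mean_binarize(img, p)
        assert (out[12:18, 13:17] == 0).all()  # glyph interior black
        assert (out[:5, :5] == 255).all()  # far field white

    def test_inverted_polarity_recovers_the_same_glyph_mask(self):
        img = np.full((30, 30), 220, dtype=np.uint8)
        img[10:20, 12:18] = 30
        out_dark = adaptive_mean_binarize(img, DeskewParams(block_size=9))
        out_light = adaptive_mean_binarize(255 - img, DeskewParams(block_size=9, polarity="light-on-dark"))
        assert (out_dark == out_light).all()

    @pytest.mark.parametrize("polarity", ["dark-on-light", "light-on-dark"])
    @pytest.mark.parametrize("block_size", [3, 5, 11])
    def test_matches_brute_force_oracle_exactly(self, rng, polarity, block_size):
        p = DeskewParams(block_size=block_size, offset_c=7, polarity=polarity)
        for _ in range(5):
            h, w = rng.integers(4, 33, size=2)
            img = rng.integers(0, 256, size=(int(h), int(w))).astype(np.uint8)
            assert (adaptive_mean_binarize(img, p) == brute_force_binarize(img, p)).all()

    def test_even_block_size_is_rejected(self):
        with pytest.raises(InvalidParameter):
            DeskewParams(block_size=30)


def _bar_image(w=800, h=600, bar_y=100, bar_h=4, angle=0.0):
    from skimage.transform import rotate

    img = np.full((h, w), 255, dtype=np.uint8)
    img[bar_y : bar_y + bar_h, :] = 0
    if angle:
        img = rotate(img.astype(float), angle, resize=False, order=0, cval=255.0,
                     preserve_range=True).astype(np.uint8)
        img = np.where(img < 128, 0, 255).astype(np.uint8)
    return img


class TestFindKeyLine:
    def test_full_width_horizontal_bar_has_zero_angle(self):
        line = find_key_line(_bar_image(), DeskewParams())
        assert line.angle_degrees == pytest.approx(0.0, abs=0.01)
        assert line.source_rect.w >= 600  # three quarters of 800

    def test_rotated_bar_angle_recovered_within_half_degree(self):
        for true in (+5.0, -5.0):
            line = find_key_line(_bar_image(bar_y=300, angle=true), DeskewParams())
            assert abs(line.angle_degrees - true) <= 0.5

    def test_thinnest_qualifying_bar_is_chosen(self):
        img = np.full((600, 800), 255, dtype=np.uint8)
        img[100:112, :] = 0  # 12 px tall
        img[300:304, :] = 0  # 4 px tall -> winner
        line = find_key_line(img, DeskewParams())
        assert line.source_rect.y == 300 and line.source_rect.h == 4

    def test_narrow_shapes_do_not_qualify(self):
        img = np.full((600, 800), 255, dtype=np.uint8)
        img[100:104, 0:500] = 0  # 500 < 0.75 * 800
        with pytest.raises(KeyLineNotFound):
            find_key_line(img, DeskewParams())


class TestRotateAndCrop:
    def test_vertical_crop_lands_at_the_5_and_90_percent_rows(self):
        h, w = 1000, 800
        img = np.full((h, w), 255, dtype=np.uint8)
        img[500:504, :] = 0
        line = LineFit(angle_degrees=0.0, point=(400.0, 502.0), source_rect=PixelRect(0, 500, w, 4))
        out = rotate_and_crop(img, line, DeskewParams())
        # rows floor(0.05*1000)=50 .. floor(0.90*1000)=900, all columns
        assert out.shape == (850, w)

    def test_deskewed_text_is_horizontal_within_tolerance(self):
        spec = DisplaySpec(lines=("HEPARIN 5 UNITS/HR",), rotation_degrees=-3.0, seed=6)
        frame, gt = render_frame(spec)
        p = DeskewParams()
        _, crop = locate_display(frame)
        binary = adaptive_mean_binarize(enlarge(crop, p.enlarge_factor), p)
        line = find_key_line(binary, p)
        out = rotate_and_crop(binary, line, p)
        # re-estimate the residual angle on the deskewed output
        residual = find_key_line(out, DeskewParams(min_width_fraction=0.5))
        assert abs(residual.angle_degrees) <= 0.5

    def test_opposite_rotations_compose_to_near_identity(self):
        from skimage.transform import rotate

        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(0)
        img = np.full((200, 200), 255.0)
        # smooth content: bilinear resampling is only near-exact on
        # band-limited images, not on pixel noise
        img[60:140, 40:160] = gaussian_filter(
            rng.integers(0, 256, size=(80, 120)).astype(float), 4.0
        )
        once = rotate(img, 7.0, order=1, mode="constant", cval=255.0, preserve_range=True)
        back = rotate(once, -7.0, order=1, mode="constant", cval=255.0, preserve_range=True)
        safe = (slice(70, 130), slice(60, 140))
        assert np.abs(back[safe] - img[safe]).mean() <= 2.0

    def test_empty_crop_is_degenerate(self):
        img = np.full((1, 100), 255, dtype=np.uint8)
        line = LineFit(angle_degrees=0.0, point=(50.0, 0.0), source_rect=PixelRect(0, 0, 100, 1))
        with pytest.raises(DegenerateCrop):
            rotate_and_crop(img, line, DeskewParams())


@pytest.mark.parametrize("true_angle", [-10, -5, -2, 0, 2, 5, 10])
def test_deskew_recovery_across_rendered_angles(true_angle):
    """The estimated rotation matches the render parameter within 0.5 degrees."""
    p = DeskewParams()
    spec = DisplaySpec(
        lines=("PROPOFOL 20 ML/HR 3:45",),
        rotation_degrees=float(true_angle),
        seed=100 + true_angle,
    )
    frame, gt = render_frame(spec)
    _, crop = locate_display(frame)
    binary = adaptive_mean_binarize(enlarge(crop, p.enlarge_factor), p)
    line = find_key_line(binary, p)
    assert abs(line.angle_degrees - gt.rotation_degrees) <= 0.5
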