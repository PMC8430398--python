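"""Display localization: grayscale conversion, edge tracing, contours, crop."""

import numpy as np
import pytest

from pumpscribe import PixelRect, find_contour_rects, locate_display, to_grayscale, trace_edges
from pumpscribe.errors import DisplayNotFound, InvalidImage, InvalidParameter
from pumpscribe.synthetic import DisplaySpec, render_frame, render_suite


def _bfs_components(mask):
    """Independent connected-component bounding-box oracle (8-connectivity)."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    boxes = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            x0 = x1 = sx
            y0 = y1 = sy
            while stack:
                y, x = stack.pop()
                x0, x1 = min(x0, x), max(x1, x)
                y0, y1 = min(y0, y), max(y1, y)
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            boxes.append((x0, y0, x1 - x0 + 1, y1 - y0 + 1))
    return sorted(boxes)


class TestToGrayscale:
    def test_equal_channels_map_to_the_common_value(self):
        img = np.full((4, 5, 3), 200, dtype=np.uint8)
        assert (to_grayscale(img) == 200).all()

    def test_grayscale_input_is_returned_byte_identical(self):
        img = np.arange(30, dtype=np.uint8).reshape(5, 6)
        out = to_grayscale(img)
        assert out.dtype == np.uint8 and (out == img).all()

    def test_red_is_brighter_than_blue_under_luminance_weights(self):
        red = np.zeros((1, 1, 3), dtype=np.uint8)
        red[..., 0] = 255
        blue = np.zeros((1, 1, 3), dtype=np.uint8)
        blue[..., 2] = 255
        # hand-computed: 0.299*255 = 76.2 vs 0.114*255 = 29.1
        assert to_grayscale(red)[0, 0] == 76
        assert to_grayscale(blue)[0, 0] == 29
        assert to_grayscale(red)[0, 0] > to_grayscale(blue)[0, 0]

    def test_empty_or_misshaped_input_is_rejected(self):
        with pytest.raises(InvalidImage):
            to_grayscale(np.zeros((0, 5), dtype=np.uint8))
        with pytest.raises(InvalidImage):
            to_grayscale(np.zeros((3, 3, 4), dtype=np.uint8))


class TestTraceEdges:
    def test_constant_image_has_no_edges(self):
        img = np.full((40, 60), 120, dtype=np.uint8)
        assert trace_edges(img, 50, 150).sum() == 0

    def test_bright_rectangle_yields_a_closed_ring_at_its_bounds(self):
        img = np.zeros((200, 300), dtype=np.uint8)
        img[70:130, 100:200] = 220  # contrast 220, well above the high threshold
        edges = trace_edges(img, 50, 150)
        ys, xs = np.nonzero(edges)
        assert ys.size > 0
        assert abs(xs.min() - 100) <= 1 and abs(xs.max() - 199) <= 1
        assert abs(ys.min() - 70) <= 1 and abs(ys.max() - 129) <= 1

    def test_contrast_below_low_threshold_gives_empty_edge_map(self):
        img = np.zeros((200, 300), dtype=np.uint8)
        img[70:130, 100:200] = 40  # below low threshold of 50
        assert trace_edges(img, 50, 150).sum() == 0

    def test_thresholds_outside_range_are_rejected(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(InvalidParameter):
            trace_edges(img, -1, 100)
        with pytest.raises(InvalidParameter):
            trace_edges(img, 50, 300)
        with pytest.raises(InvalidParameter):
            trace_edges(img, 150, 50)


class TestFindContourRects:
    def test_blank_image_yields_no_groups(self):
        assert find_contour_rects(np.zeros((20, 20), dtype=np.uint8)) == []

    def test_two_disjoint_squares_recover_their_bounds(self):
        img = np.zeros((200, 200), dtype=np.uint8)
        img[10:30, 10:30] = 255
        img[100:140, 100:140] = 255
        groups = find_contour_rects(img, foreground="white")
        rects = sorted((g.bounding.x, g.bounding.y, g.bounding.w, g.bounding.h) for g in groups)
        assert rects == [(10, 10, 20, 20), (100, 100, 40, 40)]

    def test_black_foreground_polarity(self):
        img = np.full((60, 60), 255, dtype=np.uint8)
        img[20:40, 15:45] = 0
        groups = find_contour_rects(img, foreground="black")
        assert len(groups) == 1
        b = groups[0].bounding
        assert (b.x, b.y, b.w, b.h) == (15, 20, 30, 20)

    def test_bounding_contains_every_contour_point(self):
        img = np.zeros((50, 50), dtype=np.uint8)
        img[5:20, 8:30] = 255
        (g,) = find_contour_rects(img)
        xs, ys = g.points[:, 0], g.points[:, 1]
        assert xs.min() >= g.bounding.x - 0.5 and xs.max() <= g.bounding.x2 - 0.5
        assert ys.min() >= g.bounding.y - 0.5 and ys.max() <= g.bounding.y2 - 0.5

    def test_agrees_with_bfs_oracle_on_random_small_images(self, rng):
        for _ in range(25):
            img = np.zeros((64, 64), dtype=np.uint8)
            for _ in range(int(rng.integers(0, 6))):
                w, h = rng.integers(3, 15, size=2)
                x = int(rng.integers(0, 64 - w))
                y = int(rng.integers(0, 64 - h))
                img[y : y + h, x : x + w] = 255
            groups = find_contour_rects(img)
            got = sorted((g.bounding.x, g.bounding.y, g.bounding.w, g.bounding.h) for g in groups)
            assert got == _bfs_components(img == 255)

    def test_non_binary_input_is_rejected(self):
        with pytest.raises(InvalidImage):
            find_contour_rects(np.full((5, 5), 7, dtype=np.uint8))


class TestLocateDisplay:
    def test_display_found_among_distractors(self):
        spec = DisplaySpec(
            lines=("FENTANYL 25 ML/HR",),
            rotation_degrees=3.0,
            background_clutter=2,
            seed=4,
        )
        frame, gt = render_frame(spec)
        rect, crop = locate_display(frame)
        assert rect.iou(gt.display_rect) >= 0.9
        assert crop.shape == (rect.h, rect.w)

    def test_strictly_larger_area_wins(self):
        img = np.zeros((300, 400), dtype=np.uint8)
        img[30:80, 20:120] = 220  # 100x50
        img[120:220, 150:350] = 220  # 200x100 -> winner
        rect, _ = locate_display(img, min_area_fraction=0.01)
        # the traced edge ring sits within a pixel or two of the true bounds
        assert abs(rect.w - 200) <= 3 and abs(rect.h - 100) <= 3
        assert abs(rect.x - 150) <= 2 and abs(rect.y - 120) <= 2

    def test_equal_area_tie_breaks_topmost_then_leftmost(self):
        img = np.zeros((300, 400), dtype=np.uint8)
        img[150:210, 200:300] = 220
        img[40:100, 50:150] = 220  # same 100x60 area, higher up
        rect, _ = locate_display(img, min_area_fraction=0.01)
        assert abs(rect.x - 50) <= 2 and abs(rect.y - 40) <= 2

    def test_uniform_frame_has_no_display(self):
        with pytest.raises(DisplayNotFound):
            locate_display(np.full((100, 100), 128, dtype=np.uint8))

    def test_small_specks_are_not_the_display(self):
        img = np.zeros((400, 400), dtype=np.uint8)
        img[10:20, 10:20] = 255  # far below the 5% area floor
        with pytest.raises(DisplayNotFound):
            locate_display(img)

    def test_located_rect_is_deterministic_and_inside_frame(self):
        frame, _ = render_frame(DisplaySpec(lines=("SALINE 5 ML",), seed=8))
        r1, _ = locate_display(frame)
        r2, _ = locate_display(frame)
        assert r1 == r2
        assert PixelRect(0, 0, frame.shape[1], frame.shape[0]).contains_rect(r1)


def test_localization_rate_on_randomized_renders():
    """Rendered display is recovered with IoU >= 0.9 in >= 95% of seeded frames."""
    frames = render_suite(20, seed=31, difficulty="clean")
    hits = sum(locate_display(f)[0].iou(gt.display_rect) >= 0.9 for f, gt in frames)
    assert hits >= 19
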