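"""Enhancement and deskew: enlarge, binarize, find the key line, rotate, crop.

The display crop is enlarged so small glyph edges survive thresholding,
binarized against the local mean intensity, and deskewed using the key
horizontal line: the widest, thinnest dark shape on the screen (a rule
line).  The least-squares line through that shape's outline gives the
rotation angle; after rotation the image is cropped horizontally to the
key line's extent and vertically to the 5%-90% band of the image height.

Binarized images use the convention text = black (0), field = white (255)
regardless of the display's own polarity.
"""

from __future__ import annotations

import math

import numpy as np
from PIL import Image
from skimage import transform

from .config import DeskewParams
from .core import LineFit, PixelRect, as_gray, require_binary
from .errors import DegenerateCrop, InvalidParameter, KeyLineNotFound
from .localization import find_contour_rects

__all__ = ["enlarge", "adaptive_mean_binarize", "find_key_line", "rotate_and_crop"]


def enlarge(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale an image by ``factor`` (>= 1) with bilinear interpolation.

    Output dimensions are ``round(factor * dim)``; factor 1 returns the
    input byte-identically.
    """
    gray = as_gray(img)
    if factor < 1:
        raise InvalidParameter(f"enlarge factor must be >= 1, got {factor}")
    if factor == 1:
        return gray.copy()
    h, w = gray.shape
    new_w = int(round(w * factor))
    new_h = int(round(h * factor))
    out = Image.fromarray(gray).resize((new_w, new_h), Image.BILINEAR)
    return np.asarray(out, dtype=np.uint8)


def adaptive_mean_binarize(gray: np.ndarray, p: DeskewParams) -> np.ndarray:
    """Binarize against the local block mean (adaptive mean threshold).

    Each pixel is compared with the mean intensity of its
    ``block_size x block_size`` neighbourhood (edge-replicated) minus
    ``offset_c``.  For dark-on-light polarity a pixel strictly below
    ``mean - offset_c`` becomes text (black, 0); for light-on-dark,
    strictly above ``mean + offset_c``.  Equality classifies as background,
    so a constant image is uniformly white.  Block sums are computed
    exactly in integer arithmetic, so the decision per pixel is exact.
    """
    img = as_gray(gray)
    if p.block_size % 2 == 0 or p.block_size < 3:
        raise InvalidParameter("block_size must be odd and >= 3")
    r = p.block_size // 2
    padded = np.pad(img.astype(np.int64), r, mode="edge")
    # exact block sums via a 2-D summed-area table
    sat = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.int64)
    sat[1:, 1:] = padded.cumsum(0).cumsum(1)
    k = p.block_size
    h, w = img.shape
    sums = sat[k : k + h, k : k + w] - sat[:h, k : k + w] - sat[k : k + h, :w] + sat[:h, :w]
    n = k * k
    # pixel < mean - C  <=>  n*(pixel + C) < sum   (exact when C*n is exact)
    if p.polarity == "dark-on-light":
        is_text = n * (img.astype(np.float64) + p.offset_c) < sums
    else:
        is_text = n * (img.astype(np.float64) - p.offset_c) > sums
    return np.where(is_text, 0, 255).astype(np.uint8)


def find_key_line(binary: np.ndarray, p: DeskewParams) -> LineFit:
    """Find the key horizontal line and fit its angle.

    Candidates are connected black shapes whose bounding rectangle is wider
    than ``min_width_fraction`` of the image width; among them the one with
    the smallest bounding height wins (ties: topmost-then-leftmost).  The
    angle is the slope of the least-squares regression line through the
    shape's outline points, positive counterclockwise as displayed.
    """
    img = require_binary(binary)
    h, w = img.shape
    groups = find_contour_rects(img, foreground="black")
    candidates = [g for g in groups if g.bounding.w > p.min_width_fraction * w]
    if not candidates:
        raise KeyLineNotFound(
            f"no shape wider than {p.min_width_fraction:.0%} of {w} px"
        )
    best = min(candidates, key=lambda g: (g.bounding.h, g.bounding.y, g.bounding.x))
    xs = best.points[:, 0]
    ys = best.points[:, 1]
    slope = np.polyfit(xs, ys, 1)[0]
    # y grows downward, so a visually counterclockwise line has dy/dx < 0
    angle = -math.degrees(math.atan(slope))
    return LineFit(
        angle_degrees=angle,
        point=(float(xs.mean()), float(ys.mean())),
        source_rect=best.bounding,
    )


def rotate_and_crop(binary: np.ndarray, line: LineFit, p: DeskewParams) -> np.ndarray:
    """Rotate so the key line is horizontal, then crop to the text region.

    The image rotates by ``-angle`` about its centre (bilinear, border
    filled white = background).  Columns are cropped to the key line's
    bounding-rectangle x-range; rows to
    ``[floor(crop_top_fraction*H), floor(crop_bottom_fraction*H))`` of the
    image height at the moment of cropping.
    """
    img = require_binary(binary)
    h, w = img.shape
    rotated = transform.rotate(
        img.astype(np.float64),
        -line.angle_degrees,
        resize=False,
        order=1,
        mode="constant",
        cval=255.0,
        preserve_range=True,
    )
    rotated = np.where(rotated < 128, 0, 255).astype(np.uint8)
    pad = round(p.crop_x_pad_fraction * w)
    x0 = max(0, line.source_rect.x - pad)
    x1 = min(w, line.source_rect.x2 + pad)
    y0 = math.floor(p.crop_top_fraction * h)
    y1 = math.floor(p.crop_bottom_fraction * h)
    if x1 <= x0 or y1 <= y0:
        raise DegenerateCrop(f"empty crop: x [{x0}, {x1}), y [{y0}, {y1})")
    out = rotated[y0:y1, x0:x1]
    assert out.shape == (y1 - y0, x1 - x0)
    return out
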