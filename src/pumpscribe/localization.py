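"""Display localization: find the pump screen inside a raw camera frame.

The display is assumed to be the largest edge-bounded shape in the frame.
The frame is converted to grayscale, edges are traced with a Canny
detector, each connected edge shape is bounded by its smallest enclosing
axis-aligned rectangle, and the largest-area rectangle wins; the grayscale
frame cropped to it is handed to the enhancement stage.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, measure

from .config import LocalizationParams
from .core import ContourGroup, PixelRect, as_gray, as_image, require_binary
from .errors import DisplayNotFound, InvalidImage, InvalidParameter

__all__ = ["to_grayscale", "trace_edges", "find_contour_rects", "locate_display"]

# Peak gradient magnitude produced by the sigma=1 Gaussian + Sobel chain
# for an ideal unit-contrast step edge.  Dividing by it lets hysteresis
# thresholds be stated in intensity units of step contrast (0-255).
_STEP_GAIN = 2.5644

_CANNY_SIGMA = 1.0


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to single-channel grayscale.

    Colour input is combined with the standard ITU-R BT.601 luminance
    weights (0.299 R + 0.587 G + 0.114 B); grayscale input is returned
    byte-identical.
    """
    img = as_image(frame)
    if img.ndim == 2:
        return img
    weights = np.array([0.299, 0.587, 0.114])
    gray = img.astype(np.float64) @ weights
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def trace_edges(gray: np.ndarray, low_threshold: float, high_threshold: float) -> np.ndarray:
    """Binary Canny edge map of a grayscale image.

    Hysteresis thresholds are in intensity units of local step contrast: an
    isolated edge of contrast below ``low_threshold`` yields no edge
    pixels.  Output is uint8 with edge pixels at 255.
    """
    img = as_gray(gray)
    if not (0 <= low_threshold <= 255 and 0 <= high_threshold <= 255):
        raise InvalidParameter("Canny thresholds must lie in [0, 255]")
    if low_threshold > high_threshold:
        raise InvalidParameter("low_threshold must not exceed high_threshold")
    edges = feature.canny(
        img.astype(np.float64),
        sigma=_CANNY_SIGMA,
        low_threshold=low_threshold * _STEP_GAIN,
        high_threshold=high_threshold * _STEP_GAIN,
    )
    return np.where(edges, 255, 0).astype(np.uint8)


def find_contour_rects(edges: np.ndarray, foreground: str = "white") -> list[ContourGroup]:
    """One :class:`ContourGroup` per connected foreground shape of a binary image.

    ``foreground`` selects the polarity: ``"white"`` groups 255-valued
    pixels, ``"black"`` groups 0-valued pixels.  Shapes are connected under
    8-connectivity; only the outermost outline of each shape is traced
    (holes are ignored).  The bounding rectangle is the smallest
    axis-aligned rectangle containing the shape's pixels.
    """
    img = require_binary(edges)
    if foreground not in ("white", "black"):
        raise InvalidParameter(f"foreground must be 'white' or 'black', got {foreground!r}")
    mask = img == (255 if foreground == "white" else 0)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    groups: list[ContourGroup] = []
    slices = ndi.find_objects(labels)
    for idx, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        ys, xs = slc
        rect = PixelRect(x=xs.start, y=ys.start, w=xs.stop - xs.start, h=ys.stop - ys.start)
        sub = labels[slc] == idx
        pts = _outline_points(sub, x0=xs.start, y0=ys.start)
        groups.append(ContourGroup(points=pts, bounding=rect))
    # deterministic order: topmost, then leftmost
    groups.sort(key=lambda g: (g.bounding.y, g.bounding.x))
    return groups


def _outline_points(mask: np.ndarray, x0: int, y0: int) -> np.ndarray:
    """Outer boundary points of a component mask, as (x, y) pixel coordinates."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if contours:
        # keep the longest outline: the outermost boundary; subtract the pad
        outline = max(contours, key=len)
        ys = outline[:, 0] - 1 + y0
        xs = outline[:, 1] - 1 + x0
        return np.column_stack([xs, ys])
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs + x0, ys + y0]).astype(float)


def locate_display(
    frame: np.ndarray,
    canny_low: float = LocalizationParams.canny_low,
    canny_high: float = LocalizationParams.canny_high,
    min_area_fraction: float = LocalizationParams.min_area_fraction,
) -> tuple[PixelRect, np.ndarray]:
    """Locate the display screen in a frame and crop the grayscale image to it.

    Returns ``(rect, crop)`` where ``rect`` is the largest-area contour
    bounding rectangle.  Ties on area break topmost-then-leftmost.  Raises
    :class:`DisplayNotFound` when no contours exist or the winner covers
    less than ``min_area_fraction`` of the frame.
    """
    gray = to_grayscale(frame)
    edges = trace_edges(gray, canny_low, canny_high)
    groups = find_contour_rects(edges, foreground="white")
    if not groups:
        raise DisplayNotFound("no edge contours in frame")
    best = max(groups, key=lambda g: (g.bounding.area, -g.bounding.y, -g.bounding.x))
    rect = best.bounding
    if rect.area < min_area_fraction * gray.shape[0] * gray.shape[1]:
        raise DisplayNotFound(
            f"largest rectangle covers {rect.area} px, below "
            f"{min_area_fraction:.0%} of the frame"
        )
    frame_rect = PixelRect(0, 0, gray.shape[1], gray.shape[0])
    assert frame_rect.contains_rect(rect), "located rect must lie inside the frame"
    return rect, rect.crop(gray)
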