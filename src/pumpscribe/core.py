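"""Shared domain types and image conventions.

Images are ``numpy`` ``uint8`` arrays: shape ``(H, W)`` for grayscale or
``(H, W, 3)`` for RGB.  The coordinate convention is fixed throughout the
package: origin at the top-left pixel, ``x`` rightward, ``y`` downward,
0-based indices, and every rectangle is half-open ``[x, x+w) x [y, y+h)``.

Rotation angles are in degrees, positive counterclockwise *as displayed*
(y pointing down), matching ``PIL.Image.rotate`` and
``skimage.transform.rotate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidImage

__all__ = [
    "PixelRect",
    "ContourGroup",
    "LineFit",
    "OcrToken",
    "PumpRecord",
    "as_image",
    "as_gray",
    "require_binary",
]


@dataclass(frozen=True)
class PixelRect:
    """Axis-aligned half-open pixel rectangle ``[x, x+w) x [y, y+h)``."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"rectangle extent must be >= 1, got {self.w}x{self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        return self.x <= x < self.x2 and self.y <= y < self.y2

    def contains_rect(self, other: "PixelRect") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.x2 <= self.x2
            and other.y2 <= self.y2
        )

    def iou(self, other: "PixelRect") -> float:
        """Intersection-over-union of two rectangles (0 when disjoint)."""
        ix = max(self.x, other.x)
        iy = max(self.y, other.y)
        ix2 = min(self.x2, other.x2)
        iy2 = min(self.y2, other.y2)
        if ix >= ix2 or iy >= iy2:
            return 0.0
        inter = (ix2 - ix) * (iy2 - iy)
        return inter / float(self.area + other.area - inter)

    def crop(self, img: np.ndarray) -> np.ndarray:
        return img[self.y : self.y2, self.x : self.x2]


@dataclass(frozen=True)
class ContourGroup:
    """Boundary points of one connected foreground shape plus its bounding rect.

    ``points`` is an ``(N, 2)`` float array of (x, y) pixel coordinates
    tracing the shape outline; only outermost contours are kept (holes
    inside a shape are ignored).
    """

    points: np.ndarray
    bounding: PixelRect

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("points must be a non-empty (N, 2) array")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class LineFit:
    """Least-squares fit of the key horizontal line.

    ``angle_degrees`` is the in-plane rotation of the line, positive
    counterclockwise as displayed, in (-90, 90].  ``point`` is a point on
    the fitted line (the centroid of the contour points) and
    ``source_rect`` the bounding rectangle of the chosen shape.
    """

    angle_degrees: float
    point: tuple[float, float]
    source_rect: PixelRect

    def __post_init__(self) -> None:
        if not (-90.0 < self.angle_degrees <= 90.0):
            raise ValueError(f"angle out of range: {self.angle_degrees}")


@dataclass(frozen=True)
class OcrToken:
    """One recognized text span with its position in processed-image coordinates."""

    text: str
    bbox: PixelRect
    line_index: int
    confidence: Optional[float] = None
    unmatched: bool = False
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("token text must be non-empty")

    def with_text(self, text: str, **kw) -> "OcrToken":
        return OcrToken(
            text=text,
            bbox=self.bbox,
            line_index=self.line_index,
            confidence=self.confidence,
            unmatched=kw.get("unmatched", self.unmatched),
            low_confidence=kw.get("low_confidence", self.low_confidence),
        )


@dataclass(frozen=True)
class PumpRecord:
    """Structured medication record extracted from one display frame.

    ``remaining`` keeps the raw display token; the display does not always
    distinguish volume-left from time-left, so ``remaining_kind`` tags it as
    ``"time"`` (hh:mm pattern) or ``"volume"`` (bare number) without
    interpreting it further.
    """

    medication: str
    dose_value: float
    dose_units: Optional[str] = None
    remaining: Optional[str] = None
    remaining_kind: Optional[str] = None
    timestamp: Optional[str] = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.dose_value < 0:
            raise ValueError("dose_value must be >= 0")
        if self.remaining_kind not in (None, "time", "volume"):
            raise ValueError(f"bad remaining_kind: {self.remaining_kind}")


def as_image(arr: np.ndarray) -> np.ndarray:
    """Validate a 1- or 3-channel uint8 image and return it as uint8."""
    a = np.asarray(arr)
    if a.ndim == 3 and a.shape[2] == 3:
        pass
    elif a.ndim == 2:
        pass
    else:
        raise InvalidImage(f"expected (H, W) or (H, W, 3), got shape {a.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise InvalidImage("image must be at least 1x1")
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.integer) and a.min() >= 0 and a.max() <= 255:
            a = a.astype(np.uint8)
        else:
            raise InvalidImage(f"expected 8-bit intensities, got dtype {a.dtype}")
    return a


def as_gray(arr: np.ndarray) -> np.ndarray:
    """Validate a single-channel uint8 image."""
    a = as_image(arr)
    if a.ndim != 2:
        raise InvalidImage("expected a single-channel image")
    return a


def require_binary(arr: np.ndarray) -> np.ndarray:
    """Validate a binary image (values drawn from {0, 255})."""
    a = as_gray(arr)
    vals = np.unique(a)
    if not np.isin(vals, (0, 255)).all():
        raise InvalidImage("expected a binary image with values in {0, 255}")
    return a
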