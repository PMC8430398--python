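"""Character recognition and OCR post-correction.

OCR is consumed through a pluggable engine interface: an engine takes a
processed image and returns positioned tokens.  Two engines ship with the
package:

* :class:`TemplateOcrEngine` — a deterministic shape-library matcher for
  the bundled 5x7 dot-matrix display font.  It segments the binarized crop
  into line bands and glyph cells by ink projection and classifies each
  cell by nearest bitmap template (Hamming distance on a normalized grid),
  which is exactly the "compare a library of shapes, assume the best
  matched letter" model of OCR, specialised to the display font.
* :class:`TesseractEngine` — a thin adapter over ``pytesseract`` for
  deployments with Google Tesseract installed.

Raw OCR output then passes through lexicon correction (nearest dictionary
word under a weighted edit-distance bound, with known letter confusions
such as f<->t discounted) and numeric repair (fixed letter-to-digit
substitution table).  Digits from the confusable set {5, 6, 8, 9} are
never silently rewritten; low engine confidence only flags the token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import segmentation, transform

from . import font
from .config import CorrectionParams
from .core import OcrToken, PixelRect, as_gray
from .errors import EngineUnavailable, NotANumber, OcrFailed

__all__ = [
    "OcrEngine",
    "TemplateOcrEngine",
    "TesseractEngine",
    "make_engine",
    "run_ocr",
    "correct_word",
    "correct_number",
    "weighted_edit_distance",
    "DIGIT_REPAIRS",
]

_NUMERIC_RE = re.compile(r"^\d+(\.\d+)?$")

# Letter-to-digit repairs for mixed alphanumeric artifacts in numeric fields.
DIGIT_REPAIRS = {
    "O": "0", "o": "0", "D": "0", "Q": "0",
    "I": "1", "l": "1", "i": "1", "|": "1",
    "Z": "2", "z": "2",
    "A": "4",
    "S": "5", "s": "5",
    "G": "6", "b": "6",
    "T": "7",
    "B": "8",
    "g": "9", "q": "9",
}


class OcrEngine(Protocol):
    """Image in, positioned word tokens out."""

    def recognize(self, img: np.ndarray) -> list[OcrToken]:  # pragma: no cover - protocol
        ...


# ---------------------------------------------------------------------------
# Template (shape-library) engine
# ---------------------------------------------------------------------------

_GRID = (21, 15)  # rows, cols of the normalized comparison grid


def _tight_cols(bitmap: np.ndarray) -> np.ndarray:
    cols = np.nonzero(bitmap.any(axis=0))[0]
    return bitmap[:, cols[0] : cols[-1] + 1]


def _tight(bitmap: np.ndarray) -> np.ndarray:
    rows = np.nonzero(bitmap.any(axis=1))[0]
    return _tight_cols(bitmap[rows[0] : rows[-1] + 1])


def _to_grid(mask: np.ndarray) -> np.ndarray:
    g = transform.resize(mask.astype(float), _GRID, order=1, anti_aliasing=False)
    return g > 0.5


# a glyph whose ink spans at least this fraction of the line band is
# matched on its tight bounding box (registration-free); shorter marks
# ('.', '-') are identified by their placement within the band instead
_TALL_FRACTION = 0.55


class TemplateOcrEngine:
    """Deterministic shape-library OCR for the bundled display font.

    ``max_mismatch`` is the largest tolerated fraction of mismatching grid
    pixels; a worse best-match classifies the cell as ``?``.
    ``min_component_area`` despeckles: ink components smaller than this are
    noise, far below the smallest glyph feature at supported glyph sizes.
    """

    def __init__(self, max_mismatch: float = 0.40, min_component_area: int = 25):
        self.max_mismatch = max_mismatch
        self.min_component_area = min_component_area
        self._tall = {}
        self._short = {}
        for ch, bm in font.GLYPHS.items():
            rows = np.nonzero(bm.any(axis=1))[0]
            height = rows[-1] - rows[0] + 1
            if height >= _TALL_FRACTION * font.CELL_H:
                self._tall[ch] = _to_grid(_tight(bm))
            else:
                self._short[ch] = _to_grid(_tight_cols(bm))

    @staticmethod
    def _best(g: np.ndarray, templates: dict[str, np.ndarray]) -> tuple[str, float]:
        best_ch, best_d = "?", 1.0
        for ch, tpl in templates.items():
            d = np.count_nonzero(g ^ tpl) / g.size
            if d < best_d:
                best_ch, best_d = ch, d
        return best_ch, best_d

    def _classify(self, cell: np.ndarray) -> tuple[str, float]:
        rows = np.nonzero(cell.any(axis=1))[0]
        height = rows[-1] - rows[0] + 1
        if height >= _TALL_FRACTION * cell.shape[0]:
            ch, d = self._best(_to_grid(_tight(cell)), self._tall)
        else:
            ch, d = self._best(_to_grid(cell), self._short)
        conf = 100.0 * (1.0 - d)
        if d > self.max_mismatch:
            return "?", conf
        return ch, conf

    def recognize(self, img: np.ndarray) -> list[OcrToken]:
        gray = as_gray(img)
        ink = gray < 128
        # drop non-glyph structure before segmenting: display-boundary
        # stripes and clipped shapes touch the crop border, and rule lines /
        # border remnants span a large fraction of the crop; glyphs do neither
        labels, n = ndi.label(ink, structure=np.ones((3, 3), dtype=int))
        cleared = segmentation.clear_border(labels)
        h, w = ink.shape
        areas = np.bincount(cleared.ravel(), minlength=n + 1)
        keep = np.zeros(n + 1, dtype=bool)
        for idx, slc in enumerate(ndi.find_objects(cleared), start=1):
            if slc is None:
                continue
            ch = slc[0].stop - slc[0].start
            cw = slc[1].stop - slc[1].start
            keep[idx] = (
                ch <= 0.5 * h
                and cw <= 0.5 * w
                and areas[idx] >= self.min_component_area
            )
        ink = keep[cleared]
        tokens: list[OcrToken] = []
        bands = self._line_bands(ink)
        for line_index, (y0, y1) in enumerate(bands):
            tokens.extend(self._read_band(ink, y0, y1, line_index))
        return tokens

    @staticmethod
    def _line_bands(ink: np.ndarray) -> list[tuple[int, int]]:
        rows = np.nonzero(ink.any(axis=1))[0]
        if rows.size == 0:
            return []
        # split where more than 2 consecutive blank rows separate ink
        breaks = np.nonzero(np.diff(rows) > 3)[0]
        starts = np.concatenate([[rows[0]], rows[breaks + 1]])
        ends = np.concatenate([rows[breaks] + 1, [rows[-1] + 1]])
        bands = list(zip(starts.tolist(), ends.tolist()))
        # drop bands much shorter than the tallest (noise specks, rule-line slivers)
        tallest = max(y1 - y0 for y0, y1 in bands)
        return [(y0, y1) for y0, y1 in bands if (y1 - y0) >= max(4, 0.4 * tallest)]

    def _read_band(
        self, ink: np.ndarray, y0: int, y1: int, line_index: int
    ) -> list[OcrToken]:
        band = ink[y0:y1]
        band_h = y1 - y0
        cols = np.nonzero(band.any(axis=0))[0]
        if cols.size == 0:
            return []
        breaks = np.nonzero(np.diff(cols) > 1)[0]
        starts = np.concatenate([[cols[0]], cols[breaks + 1]])
        ends = np.concatenate([cols[breaks] + 1, [cols[-1] + 1]])
        cells = list(zip(starts.tolist(), ends.tolist()))
        # group glyph cells into tokens: a gap wider than ~4.5 font columns
        # (of the 7-row cell height) separates tokens
        gap_limit = 4.5 / 7.0 * band_h
        tokens: list[OcrToken] = []
        current: list[tuple[int, int, str, float]] = []

        def flush() -> None:
            if not current:
                return
            text = "".join(c[2] for c in current)
            x0 = current[0][0]
            x1 = current[-1][1]
            confs = [c[3] for c in current]
            tokens.append(
                OcrToken(
                    text=text,
                    bbox=PixelRect(x=x0, y=y0, w=x1 - x0, h=band_h),
                    line_index=line_index,
                    confidence=float(np.mean(confs)),
                )
            )
            current.clear()

        prev_end: Optional[int] = None
        for c0, c1 in cells:
            if prev_end is not None and c0 - prev_end > gap_limit:
                flush()
            ch, conf = self._classify(band[:, c0:c1])
            current.append((c0, c1, ch, conf))
            prev_end = c1
        flush()
        return tokens


# ---------------------------------------------------------------------------
# Tesseract adapter
# ---------------------------------------------------------------------------


class TesseractEngine:
    """Adapter over ``pytesseract`` word/box output (requires Google Tesseract)."""

    def __init__(self, lang: str = "eng", psm: int = 6):
        try:
            import pytesseract  # noqa: F401
        except ImportError as exc:  # pragma: no cover - depends on host install
            raise EngineUnavailable("pytesseract is not installed") from exc
        self._pt = pytesseract
        self.lang = lang
        self.psm = psm

    def recognize(self, img: np.ndarray) -> list[OcrToken]:  # pragma: no cover
        gray = as_gray(img)
        data = self._pt.image_to_data(
            gray,
            lang=self.lang,
            config=f"--psm {self.psm}",
            output_type=self._pt.Output.DICT,
        )
        tokens: list[OcrToken] = []
        line_keys: dict[tuple, int] = {}
        for i, text in enumerate(data["text"]):
            text = text.strip()
            if not text:
                continue
            key = (data["block_num"][i], data["par_num"][i], data["line_num"][i])
            line_index = line_keys.setdefault(key, len(line_keys))
            conf = float(data["conf"][i])
            tokens.append(
                OcrToken(
                    text=text,
                    bbox=PixelRect(
                        x=int(data["left"][i]),
                        y=int(data["top"][i]),
                        w=max(1, int(data["width"][i])),
                        h=max(1, int(data["height"][i])),
                    ),
                    line_index=line_index,
                    confidence=conf if conf >= 0 else None,
                )
            )
        return tokens


def make_engine(name: str) -> OcrEngine:
    """Construct an engine by config name (``template`` or ``tesseract``)."""
    if name == "template":
        return TemplateOcrEngine()
    if name == "tesseract":
        return TesseractEngine()
    raise EngineUnavailable(f"unknown OCR engine {name!r}")


def run_ocr(img: np.ndarray, engine: OcrEngine) -> list[OcrToken]:
    """Run an engine on a processed crop and return tokens in reading order.

    Engine exceptions surface as :class:`OcrFailed`, which the capture loop
    treats as a skipped frame, never a fatal error.
    """
    gray = as_gray(img)
    try:
        tokens = engine.recognize(gray)
    except Exception as exc:
        raise OcrFailed(f"OCR engine failed: {exc}") from exc
    tokens = sorted(tokens, key=lambda t: (t.line_index, t.bbox.x))
    img_rect = PixelRect(0, 0, gray.shape[1], gray.shape[0])
    for t in tokens:
        if not img_rect.contains_rect(t.bbox):
            raise OcrFailed(f"engine returned out-of-image bbox {t.bbox}")
    return tokens


# ---------------------------------------------------------------------------
# Post-correction
# ---------------------------------------------------------------------------


def weighted_edit_distance(
    a: str,
    b: str,
    confusable_letters: frozenset[frozenset[str]] = frozenset(),
    confusable_cost: float = 0.5,
) -> float:
    """Levenshtein distance with discounted substitutions for confusable pairs.

    Insertions and deletions cost 1; a substitution costs
    ``confusable_cost`` when {a, b} is a configured confusable pair and 1
    otherwise.  Case-insensitive.
    """
    a = a.lower()
    b = b.lower()
    la, lb = len(a), len(b)
    prev = [float(j) for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [float(i)] + [0.0] * lb
        for j in range(1, lb + 1):
            if a[i - 1] == b[j - 1]:
                sub = prev[j - 1]
            else:
                cost = (
                    confusable_cost
                    if frozenset((a[i - 1], b[j - 1])) in confusable_letters
                    else 1.0
                )
                sub = prev[j - 1] + cost
            cur[j] = min(prev[j] + 1.0, cur[j - 1] + 1.0, sub)
        prev = cur
    return prev[lb]


def correct_word(token: OcrToken, p: CorrectionParams) -> OcrToken:
    """Snap a word token to the nearest lexicon entry within the edit bound.

    Uses the weighted distance above so documented engine confusions (for
    example ``tentanyl`` for ``fentanyl``) are cheap to undo.  A token with
    no lexicon entry within the bound is returned unchanged but flagged
    ``unmatched``.  Correction is idempotent: an exact lexicon match is
    distance 0.
    """
    word = token.text.lower()
    if word in p.lexicon:
        return token.with_text(word, unmatched=False)
    best_entry: Optional[str] = None
    best_d = float("inf")
    for entry in sorted(p.lexicon):
        d = weighted_edit_distance(word, entry, p.confusable_letters)
        if d < best_d:
            best_entry, best_d = entry, d
    if best_entry is not None and best_d <= p.edit_bound(word):
        return token.with_text(best_entry, unmatched=False)
    return token.with_text(token.text, unmatched=True)


def correct_number(
    token: OcrToken,
    context: Sequence[OcrToken] = (),
    p: Optional[CorrectionParams] = None,
) -> OcrToken:
    """Repair a numeric token with the fixed letter-to-digit table.

    Mixed letter-digit artifacts ('O' for '0', 'S' for '5', ...) are
    substituted; a string that still fails to parse as a decimal number
    raises :class:`NotANumber`.  Digits from the confusable set are kept
    as recognized — when the engine's confidence falls below the threshold
    the token is only flagged low-confidence, never rewritten.  ``context``
    (other tokens on the frame) is accepted for future contextual checks
    and is currently unused.
    """
    p = p or CorrectionParams()
    text = token.text
    if not _NUMERIC_RE.match(text):
        repaired = "".join(DIGIT_REPAIRS.get(c, c) for c in text)
        if not _NUMERIC_RE.match(repaired):
            raise NotANumber(f"cannot repair {token.text!r} into a number")
        text = repaired
    low = token.low_confidence
    if (
        any(d in p.confusable_digits for d in text)
        and token.confidence is not None
        and token.confidence < p.confidence_threshold
    ):
        low = True
    return token.with_text(text, low_confidence=low)
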