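"""Synthetic pump-display renderer with machine-readable ground truth.

Renders parameterized camera-style frames of a text display — a bright
(or dark) rectangular screen on a cluttered background, a wide thin rule
line (the key horizontal line used for deskew), one or more medication
text lines in the bundled 5x7 dot-matrix font, small in-plane rotation,
Gaussian noise, and optional glare — so that every pipeline stage, and
the pipeline end to end, is testable without camera hardware.  Each frame
is paired with ground truth derived from the same render parameters.

Display text follows the grammar ``<medication> <dose> <units>
<remaining>`` per line; ground-truth records are derived from the lines
by that grammar, which makes the render -> extract -> parse round trip a
checkable identity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from . import font
from .config import default_lexicon, default_units
from .core import PixelRect, PumpRecord
from .errors import InvalidParameter, SpecOverflow
from .parser import TIME_RE

__all__ = [
    "DisplaySpec",
    "GroundTruth",
    "render_frame",
    "render_suite",
    "records_from_lines",
    "format_line",
    "save_suite",
    "DIFFICULTY_TIERS",
]

# frame and display geometry defaults (pixels)
FRAME_W = 960
FRAME_H = 720
BACKGROUND_GRAY = 48

# intensity levels: display field / text ink per polarity
_LEVELS = {"dark-on-light": (230, 20), "light-on-dark": (25, 230)}

# parameter distributions per difficulty tier
DIFFICULTY_TIERS = {
    "clean": {"noise_sigma": (0.0, 0.0), "glare": False, "clutter": (0, 3)},
    "noisy": {"noise_sigma": (3.0, 8.0), "glare": False, "clutter": (0, 3)},
    "glare": {"noise_sigma": (0.0, 5.0), "glare": True, "clutter": (0, 3)},
}


@dataclass(frozen=True)
class DisplaySpec:
    """Parameters of one rendered frame.

    ``display_rect`` is the unrotated screen rectangle; after rotation the
    screen is pasted with the same centre, and the ground truth records
    the axis-aligned bounding box of the rotated screen.  ``glare`` is
    ``(cx, cy, ax, ay, peak)`` in frame coordinates.
    """

    lines: tuple[str, ...]
    glyph_height: int = 21
    display_rect: PixelRect = PixelRect(240, 200, 480, 320)
    rotation_degrees: float = 0.0
    background_clutter: int = 0
    noise_sigma: float = 0.0
    glare: Optional[tuple[float, float, float, float, float]] = None
    polarity: str = "dark-on-light"
    seed: int = 0
    frame_w: int = FRAME_W
    frame_h: int = FRAME_H

    def __post_init__(self) -> None:
        if not self.lines:
            raise InvalidParameter("at least one text line is required")
        if self.glyph_height < 8:
            raise InvalidParameter("glyph_height must be >= 8")
        if not (-15 <= self.rotation_degrees <= 15):
            raise InvalidParameter("rotation must lie in [-15, 15] degrees")
        if self.polarity not in _LEVELS:
            raise InvalidParameter(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Exact render-parameter ground truth for one frame."""

    display_rect: PixelRect
    rotation_degrees: float
    tokens: tuple[tuple[str, PixelRect, int], ...]
    records: tuple[PumpRecord, ...]


def records_from_lines(
    lines,
    lexicon: Optional[frozenset[str]] = None,
    units: Optional[frozenset[str]] = None,
) -> tuple[PumpRecord, ...]:
    """Derive ground-truth records from display lines by the line grammar."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    units = units if units is not None else default_units()
    records = []
    for line in lines:
        words = line.lower().split()
        med_words = []
        rest = []
        for i, w in enumerate(words):
            if w in lexicon:
                med_words.append(w)
            else:
                rest = words[i:]
                break
        else:
            rest = []
        if not med_words or not rest:
            continue
        dose = rest[0]
        try:
            dose_value = float(dose)
        except ValueError:
            continue
        dose_units = None
        remaining = None
        kind = None
        for w in rest[1:]:
            if dose_units is None and w in units:
                dose_units = w
            elif remaining is None and TIME_RE.match(w):
                remaining, kind = w, "time"
            elif remaining is None and w.replace(".", "", 1).isdigit():
                remaining, kind = w, "volume"
        records.append(
            PumpRecord(
                medication=" ".join(med_words),
                dose_value=dose_value,
                dose_units=dose_units,
                remaining=remaining,
                remaining_kind=kind,
            )
        )
    return tuple(records)


def format_line(
    medication: str,
    dose_value: float,
    dose_units: Optional[str] = None,
    remaining: Optional[str] = None,
) -> str:
    """Compose a display line from record fields (rendered uppercase)."""
    dose = str(int(dose_value)) if dose_value == int(dose_value) else repr(dose_value)
    parts = [medication.upper(), dose]
    if dose_units:
        parts.append(dose_units.upper())
    if remaining:
        parts.append(remaining)
    return " ".join(parts)


def _rotate_points(pts: np.ndarray, theta_deg: float, center: tuple[float, float]) -> np.ndarray:
    """Rotate (x, y) points visually counterclockwise (y down) about a centre."""
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    p = pts - np.asarray(center)
    return np.column_stack([p[:, 0] * c + p[:, 1] * s, -p[:, 0] * s + p[:, 1] * c]) + np.asarray(
        center
    )


def _render_display(spec: DisplaySpec) -> tuple[np.ndarray, list[tuple[str, PixelRect, int]]]:
    """Draw the unrotated screen: field, rule line, text; return local token bboxes."""
    w, h = spec.display_rect.w, spec.display_rect.h
    fill, ink = _LEVELS[spec.polarity]
    disp = np.full((h, w), fill, dtype=np.uint8)

    scale = max(1, round(spec.glyph_height / font.CELL_H))
    gh = font.CELL_H * scale
    bar_x0 = round(0.03 * w)
    bar_x1 = w - bar_x0
    bar_y = round(0.09 * h)
    bar_t = max(2, scale)
    disp[bar_y : bar_y + bar_t, bar_x0:bar_x1] = ink

    text_x = round(0.06 * w)
    max_w = w - 2 * text_x
    y = bar_y + bar_t + round(0.6 * gh)
    pitch = gh + round(0.8 * gh)
    tokens: list[tuple[str, PixelRect, int]] = []
    for line_index, line in enumerate(spec.lines):
        width_px = font.text_width_cells(line) * scale
        if width_px > max_w:
            raise SpecOverflow(f"line {line_index} needs {width_px} px, display fits {max_w}")
        if y + gh > round(0.80 * h):
            raise SpecOverflow(f"line {line_index} falls below the readable display band")
        mask = font.render_text_mask(line, scale)
        disp[y : y + mask.shape[0], text_x : text_x + mask.shape[1]][mask] = ink
        # token bboxes: split on spaces, chars advance 6 cells each
        pos = 0
        for tok in line.split(" "):
            if tok:
                x0 = text_x + pos * font.ADVANCE * scale
                x1 = text_x + ((pos + len(tok) - 1) * font.ADVANCE + font.CELL_W) * scale
                tokens.append((tok, PixelRect(x0, y, x1 - x0, gh), line_index))
            pos += len(tok) + 1
        y += pitch
    return disp, tokens


def render_frame(spec: DisplaySpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame and its ground truth.

    Byte-reproducible for a fixed spec (all randomness flows from
    ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    frame = np.full((spec.frame_h, spec.frame_w), BACKGROUND_GRAY, dtype=np.float64)

    disp, local_tokens = _render_display(spec)
    h, w = disp.shape
    cx, cy = spec.display_rect.center

    rot = Image.fromarray(disp).rotate(
        spec.rotation_degrees,
        resample=Image.BILINEAR,
        expand=True,
        fillcolor=BACKGROUND_GRAY,
    )
    rw, rh = rot.size
    px = round(cx - rw / 2)
    py = round(cy - rh / 2)
    if px < 0 or py < 0 or px + rw > spec.frame_w or py + rh > spec.frame_h:
        raise InvalidParameter("rotated display does not fit inside the frame")
    display_rect = PixelRect(px, py, rw, rh)

    # background clutter: distractor shapes kept clear of the display
    keep_out = PixelRect(
        max(0, px - 10), max(0, py - 10),
        min(spec.frame_w, px + rw + 10) - max(0, px - 10),
        min(spec.frame_h, py + rh + 10) - max(0, py - 10),
    )
    for _ in range(spec.background_clutter):
        _draw_clutter(frame, rng, keep_out)

    frame[py : py + rh, px : px + rw] = np.asarray(rot, dtype=np.float64)

    # ground-truth token bboxes in frame coordinates
    tokens = []
    for text, rect, li in local_tokens:
        corners = np.array(
            [[rect.x, rect.y], [rect.x2, rect.y], [rect.x, rect.y2], [rect.x2, rect.y2]],
            dtype=float,
        )
        rc = _rotate_points(corners, spec.rotation_degrees, (w / 2, h / 2))
        rc += [px + (rw - w) / 2, py + (rh - h) / 2]
        x0, y0 = (int(v) for v in np.floor(rc.min(axis=0)))
        x1, y1 = (int(v) for v in np.ceil(rc.max(axis=0)))
        tokens.append((text, PixelRect(x0, y0, x1 - x0, y1 - y0), li))

    if spec.glare is not None:
        gx, gy, ax, ay, peak = spec.glare
        yy, xx = np.mgrid[0 : spec.frame_h, 0 : spec.frame_w]
        frame += peak * np.exp(-(((xx - gx) / ax) ** 2 + ((yy - gy) / ay) ** 2))

    if spec.noise_sigma > 0:
        frame += rng.normal(0.0, spec.noise_sigma, size=frame.shape)

    out = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    gt = GroundTruth(
        display_rect=display_rect,
        rotation_degrees=spec.rotation_degrees,
        tokens=tuple(tokens),
        records=records_from_lines(spec.lines),
    )
    return out, gt


def _draw_clutter(frame: np.ndarray, rng: np.random.Generator, keep_out: PixelRect) -> None:
    fh, fw = frame.shape
    for _ in range(40):
        cw = int(rng.integers(30, 120))
        ch = int(rng.integers(30, 120))
        x = int(rng.integers(0, max(1, fw - cw)))
        y = int(rng.integers(0, max(1, fh - ch)))
        cand = PixelRect(x, y, cw, ch)
        ix = max(cand.x, keep_out.x) < min(cand.x2, keep_out.x2)
        iy = max(cand.y, keep_out.y) < min(cand.y2, keep_out.y2)
        if ix and iy:
            continue
        val = float(rng.integers(210, 256))
        if rng.random() < 0.5:
            frame[y : y + ch, x : x + cw] = val
        else:
            yy, xx = np.mgrid[0:ch, 0:cw]
            ell = ((xx - cw / 2) / (cw / 2)) ** 2 + ((yy - ch / 2) / (ch / 2)) ** 2 <= 1
            frame[y : y + ch, x : x + cw][ell] = val
        return


_SUITE_MEDS = (
    "fentanyl",
    "propofol",
    "sodium chloride",
    "saline",
    "heparin",
    "insulin",
    "morphine",
    "midazolam",
    "ketamine",
    "dopamine",
    "dextrose",
    "furosemide",
)
_SUITE_DOSES = (0.5, 1, 2, 2.5, 5, 7.5, 10, 12.5, 20, 25, 40, 50, 75, 100, 125, 250)
_SUITE_UNITS = ("ml/hr", "mg/hr", "mcg/hr", "units/hr", "ml")


def _suite_line(rng: np.random.Generator, max_chars: int) -> str:
    med = _SUITE_MEDS[rng.integers(0, len(_SUITE_MEDS))]
    dose = _SUITE_DOSES[rng.integers(0, len(_SUITE_DOSES))]
    units = _SUITE_UNITS[rng.integers(0, len(_SUITE_UNITS))]
    if rng.random() < 0.5:
        remaining = f"{int(rng.integers(0, 24))}:{int(rng.integers(0, 60)):02d}"
    else:
        remaining = str(int(rng.integers(1, 1000)))
    for line in (
        format_line(med, dose, units, remaining),
        format_line(med, dose, units),
        format_line(med, dose),
    ):
        if len(line) <= max_chars:
            return line
    return format_line("saline", dose)


def render_suite(
    n: int, seed: int, difficulty: str = "clean"
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Render ``n`` frames drawn from the documented tier distributions.

    Tiers: ``clean`` (no noise or glare), ``noisy`` (Gaussian noise sigma
    3-8), ``glare`` (one bright ellipse overlapping part of the display).
    Rotations are uniform in +/-10 degrees; displays 480-620 px wide with
    up to 3 background distractors; glyph height 21 px.
    """
    if n < 1:
        raise InvalidParameter("n must be >= 1")
    if difficulty not in DIFFICULTY_TIERS:
        raise InvalidParameter(f"unknown difficulty {difficulty!r}")
    tier = DIFFICULTY_TIERS[difficulty]
    master = np.random.default_rng(seed)
    out = []
    for i in range(n):
        frame_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(frame_seed)
        dw = int(rng.integers(480, 620))
        dh = int(rng.integers(300, 380))
        rotation = float(rng.uniform(-10, 10))
        # keep the rotated bounding box inside the frame
        margin = 20
        rw = dw * math.cos(math.radians(abs(rotation))) + dh * math.sin(math.radians(abs(rotation)))
        rh = dw * math.sin(math.radians(abs(rotation))) + dh * math.cos(math.radians(abs(rotation)))
        cx = float(rng.uniform(rw / 2 + margin, FRAME_W - rw / 2 - margin))
        cy = float(rng.uniform(rh / 2 + margin, FRAME_H - rh / 2 - margin))
        rect = PixelRect(round(cx - dw / 2), round(cy - dh / 2), dw, dh)

        scale = 3
        max_chars = (dw - 2 * round(0.06 * dw)) // (font.ADVANCE * scale)
        n_lines = 1 + int(rng.random() < 0.5)
        lines = tuple(_suite_line(rng, max_chars) for _ in range(n_lines))

        sigma = float(rng.uniform(*tier["noise_sigma"]))
        clutter = int(rng.integers(tier["clutter"][0], tier["clutter"][1] + 1))
        glare = None
        if tier["glare"]:
            gx = float(rng.uniform(rect.x, rect.x2))
            gy = float(rng.uniform(rect.y, rect.y + 0.5 * dh))
            glare = (gx, gy, float(rng.uniform(60, 130)), float(rng.uniform(40, 90)),
                     float(rng.uniform(140, 230)))

        spec = DisplaySpec(
            lines=lines,
            glyph_height=21,
            display_rect=rect,
            rotation_degrees=rotation,
            background_clutter=clutter,
            noise_sigma=sigma,
            glare=glare,
            seed=frame_seed,
        )
        out.append(render_frame(spec))
    return out


def save_suite(frames, out_dir) -> Path:
    """Write PNG frames with JSON ground-truth sidecars plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (frame, gt) in enumerate(frames):
        stem = f"frame_{i:04d}"
        Image.fromarray(frame).save(out_dir / f"{stem}.png")
        sidecar = {
            "display_rect": [gt.display_rect.x, gt.display_rect.y, gt.display_rect.w, gt.display_rect.h],
            "rotation_degrees": gt.rotation_degrees,
            "tokens": [
                {"text": t, "bbox": [r.x, r.y, r.w, r.h], "line_index": li}
                for t, r, li in gt.tokens
            ],
            "records": [
                {
                    "medication": rec.medication,
                    "dose_value": rec.dose_value,
                    "dose_units": rec.dose_units,
                    "remaining": rec.remaining,
                    "remaining_kind": rec.remaining_kind,
                }
                for rec in gt.records
            ],
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        names.append(stem)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"frames": names}, indent=1))
    return manifest
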