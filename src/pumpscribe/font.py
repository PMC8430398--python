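"""Bundled 5x7 dot-matrix display font.

Pump displays use low-resolution block glyphs; this module defines a
classic 5x7 dot-matrix font directly in source so that the synthetic
renderer can place text with exactly known pixel geometry and the
shape-library OCR engine can match observed glyph cells against the same
bitmaps.  Glyph cells are 5 columns wide with a 1-column advance gap; a
space advances one full cell (6 columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GLYPHS", "CELL_W", "CELL_H", "ADVANCE", "glyph_bitmap", "layout_text", "render_text_mask", "text_width_cells"]

CELL_W = 5
CELL_H = 7
ADVANCE = 6  # cell plus 1-column gap

_RAW = {
    "A": (".###.", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "B": ("####.", "#...#", "#...#", "####.", "#...#", "#...#", "####."),
    "C": (".###.", "#...#", "#....", "#....", "#....", "#...#", ".###."),
    "D": ("####.", "#...#", "#...#", "#...#", "#...#", "#...#", "####."),
    "E": ("#####", "#....", "#....", "####.", "#....", "#....", "#####"),
    "F": ("#####", "#....", "#....", "####.", "#....", "#....", "#...."),
    "G": (".###.", "#...#", "#....", "#.###", "#...#", "#...#", ".###."),
    "H": ("#...#", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "I": (".###.", "..#..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "J": ("..###", "...#.", "...#.", "...#.", "...#.", "#..#.", ".##.."),
    "K": ("#...#", "#..#.", "#.#..", "##...", "#.#..", "#..#.", "#...#"),
    "L": ("#....", "#....", "#....", "#....", "#....", "#....", "#####"),
    "M": ("#...#", "##.##", "#.#.#", "#.#.#", "#...#", "#...#", "#...#"),
    "N": ("#...#", "##..#", "#.#.#", "#..##", "#...#", "#...#", "#...#"),
    "O": (".###.", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "P": ("####.", "#...#", "#...#", "####.", "#....", "#....", "#...."),
    "Q": (".###.", "#...#", "#...#", "#...#", "#.#.#", "#..#.", ".##.#"),
    "R": ("####.", "#...#", "#...#", "####.", "#.#..", "#..#.", "#...#"),
    "S": (".####", "#....", "#....", ".###.", "....#", "....#", "####."),
    "T": ("#####", "..#..", "..#..", "..#..", "..#..", "..#..", "..#.."),
    "U": ("#...#", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "V": ("#...#", "#...#", "#...#", "#...#", "#...#", ".#.#.", "..#.."),
    "W": ("#...#", "#...#", "#...#", "#.#.#", "#.#.#", "##.##", "#...#"),
    "X": ("#...#", "#...#", ".#.#.", "..#..", ".#.#.", "#...#", "#...#"),
    "Y": ("#...#", "#...#", ".#.#.", "..#..", "..#..", "..#..", "..#.."),
    "Z": ("#####", "....#", "...#.", "..#..", ".#...", "#....", "#####"),
    "0": (".###.", "#...#", "#..##", "#.#.#", "##..#", "#...#", ".###."),
    "1": ("..#..", ".##..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "2": (".###.", "#...#", "....#", "..##.", ".#...", "#....", "#####"),
    "3": (".###.", "#...#", "....#", "..##.", "....#", "#...#", ".###."),
    "4": ("...#.", "..##.", ".#.#.", "#..#.", "#####", "...#.", "...#."),
    "5": ("#####", "#....", "####.", "....#", "....#", "#...#", ".###."),
    "6": (".###.", "#....", "#....", "####.", "#...#", "#...#", ".###."),
    "7": ("#####", "....#", "...#.", "..#..", ".#...", ".#...", ".#..."),
    "8": (".###.", "#...#", "#...#", ".###.", "#...#", "#...#", ".###."),
    "9": (".###.", "#...#", "#...#", ".####", "....#", "....#", ".###."),
    "/": ("....#", "....#", "...#.", "..#..", ".#...", "#....", "#...."),
    ":": (".....", "..#..", "..#..", ".....", "..#..", "..#..", "....."),
    ".": (".....", ".....", ".....", ".....", ".....", "..##.", "..##."),
    "-": (".....", ".....", ".....", ".###.", ".....", ".....", "....."),
    "+": (".....", "..#..", "..#..", "#####", "..#..", "..#..", "....."),
    "%": ("##..#", "##..#", "...#.", "..#..", ".#...", "#..##", "#..##"),
}

GLYPHS: dict[str, np.ndarray] = {
    ch: np.array([[c == "#" for c in row] for row in rows], dtype=bool)
    for ch, rows in _RAW.items()
}


def glyph_bitmap(ch: str) -> np.ndarray:
    """7x5 boolean bitmap for one character (case-insensitive)."""
    return GLYPHS[ch.upper()]


@dataclass(frozen=True)
class GlyphPlacement:
    """One placed glyph: character plus its cell origin in pixels."""

    char: str
    x: int  # left edge of the 5-column cell, in pixels
    scale: int


def text_width_cells(text: str) -> int:
    """Width of a text line in font columns (cells), including advance gaps."""
    if not text:
        return 0
    return ADVANCE * len(text) - 1


def layout_text(text: str, scale: int) -> list[GlyphPlacement]:
    """Place each non-space character of ``text`` on a baseline at integer scale."""
    out = []
    for i, ch in enumerate(text.upper()):
        if ch == " ":
            continue
        if ch not in GLYPHS:
            raise KeyError(f"glyph not in font: {ch!r}")
        out.append(GlyphPlacement(char=ch, x=i * ADVANCE * scale, scale=scale))
    return out


def render_text_mask(text: str, scale: int) -> np.ndarray:
    """Boolean ink mask of one text line at ``scale`` pixels per font dot.

    Shape is ``(7*scale, width_cells*scale)``; nearest-neighbour scaling
    keeps glyph geometry exact.
    """
    w = text_width_cells(text)
    mask = np.zeros((CELL_H, max(w, 1)), dtype=bool)
    for i, ch in enumerate(text.upper()):
        if ch == " ":
            continue
        if ch not in GLYPHS:
            raise KeyError(f"glyph not in font: {ch!r}")
        mask[:, i * ADVANCE : i * ADVANCE + CELL_W] = GLYPHS[ch]
    return np.kron(mask, np.ones((scale, scale), dtype=bool))
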