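"""Pipeline configuration.

Every tunable parameter of the pipeline lives in one of the dataclasses
below and can be overridden from a YAML key-value file via
:func:`load_config`.  The shipped medication lexicon and unit list are
plain-text files (one entry per line, ``#`` comments) that deployments are
expected to edit for their own pumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import InvalidParameter

__all__ = [
    "LocalizationParams",
    "DeskewParams",
    "CorrectionParams",
    "ParserParams",
    "StreamParams",
    "CaptureConfig",
    "PipelineConfig",
    "load_config",
    "load_wordlist",
    "default_lexicon",
    "default_units",
]

# Letter pairs OCR engines routinely confuse on low-resolution display
# glyphs; substitutions between pair members cost half a regular edit.
DEFAULT_CONFUSABLE_LETTERS = frozenset(
    {
        frozenset("ft"),
        frozenset("il"),
        frozenset("ce"),
        frozenset("ao"),
        frozenset("nm"),
        frozenset("uv"),
        frozenset("gq"),
        frozenset("hb"),
    }
)

# Digits that become mutually interchangeable when the image is
# insufficiently processed; never auto-corrected, only flagged.
DEFAULT_CONFUSABLE_DIGITS = frozenset("5689")


def load_wordlist(path: Union[str, Path]) -> frozenset[str]:
    """Read a plain-text word list: one entry per line, '#' comments, blank lines ignored."""
    words = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)


def _packaged_wordlist(name: str) -> frozenset[str]:
    text = resources.files("pumpscribe.data").joinpath(name).read_text(encoding="utf-8")
    words = set()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)


def default_lexicon() -> frozenset[str]:
    """The shipped medication/display-vocabulary lexicon."""
    return _packaged_wordlist("lexicon.txt")


def default_units() -> frozenset[str]:
    """The shipped dose-rate unit strings."""
    return _packaged_wordlist("units.txt")


@dataclass(frozen=True)
class LocalizationParams:
    """Display-localization stage.

    Canny hysteresis thresholds are expressed in intensity units of local
    step contrast (0-255): an isolated edge whose contrast falls below
    ``canny_low`` produces no edge pixels.  ``min_area_fraction`` is the
    smallest fraction of the frame area the winning rectangle may cover
    before the frame is rejected as having no display.
    """

    canny_low: float = 50.0
    canny_high: float = 150.0
    min_area_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.canny_low <= self.canny_high <= 255):
            raise InvalidParameter(
                f"canny thresholds must satisfy 0 <= low <= high <= 255, "
                f"got {self.canny_low}, {self.canny_high}"
            )
        if not (0 < self.min_area_fraction < 1):
            raise InvalidParameter("min_area_fraction must be in (0, 1)")


@dataclass(frozen=True)
class DeskewParams:
    """Enhancement and deskew stage.

    ``min_width_fraction`` is the fraction of the image width a shape's
    bounding rectangle must exceed to be a key-horizontal-line candidate
    (3/4 by default); ``crop_top_fraction``/``crop_bottom_fraction`` place
    the vertical crop at 5% and 90% of the image height.
    """

    enlarge_factor: float = 2.0
    block_size: int = 31
    offset_c: float = 10.0
    min_width_fraction: float = 0.75
    crop_top_fraction: float = 0.05
    crop_bottom_fraction: float = 0.90
    crop_x_pad_fraction: float = 0.02  # x-crop padding beyond the key-line rect
    polarity: str = "dark-on-light"  # text polarity on the display

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise InvalidParameter(f"block_size must be odd and >= 3, got {self.block_size}")
        if not (0 < self.min_width_fraction <= 1):
            raise InvalidParameter("min_width_fraction must be in (0, 1]")
        if not (0 <= self.crop_top_fraction < self.crop_bottom_fraction <= 1):
            raise InvalidParameter("crop fractions must satisfy 0 <= top < bottom <= 1")
        if not (0 <= self.crop_x_pad_fraction < 0.5):
            raise InvalidParameter("crop_x_pad_fraction must be in [0, 0.5)")
        if self.enlarge_factor < 1:
            raise InvalidParameter("enlarge_factor must be >= 1")
        if self.polarity not in ("dark-on-light", "light-on-dark"):
            raise InvalidParameter(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class CorrectionParams:
    """OCR post-correction stage."""

    lexicon: frozenset[str] = field(default_factory=default_lexicon)
    max_edit_distance: int = 2
    confusable_digits: frozenset[str] = DEFAULT_CONFUSABLE_DIGITS
    confusable_letters: frozenset[frozenset[str]] = DEFAULT_CONFUSABLE_LETTERS
    confidence_threshold: float = 60.0

    def __post_init__(self) -> None:
        if self.max_edit_distance < 0:
            raise InvalidParameter("max_edit_distance must be >= 0")
        for w in self.lexicon:
            if not (w.isalpha() and w == w.lower()):
                raise InvalidParameter(f"lexicon entries must be lowercase alphabetic: {w!r}")

    def edit_bound(self, word: str) -> float:
        """Edit-distance bound for a word: the configured maximum, scaled up to ceil(len/4) for long words."""
        return max(self.max_edit_distance, math.ceil(len(word) / 4))


@dataclass(frozen=True)
class ParserParams:
    """Keyword/number pairing and record assembly.

    A token is a keyword when its count of alphabetic characters is
    *strictly greater than* ``min_keyword_alpha_chars`` (the display-text
    rule: keywords have more than 4 letters).
    """

    min_keyword_alpha_chars: int = 4
    pairing_metric: str = "same-line-then-nearest-x"
    known_units: frozenset[str] = field(default_factory=default_units)

    def __post_init__(self) -> None:
        if self.min_keyword_alpha_chars < 1:
            raise InvalidParameter("min_keyword_alpha_chars must be >= 1")
        if self.pairing_metric not in ("same-line-then-nearest-x", "euclidean-bbox-centers"):
            raise InvalidParameter(f"unknown pairing metric {self.pairing_metric!r}")


@dataclass(frozen=True)
class StreamParams:
    """Serial/file output stage (8-N-1 framing; baud applies to real ports only)."""

    baud: int = 9600
    retries: int = 3
    retry_delay_seconds: float = 0.1

    def __post_init__(self) -> None:
        if self.baud <= 0 or self.retries < 0:
            raise InvalidParameter("baud must be > 0 and retries >= 0")


@dataclass(frozen=True)
class CaptureConfig:
    """Capture-loop configuration.

    ``source`` is an image file, a directory, a glob pattern, or
    ``camera:<index>``.  One frame is processed per ``interval_seconds``
    tick; acquisition may run faster, only the latest frame at each tick is
    processed.
    """

    source: str = "."
    interval_seconds: float = 1.0
    max_frames: Optional[int] = None
    sinks: tuple[str, ...] = ("stdout",)
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.interval_seconds <= 0:
            raise InvalidParameter("interval_seconds must be > 0")
        if not self.sinks:
            raise InvalidParameter("at least one sink is required")
        if self.log_level not in ("debug", "info", "warning", "error"):
            raise InvalidParameter(f"unknown log level {self.log_level!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters bundled together."""

    localization: LocalizationParams = field(default_factory=LocalizationParams)
    deskew: DeskewParams = field(default_factory=DeskewParams)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    parser: ParserParams = field(default_factory=ParserParams)
    stream: StreamParams = field(default_factory=StreamParams)
    capture: CaptureConfig = field(default_factory=CaptureConfig)
    engine: str = "template"  # "template" or "tesseract"


_SECTION_TYPES = {
    "localization": LocalizationParams,
    "deskew": DeskewParams,
    "correction": CorrectionParams,
    "parser": ParserParams,
    "stream": StreamParams,
    "capture": CaptureConfig,
}


def _build_section(cls, data: dict, base_dir: Path):
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if cls is CorrectionParams and key == "lexicon_file":
            kwargs["lexicon"] = load_wordlist(base_dir / value)
            continue
        if cls is ParserParams and key == "units_file":
            kwargs["known_units"] = load_wordlist(base_dir / value)
            continue
        if key not in known:
            raise InvalidParameter(f"unknown {cls.__name__} key {key!r}")
        if cls is CorrectionParams and key == "confusable_digits":
            value = frozenset(str(d) for d in value)
        elif cls is CorrectionParams and key == "confusable_letters":
            value = frozenset(frozenset(p) for p in value)
        elif cls is CorrectionParams and key == "lexicon":
            value = frozenset(str(w).lower() for w in value)
        elif cls is ParserParams and key == "known_units":
            value = frozenset(str(u).lower() for u in value)
        elif cls is CaptureConfig and key == "sinks":
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (``None`` = all defaults).

    The file holds one mapping per stage (``localization``, ``deskew``,
    ``correction``, ``parser``, ``stream``, ``capture``) plus the top-level
    ``engine`` key.  Relative ``lexicon_file``/``units_file`` paths are
    resolved against the config file's directory.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise InvalidParameter("config file must contain a mapping")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        data = raw.pop(section, None)
        if data is not None:
            kwargs[section] = _build_section(cls, dict(data), path.parent)
    engine = raw.pop("engine", None)
    if engine is not None:
        kwargs["engine"] = str(engine)
    if raw:
        raise InvalidParameter(f"unknown config sections: {sorted(raw)}")
    return PipelineConfig(**kwargs)
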