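"""End-to-end frame processing and the operator capture loop.

``process_frame`` chains the stages in the order they run: locate the
display, enlarge, binarize, find the key line, rotate and crop, OCR,
correct, parse.  ``run_capture`` drives it over a frame source on a timed
trigger, emits packets to the configured sinks, and keeps strict frame
accounting: every processed frame is exactly one of succeeded, skipped
(recoverable per-frame failure, heartbeat emitted) or failed (unexpected
error, heartbeat emitted).
"""

from __future__ import annotations

import glob as globmod
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .config import CaptureConfig, PipelineConfig
from .core import PumpRecord
from .deskew import adaptive_mean_binarize, enlarge, find_key_line, rotate_and_crop
from .errors import FrameError, SourceError
from .localization import locate_display
from .parser import parse_tokens
from .recognition import OcrEngine, make_engine, run_ocr
from .stream import PacketWriter

__all__ = ["process_frame", "run_capture", "SessionSummary", "load_frame", "iso_now"]

logger = logging.getLogger("pumpscribe")

_LOG_FORMAT = "%(asctime)s %(levelname)s %(stage)s %(frame_id)s %(message)s"


def iso_now() -> str:
    """Current UTC time, ISO-8601 with millisecond precision."""
    return datetime.now(timezone.utc).isoformat(timespec="milliseconds")


def load_frame(path) -> np.ndarray:
    """Read a PNG/JPEG/BMP still into a uint8 array (grayscale or RGB)."""
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB")
            return np.asarray(im)
    except (OSError, UnidentifiedImageError) as exc:
        raise SourceError(f"cannot read image {path}: {exc}") from exc


def process_frame(
    frame: np.ndarray,
    config: Optional[PipelineConfig] = None,
    engine: Optional[OcrEngine] = None,
    frame_time: Optional[str] = None,
) -> list[PumpRecord]:
    """Run the full extraction pipeline on one frame.

    Raises a :class:`~pumpscribe.errors.FrameError` subclass on any
    recoverable per-frame failure; callers in a capture loop count and
    skip such frames.
    """
    cfg = config or PipelineConfig()
    eng = engine if engine is not None else make_engine(cfg.engine)
    _, crop = locate_display(
        frame,
        canny_low=cfg.localization.canny_low,
        canny_high=cfg.localization.canny_high,
        min_area_fraction=cfg.localization.min_area_fraction,
    )
    big = enlarge(crop, cfg.deskew.enlarge_factor)
    binary = adaptive_mean_binarize(big, cfg.deskew)
    line = find_key_line(binary, cfg.deskew)
    text_img = rotate_and_crop(binary, line, cfg.deskew)
    tokens = run_ocr(text_img, eng)
    return parse_tokens(tokens, cfg.correction, cfg.parser, frame_time or iso_now())


@dataclass
class SessionSummary:
    """Reconciled accounting for one capture session."""

    processed: int = 0
    succeeded: int = 0
    skipped: int = 0
    failed: int = 0
    records_emitted: int = 0

    def reconciles(self) -> bool:
        return self.processed == self.succeeded + self.skipped + self.failed


def _list_source_frames(source: str) -> list[Path]:
    p = Path(source)
    if p.is_dir():
        paths = sorted(q for q in p.iterdir() if q.suffix.lower() in (".png", ".jpg", ".jpeg", ".bmp"))
    elif p.is_file():
        paths = [p]
    else:
        paths = [Path(s) for s in sorted(globmod.glob(source))]
    if not paths:
        raise SourceError(f"no readable frames at {source!r}")
    return paths


def _log(level: int, stage: str, frame_id: str, msg: str) -> None:
    logger.log(level, msg, extra={"stage": stage, "frame_id": frame_id})


def run_capture(
    cfg: CaptureConfig,
    pipeline_config: Optional[PipelineConfig] = None,
    engine: Optional[OcrEngine] = None,
    session_id: str = "",
) -> SessionSummary:
    """Process one frame per interval tick from the source and stream records.

    File/directory/glob sources are replayed in name order (the interval
    sleep is skipped when replaying files faster than real time is
    harmless); a ``camera:<index>`` source requires an imaging backend
    with camera support and otherwise raises :class:`SourceError` at
    startup.  Per-frame pipeline errors are logged and counted, never
    fatal.
    """
    pcfg = pipeline_config or PipelineConfig()
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
    logger.setLevel(cfg.log_level.upper())

    if cfg.source.startswith("camera:"):
        try:
            import cv2  # noqa: F401
        except ImportError as exc:
            raise SourceError("camera capture requires OpenCV (cv2)") from exc
        raise SourceError("live camera capture is not supported in this build")

    frames = _list_source_frames(cfg.source)
    if cfg.max_frames is not None:
        frames = frames[: cfg.max_frames]

    eng = engine if engine is not None else make_engine(pcfg.engine)
    writers = [PacketWriter(s, session_id=session_id, params=pcfg.stream) for s in cfg.sinks]
    summary = SessionSummary()
    try:
        for i, path in enumerate(frames):
            if i > 0 and cfg.interval_seconds >= 0.05:
                time.sleep(cfg.interval_seconds)
            t = iso_now()
            frame_id = path.name
            summary.processed += 1
            records: Sequence[PumpRecord] = []
            try:
                frame = load_frame(path)
                records = process_frame(frame, pcfg, eng, frame_time=t)
                summary.succeeded += 1
                _log(logging.INFO, "pipeline", frame_id, f"{len(records)} record(s)")
            except FrameError as exc:
                summary.skipped += 1
                _log(logging.WARNING, "pipeline", frame_id, f"skipped: {exc}")
            except SourceError as exc:
                summary.failed += 1
                _log(logging.ERROR, "source", frame_id, f"failed: {exc}")
            except Exception as exc:  # unexpected: count, never crash the loop
                summary.failed += 1
                _log(logging.ERROR, "pipeline", frame_id, f"failed: {exc}")
            for w in writers:
                w.emit(list(records), timestamp=t)
            summary.records_emitted += len(records)
    finally:
        for w in writers:
            w.close()
    assert summary.reconciles(), "frame accounting must reconcile"
    return summary
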