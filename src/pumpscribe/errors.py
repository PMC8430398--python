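"""Exception hierarchy for the pump-display extraction pipeline.

Per-frame failures (``DisplayNotFound``, ``KeyLineNotFound``, ``OcrFailed``,
``NoMedicationFound``, ``DegenerateCrop``) are recoverable: the capture loop
counts and skips the frame, emits a heartbeat packet, and continues.  Only
configuration and environment problems (``InvalidParameter``,
``EngineUnavailable``, ``SourceError``) abort a session.
"""


class PumpscribeError(Exception):
    """Base class for all pipeline errors."""


class InvalidImage(PumpscribeError):
    """Input array is not a valid image for the requested operation."""


class InvalidParameter(PumpscribeError):
    """A configuration value violates its documented invariant."""


class FrameError(PumpscribeError):
    """Base for recoverable per-frame failures; the capture loop skips the frame."""


class DisplayNotFound(FrameError):
    """No edge-bounded rectangle large enough to be the display screen."""


class KeyLineNotFound(FrameError):
    """No binarized shape satisfies the key-horizontal-line width criterion."""


class DegenerateCrop(FrameError):
    """The requested crop region is empty."""


class OcrFailed(FrameError):
    """The OCR engine failed on this frame."""


class NotANumber(FrameError):
    """A token could not be repaired into a numeric string."""


class NoMedicationFound(FrameError):
    """No lexicon medication keyword present among the frame's tokens."""


class EngineUnavailable(PumpscribeError):
    """The configured OCR engine cannot be constructed in this environment."""


class SpecOverflow(PumpscribeError):
    """Requested display text does not fit the display rectangle."""


class EncodingError(PumpscribeError):
    """A record field cannot be serialized as printable ASCII."""


class SinkError(PumpscribeError):
    """An output sink is unavailable after the configured retries."""


class SourceError(PumpscribeError):
    """The capture source cannot be opened."""
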