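# Methods

## Problem and scope

`pumpscribe` turns camera frames of a text-based infusion-pump display
into structured medication records and streams them as line-oriented
ASCII. The pipeline assumes a camera mounted roughly face-on to the
display (small in-plane rotation only — no keystone/perspective
correction), a display that is the largest edge-bounded rectangle in the
frame, and screen text laid out as one medication per line:
`<medication> <dose> <units> <remaining>`. Consumer-side parsing by the
acquisition platform, virtual-port creation, and co-acquired
physiological signals are out of scope.

## Coordinate and angle conventions

Images are `uint8` arrays, origin top-left, x rightward, y downward,
rectangles half-open `[x, x+w) × [y, y+h)`. Angles are degrees, positive
counterclockwise *as displayed* (with y down), matching
`PIL.Image.rotate` and `skimage.transform.rotate`. The synthetic
renderer uses the same convention, so a frame rendered at +5° must be
estimated at +5°.

## Localization

Grayscale conversion uses ITU-R BT.601 luminance weights. Edges come
from a Canny detector (σ = 1). Its hysteresis thresholds are exposed in
*intensity units of step contrast*: the detector's internal gradient
magnitude for an ideal step edge of unit contrast at σ = 1 is 2.5644, so
user thresholds are multiplied by this gain before they reach the
detector. The contract is that an isolated edge of contrast below
`canny_low` produces no edge pixels; defaults are 50/150, tunable per
deployment. Connected edge shapes (8-connectivity, outermost outline
only — holes ignored) are bounded by their smallest enclosing rectangle;
the largest area wins, with area ties broken topmost-then-leftmost so
the result is deterministic and order-independent. A winner covering
less than `min_area_fraction` (default 5%) of the frame raises
`DisplayNotFound`, which prevents glare specks from being declared "the
display". No aspect-ratio restriction is applied to candidates.

## Enhancement and deskew

The display crop is enlarged (default ×2, bilinear) so small glyph edges
survive thresholding, then binarized against the local block mean:
pixel < mean − offset (dark-on-light) or > mean + offset
(light-on-dark), block 31 px, offset 10 by default; equality classifies
as background so a constant image is deterministically all-background.
Block sums use an exact integer summed-area table, making each per-pixel
decision bit-exact — the unit suite verifies exact agreement with a
brute-force per-neighbourhood oracle on inputs up to 32×32. Defaults
were chosen so glyphs of ≥ 18 px survive binarization after enlargement.

The key horizontal line is the connected dark shape whose bounding box
is wider than ¾ of the image width with the smallest height. Its
rotation angle is the slope of the least-squares regression line through
the shape's outline points. The image rotates by −angle about its centre
(bilinear, border filled with background white so no fake edges enter),
then is cropped: columns to the key line's bounding-box x-range padded by
`crop_x_pad_fraction` (default 2% per side — without padding, at
rotations near 10° the bounding box of the *rotated* key line can fall a
few pixels short of the deskewed text extent and clip the last glyph of
a line), rows to `[⌊0.05·H⌋, ⌊0.90·H⌋)` of the image height. The crop
fractions are applied to the height at the moment of cropping
(post-rotation); rotation preserves the frame size here, so pre- and
post-rotation heights coincide.

## Recognition

OCR is consumed through a minimal engine protocol (image in, positioned
tokens out), so a deterministic engine can drive the tests and Tesseract
can be plugged in where installed. The bundled `TemplateOcrEngine` is a
shape-library matcher for the package's 5×7 dot-matrix display font:

* ink = pixels < 128; components touching the crop border (display-edge
  stripes, clipped shapes), components spanning more than half the crop
  in either direction (rule lines, border remnants), and components
  under `min_component_area` = 25 px (noise specks, far below the
  smallest glyph feature at supported glyph sizes) are discarded;
* rows with ink are split into line bands at gaps of more than 3 blank
  rows; bands shorter than 40% of the tallest are dropped;
* each band splits into glyph cells at blank columns; cells separated by
  more than 4.5/7 of the band height start a new token (the font's
  advance gap is 1 column vs. 6 for a space);
* a cell whose ink spans ≥ 55% of the band height is classified against
  tight-cropped glyph templates (registration-free — this absorbs the
  few-pixel vertical drift a 0.3–0.5° residual rotation causes across a
  long line); short marks (`.`, `-`) are classified in band-frame
  position, since their identity *is* their placement. Matching is
  minimum Hamming distance on a 21×15 normalized grid; confidence is
  100·(1 − distance), and a best match worse than 40% mismatch yields
  `?`.

Post-correction implements the documented display-reading rules:

* **Words** snap to the nearest lexicon entry under a weighted
  Levenshtein bound — substitutions between configured confusable letter
  pairs (f↔t and a standard OCR confusion set) cost 0.5, everything else
  1. The bound is `max(2, ⌈len/4⌉)`. Correction never increases distance
  to the lexicon and is idempotent; unmatched tokens are flagged, not
  altered.
* **Numbers** are repaired with a fixed letter→digit table (O→0, S→5,
  I/l→1, B→8, …); a string that still fails `\d+(\.\d+)?` raises
  `NotANumber`. The mutually confusable digits {5, 6, 8, 9} are never
  auto-corrected by context — when one appears with engine confidence
  below 60/100 the token is only flagged low-confidence.

## Parsing

Keywords are tokens with strictly more than `min_keyword_alpha_chars`
(default 4) alphabetic characters. Keyword–number pairing is a globally
optimal one-to-one assignment (Hungarian algorithm) under the configured
metric: same-line-then-nearest-horizontal-centre by default, Euclidean
bbox-centres as an alternative. "At most one" is implemented with an
explicit stay-unpaired option priced at 5·10⁵, below the same-line
metric's cross-line penalty (10⁶ per line of separation): a surplus
keyword stays unpaired rather than grabbing a number from another line.
Note the >4-letters rule admits unit tokens such as `units/hr`; record
assembly therefore takes the dose from same-line pairs only, preferring
the pair anchored on the medication token and otherwise the leftmost
paired number on the line — which reproduces the display order where the
dose amount follows the medication. Adjacent lexicon words on one line
merge into one multi-word medication (`sodium chloride`). Units attach
from the nearest known-units token on the dose line; the remaining field
is the first `h:mm` token (kind `time`) or bare number (kind `volume`)
to the right of the dose, stored raw — the display does not always
distinguish volume-left from time-left, so the package tags rather than
interprets. Decimal separator is `.`; thousands separators are rejected.
A frame with no lexicon medication raises `NoMedicationFound`, which the
capture loop converts to a heartbeat packet.

## Streaming

The wire format is invented here (the transport's consumer side is a
configurable parser on the acquisition platform): one CRLF-terminated
printable-ASCII line per record,
`T=<iso8601>;SEQ=<n>;MED=<name>;DOSE=<v>;UNITS=<u>;REM=<r>;LC=<0|1>`,
absent fields empty, heartbeats with all record fields empty. The
decoder is total over this grammar and `decode(encode(r)) == r`
field-wise (`remaining_kind` is recovered from the field's shape).
Sequences are strictly increasing per session and asserted on every
write. Serial sinks are opened as named files (a virtual port path is
file-like; creating the port is the operator's job); 8-N-1 framing and
baud are configuration for real ports. CSV (fixed seven-column header)
and JSON-lines sinks are provided for research use.

## Capture loop

One frame is processed per interval tick (default 1.0 s; acquisition may
run faster, only the latest frame per tick is processed — file sources
replay in name order). Timestamps are taken at frame acquisition, not at
OCR completion, for alignment with other bedside signals. Per-frame
errors are never fatal: every processed frame is exactly one of
succeeded / skipped (recoverable `FrameError`, heartbeat emitted) /
failed (unexpected error), and the summary asserts
`processed = succeeded + skipped + failed`. Camera sources require an
imaging backend with camera support; file, directory and glob sources
cover headless and test use. Log lines carry timestamp, level, stage and
frame id.

## Synthetic display renderer

The renderer emulates what the pipeline must survive, with exact ground
truth by construction: a bright (or dark) display rectangle on a darker
cluttered background, a wide thin rule line (the key horizontal line),
1–2 medication lines in the bundled 5×7 font, in-plane rotation, Gaussian
noise, and an optional glare ellipse. Geometry: 960×720 frames,
background gray 48, display 480–620 × 300–380 px at fill 230 (text 20),
rule line at 9% of display height spanning 3%–97% of its width, text
from 6% width with line pitch 1.8× glyph height ("significant space
between lines" is what makes the line-band segmentation reliable), glyph
height 21 px (5×7 font at integer scale 3). Rotations are uniform in
±10°, distractor count 0–3 (bright rectangles/ellipses kept clear of the
display and smaller than it). Difficulty tiers: *clean* (no noise or
glare), *noisy* (σ ∈ [3, 8]), *glare* (one ellipse, peak 140–230, axes
60–130 × 40–90, placed over the display). All randomness flows from the
spec seed, so renders are byte-reproducible.

Ground-truth records derive from the rendered lines by the display
grammar itself, making render → extract → parse a checkable identity.
What the renderer deliberately does **not** model: perspective/keystone
distortion, lens blur and chromatic effects, proportional or unknown
fonts, specular reflections with structure, and motion blur. Passing the
synthetic suites therefore demonstrates the pipeline's geometric and
parsing logic, not performance on arbitrary real cameras or pump models;
a real deployment revalidates with its own device and the Tesseract
adapter if the display font differs.

## Verification sizes and numerical choices

The shipped suites are sized to run in seconds-to-minutes on one CPU:
50-frame end-to-end clean suite, 100-render deskew and localization
checks, 500-record stream round-trip, 200-trial pairing-oracle
comparison, brute-force binarization oracle on ≤ 32×32 inputs. Ties and
degenerate inputs are pinned down deliberately: equal local mean →
background; equal contour area → topmost-then-leftmost; constant image →
no edges; empty crop → `DegenerateCrop`; rotation interpolation is
bilinear with background fill, and binarized images are re-thresholded
at 128 after rotation to keep the binary contract.

## Configuration

All parameters live in dataclasses (`LocalizationParams`,
`DeskewParams`, `CorrectionParams`, `ParserParams`, `StreamParams`,
`CaptureConfig`) and can be overridden from a YAML file with one mapping
per stage plus a top-level `engine` key (`template` or `tesseract`);
`correction.lexicon_file` and `parser.units_file` point at user-editable
word lists, resolved relative to the config file.

## Known limitations

* Oblique camera angles are not corrected; the mitigation is centered
  mounting.
* Strong glare over the medication name loses the frame (by design it is
  skipped with a heartbeat, never guessed).
* The >4-letter keyword rule cannot see short medication names (e.g.
  "kcl"); lexicon matching still finds them on the line, but they cannot
  anchor a pairing.
* The template engine is specialised to the bundled dot-matrix font;
  other display fonts need the Tesseract adapter or a new template set.
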