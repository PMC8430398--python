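# pumpscribe

Many bedside infusion pumps show everything a clinician needs — medication,
dose rate, volume or time remaining — on a small text display, but have no
digital output port. Treatment data therefore ends up hand-copied into
charts at hourly resolution while the physiological signals around it are
recorded continuously. `pumpscribe` closes that gap with computer vision:
a camera pointed at the pump's screen, a text-information-extraction (TIE)
pipeline that localizes the display, enhances and deskews it, recognizes
the text, and a streamer that emits the resulting structured records as
RS232-friendly ASCII lines any bedside acquisition platform can ingest.

It is aimed at clinical-research engineers who need continuous medication
records aligned with other bedside time series, without touching the pump
itself. A synthetic display renderer with exact ground truth makes the
whole pipeline testable end to end without any hardware.

## The pipeline

For each captured frame:

1. **Localization** — convert to grayscale, trace edges with a Canny
   detector (hysteresis thresholds in intensity units, defaults 50/150),
   bound every connected edge shape with its smallest enclosing rectangle,
   and crop to the largest-area rectangle, assumed to be the display.
2. **Enhancement & deskew** — enlarge (×2), binarize against the local
   block mean (adaptive mean threshold, 31-px blocks, offset 10), find the
   *key horizontal line*: the shape whose bounding box is wider than ¾ of
   the image with the smallest height. The least-squares line through its
   contour points gives the rotation angle θ; the image is rotated by −θ,
   cropped horizontally to the key line's extent and vertically to the
   5%–90% band of the image height.
3. **Recognition** — a pluggable OCR engine returns positioned word
   tokens. The bundled engine is a deterministic shape-library matcher for
   the package's 5×7 dot-matrix display font; a `pytesseract` adapter is
   provided for hosts with Google Tesseract. Post-correction snaps words
   to the nearest lexicon entry under a weighted edit-distance bound
   (known confusions such as f↔t cost ½), repairs letter-digit artifacts
   (`2S` → `25`), and flags — never rewrites — the mutually confusable
   digits {5, 6, 8, 9} when engine confidence is low.
4. **Parsing** — *keywords* are tokens with strictly more than 4
   alphabetic characters; each keyword is connected with the number in the
   most similar location (globally optimal one-to-one assignment,
   same-line-then-nearest-x metric) and each medication line
   `<medication> <dose> <units> <remaining>` becomes a `PumpRecord`.
5. **Streaming** — records are serialized as CRLF-terminated key-value
   lines (`T=…;SEQ=…;MED=…;DOSE=…;UNITS=…;REM=…;LC=…`) to a serial port
   path, CSV, or JSON-lines sink, with heartbeat packets on empty frames
   so downstream time series stay aligned.

## Worked example

Render three synthetic pump frames, read one back, then run the capture
loop into a CSV sink:

```sh
$ pumpscribe render-suite --n 3 --seed 11 --difficulty clean --out demo
wrote 3 frames, manifest demo/manifest.json

$ pumpscribe single demo/frame_0000.png
[
 {
  "medication": "insulin",
  "dose_value": 75.0,
  "dose_units": "ml/hr",
  "remaining": "776",
  "remaining_kind": "volume",
  "timestamp": "2026-09-27T18:06:06.333+00:00",
  "low_confidence": false
 }
]

$ pumpscribe capture --source demo --interval 0.01 --out csv:demo/records.csv
{"processed": 3, "succeeded": 3, "skipped": 0, "failed": 0, "records_emitted": 4}

$ head -4 demo/records.csv
timestamp,sequence,medication,dose_value,dose_units,remaining,low_confidence
2026-09-27T18:06:07.397+00:00,1,insulin,75,ml/hr,776,0
2026-09-27T18:06:07.652+00:00,2,midazolam,50,mcg/hr,7:22,0
2026-09-27T18:06:07.652+00:00,3,insulin,50,units/hr,872,0
```

The first frame showed `INSULIN 75 ML/HR 776`: insulin running at
75 ml/hr with 776 (a volume, tagged `volume` rather than a time) left in
the bag. The capture summary reconciles exactly: every processed frame is
either succeeded, skipped (recoverable failure, heartbeat emitted) or
failed. A virtual serial port (e.g. from a null-modem emulator) can be
given as `--out serial:/path/to/port` to feed an acquisition platform.

The medication lexicon (`src/pumpscribe/data/lexicon.txt`) and unit list
(`units.txt`) are plain text and meant to be edited per deployment; all
stage parameters can be overridden from a YAML config file (see
`docs/methods.md`).

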