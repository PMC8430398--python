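"""Key-information reduction: corrected tokens -> structured medication records.

The display grammar is ``<medication> <dose> <units> <remaining>`` per
line, with the dose always followed by its amount and the left/time
remaining.  Keywords are tokens with strictly more than four alphabetic
characters; each keyword is connected to the number in the most similar
location by a globally optimal one-to-one assignment, and records are
assembled per medication line.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import CorrectionParams, ParserParams
from .core import OcrToken, PumpRecord
from .errors import NoMedicationFound, NotANumber
from .recognition import correct_number, correct_word, weighted_edit_distance

__all__ = [
    "is_keyword",
    "is_numeric_token",
    "pair_keywords_with_numbers",
    "assemble_record",
    "parse_tokens",
    "TIME_RE",
]

TIME_RE = re.compile(r"^\d{1,3}:\d{2}$")

# line mismatches dominate any horizontal offset in the same-line metric
_LINE_PENALTY = 1e6

# a keyword prefers staying unpaired over any pairing costlier than this
# (cross-line pairings under the same-line metric are overflow artifacts)
UNPAIRED_COST = _LINE_PENALTY / 2


def is_keyword(token: OcrToken, p: ParserParams) -> bool:
    """True iff the token has strictly more than ``min_keyword_alpha_chars`` letters."""
    alpha = sum(1 for c in token.text if c.isalpha())
    return alpha > p.min_keyword_alpha_chars


def is_numeric_token(token: OcrToken) -> bool:
    """True for a plain decimal number (no time separators, no unit slashes)."""
    return bool(re.match(r"^\d+(\.\d+)?$", token.text))


def _pair_cost(k: OcrToken, n: OcrToken, p: ParserParams) -> float:
    kc = k.bbox.center
    nc = n.bbox.center
    if p.pairing_metric == "same-line-then-nearest-x":
        return _LINE_PENALTY * abs(k.line_index - n.line_index) + abs(kc[0] - nc[0])
    return float(np.hypot(kc[0] - nc[0], kc[1] - nc[1]))


def pair_keywords_with_numbers(
    tokens: Sequence[OcrToken], p: ParserParams
) -> tuple[list[tuple[OcrToken, OcrToken]], list[OcrToken]]:
    """Pair each keyword with at most one numeric token, minimizing total distance.

    The assignment is globally optimal and one-to-one (Hungarian algorithm
    over the configured spatial metric).  "At most one": a keyword stays
    unpaired rather than accept a pairing costlier than
    :data:`UNPAIRED_COST`, which under the same-line metric rules out
    cross-line overflow pairings.  Returns ``(pairs, unpaired_keywords)``.
    """
    keywords = [t for t in tokens if is_keyword(t, p)]
    numbers = [t for t in tokens if is_numeric_token(t)]
    if not keywords or not numbers:
        return [], keywords
    k, m = len(keywords), len(numbers)
    # square matrix with one dummy "stay unpaired" column per keyword
    cost = np.full((k, m + k), UNPAIRED_COST, dtype=float)
    for i, kw in enumerate(keywords):
        for j, num in enumerate(numbers):
            cost[i, j] = _pair_cost(kw, num, p)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(keywords[r], numbers[c]) for r, c in zip(rows, cols) if c < m]
    paired_kw = {id(kw) for kw, _ in pairs}
    unpaired = [kw for kw in keywords if id(kw) not in paired_kw]
    return pairs, unpaired


def _merge_medication(
    line_tokens: list[OcrToken], lexicon: frozenset[str]
) -> Optional[list[OcrToken]]:
    """Maximal run of adjacent lexicon words at the start of the medication phrase."""
    run: list[OcrToken] = []
    for t in line_tokens:
        if t.text.lower() in lexicon:
            run.append(t)
        elif run:
            break
    return run or None


def assemble_record(
    pairs: Sequence[tuple[OcrToken, OcrToken]],
    tokens: Sequence[OcrToken],
    lexicon: frozenset[str],
    frame_time: Optional[str],
    p: Optional[ParserParams] = None,
) -> list[PumpRecord]:
    """Build one :class:`PumpRecord` per medication line.

    The medication is the (possibly multi-word) run of adjacent lexicon
    words on the line; the dose comes from the keyword/number pairing;
    units attach from the nearest known-units token on the dose line; the
    remaining field is the first time (hh:mm) or bare number after the
    dose, per the display's left-to-right ordering.  Raises
    :class:`NoMedicationFound` when no lexicon keyword is present.
    """
    p = p or ParserParams()
    by_line: dict[int, list[OcrToken]] = {}
    for t in tokens:
        by_line.setdefault(t.line_index, []).append(t)
    records: list[PumpRecord] = []
    for line_index in sorted(by_line):
        line_tokens = sorted(by_line[line_index], key=lambda t: t.bbox.x)
        med_run = _merge_medication(line_tokens, lexicon)
        if med_run is None:
            continue
        medication = " ".join(t.text.lower() for t in med_run)
        # dose: same-line pair only (cross-line pairings are assignment
        # overflow artifacts); prefer a pair anchored on the medication
        # itself, else the leftmost same-line paired number — unit tokens
        # such as 'units/hr' also clear the keyword rule and often carry
        # the pairing for their line
        same_line = [
            (k, n)
            for k, n in pairs
            if k.line_index == line_index and n.line_index == line_index
        ]
        dose_tok = next(
            (n for t in med_run for k, n in same_line if k is t), None
        )
        if dose_tok is None and same_line:
            dose_tok = min((n for _, n in same_line), key=lambda n: n.bbox.x)
        if dose_tok is None:
            continue
        dose_value = float(dose_tok.text)
        units = _nearest_units(line_tokens, dose_tok, p)
        remaining, kind = _remaining_after(line_tokens, dose_tok)
        low = any(t.low_confidence for t in (*med_run, dose_tok))
        records.append(
            PumpRecord(
                medication=medication,
                dose_value=dose_value,
                dose_units=units,
                remaining=remaining,
                remaining_kind=kind,
                timestamp=frame_time,
                low_confidence=low,
            )
        )
    if not records:
        raise NoMedicationFound("no lexicon medication keyword among tokens")
    return records


def _nearest_units(
    line_tokens: list[OcrToken], dose_tok: OcrToken, p: ParserParams
) -> Optional[str]:
    unit_toks = [t for t in line_tokens if t.text.lower() in p.known_units]
    if not unit_toks:
        return None
    cx = dose_tok.bbox.center[0]
    best = min(unit_toks, key=lambda t: abs(t.bbox.center[0] - cx))
    return best.text.lower()


def _remaining_after(
    line_tokens: list[OcrToken], dose_tok: OcrToken
) -> tuple[Optional[str], Optional[str]]:
    after = [t for t in line_tokens if t.bbox.x > dose_tok.bbox.x and t is not dose_tok]
    for t in after:
        if TIME_RE.match(t.text):
            return t.text, "time"
    for t in after:
        if is_numeric_token(t):
            return t.text, "volume"
    return None, None


def _correct_unit(
    token: OcrToken, correction: CorrectionParams, p: ParserParams
) -> OcrToken:
    """Snap a slash-bearing token to the nearest known unit within the edit bound."""
    word = token.text.lower()
    if word in p.known_units:
        return token.with_text(word)
    best, best_d = None, float("inf")
    for unit in sorted(p.known_units):
        d = weighted_edit_distance(word, unit, correction.confusable_letters)
        if d < best_d:
            best, best_d = unit, d
    if best is not None and best_d <= correction.edit_bound(word):
        return token.with_text(best)
    return token.with_text(word)


def parse_tokens(
    raw_tokens: Sequence[OcrToken],
    correction: CorrectionParams,
    parser_params: ParserParams,
    frame_time: Optional[str],
) -> list[PumpRecord]:
    """Full token-to-record stage: correct words and numbers, pair, assemble."""
    corrected: list[OcrToken] = []
    for t in raw_tokens:
        n_alpha = sum(c.isalpha() for c in t.text)
        if "/" in t.text:
            corrected.append(_correct_unit(t, correction, parser_params))
        elif n_alpha >= 3:
            # word-like, punctuation artifacts included ('P:ORPHINE')
            maybe_word = correct_word(t, correction)
            if not maybe_word.unmatched:
                corrected.append(maybe_word)
                continue
            try:
                corrected.append(correct_number(t, raw_tokens, correction))
            except NotANumber:
                corrected.append(maybe_word)
        elif any(c.isdigit() for c in t.text) and ":" not in t.text:
            # numeric with possible letter artifacts ('2S' -> '25')
            try:
                corrected.append(correct_number(t, raw_tokens, correction))
            except NotANumber:
                corrected.append(t)
        else:
            corrected.append(t.with_text(t.text.lower()))
    pairs, _ = pair_keywords_with_numbers(corrected, parser_params)
    return assemble_record(pairs, corrected, correction.lexicon, frame_time, parser_params)
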