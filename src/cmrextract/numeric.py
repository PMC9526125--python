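"""Numerical surface representations for report text.

Subword vocabularies contain few numerals and no decimal numbers, so a value
like ``51.01`` fragments into several pieces during tokenization.  This
module implements five representations of numeric tokens intended to probe
whether that fragmentation matters for extraction:

========================  ==========================================
mode                      ``RVESV: 51.01 ml`` becomes
========================  ==========================================
``original``              ``RVESV: 51.01 ml`` (identity)
``replaced_decimal``      ``RVESV: 51|01 ml``
``consistent_digits``     ``RVESV: 051010 ml``
``scientific``            ``RVESV: 5.10100e+01 ml``
``words``                 ``RVESV: fifty one point zero one ml``
========================  ==========================================

Only maximal numeric tokens are rewritten; every other character is
preserved byte-for-byte.  Each rewrite is recorded in an offset map so spans
in the transformed text can be projected back onto the original text (and
gold annotations projected forward) exactly.

The consistent-digits format is a fixed 6-character encoding: three integer
digits and three fractional digits, zero-padded, with the decimal point
removed (``51.01`` -> ``051010``).  Values that do not fit (negative, or
>= 1000 after rounding to 3 decimals) are left untransformed and flagged in
``TransformedText.warnings``.  Scientific notation uses a mantissa with five
digits after the decimal point and a signed two-digit exponent
(``5.10100e+01``).  The words mode spells numbers in lowercase English
without hyphens, reading fractional digits one at a time after "point".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

__all__ = [
    "MODES",
    "TransformedText",
    "transform_text",
    "invert_value",
    "map_span",
    "project_annotations",
    "number_to_words",
    "words_to_number",
    "NUMBER_RE",
]

Mode = Literal["original", "replaced_decimal", "consistent_digits", "scientific", "words"]
MODES: tuple[str, ...] = (
    "original",
    "replaced_decimal",
    "consistent_digits",
    "scientific",
    "words",
)

# A numeric token: optionally signed digits with at most one decimal point,
# delimited by non-alphanumerics.  A trailing bare period (sentence end) is
# not part of the token; digits glued to letters ("55ml") are not numbers.
NUMBER_RE = re.compile(r"(?<![0-9A-Za-z.])(-?\d+(?:\.\d+)?)(?![0-9A-Za-z])")


@dataclass(frozen=True)
class Replacement:
    """One rewritten numeric token: transformed span <-> original span."""

    t_start: int
    t_end: int
    o_start: int
    o_end: int


@dataclass(frozen=True)
class TransformWarning:
    o_start: int
    o_end: int
    token: str
    reason: str


@dataclass
class TransformedText:
    """Result of :func:`transform_text` with an exact two-way offset map."""

    mode: str
    text: str
    original_text: str
    replacements: tuple[Replacement, ...] = ()
    warnings: tuple[TransformWarning, ...] = field(default=())

    def to_original_span(self, span: tuple[int, int]) -> tuple[int, int]:
        """Project a span in transformed coordinates back onto the original.

        A boundary falling inside a rewritten token expands to cover the
        whole original token, so any partial hit on a transformed number
        recovers the full original number.
        """
        ts, te = span
        if not (0 <= ts <= te <= len(self.text)):
            raise ValueError(f"span {span} outside transformed text of length {len(self.text)}")
        return (
            self._map_pos(ts, start=True, forward=False),
            self._map_pos(te, start=False, forward=False),
        )

    def to_transformed_span(self, span: tuple[int, int]) -> tuple[int, int]:
        """Project an original-text span into transformed coordinates."""
        os_, oe = span
        if not (0 <= os_ <= oe <= len(self.original_text)):
            raise ValueError(
                f"span {span} outside original text of length {len(self.original_text)}"
            )
        return (
            self._map_pos(os_, start=True, forward=True),
            self._map_pos(oe, start=False, forward=True),
        )

    def _map_pos(self, p: int, start: bool, forward: bool) -> int:
        shift = 0  # accumulated (target - source) length difference
        for r in self.replacements:
            s_lo, s_hi = (r.o_start, r.o_end) if forward else (r.t_start, r.t_end)
            t_lo, t_hi = (r.t_start, r.t_end) if forward else (r.o_start, r.o_end)
            if p < s_lo or (p == s_lo and start):
                break
            if (start and s_lo <= p < s_hi) or (not start and s_lo < p <= s_hi):
                return t_lo if start else t_hi
            if p >= s_hi:
                shift += (t_hi - t_lo) - (s_hi - s_lo)
        return p + shift


# ---------------------------------------------------------------------------
# number <-> words

_ONES = (
    "zero one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen sixteen seventeen eighteen nineteen"
).split()
_TENS = "twenty thirty forty fifty sixty seventy eighty ninety".split()


def _int_to_words(n: int) -> str:
    if n < 0:
        return "minus " + _int_to_words(-n)
    if n < 20:
        return _ONES[n]
    if n < 100:
        tens, rem = divmod(n, 10)
        word = _TENS[tens - 2]
        return word if rem == 0 else f"{word} {_ONES[rem]}"
    if n < 1000:
        hundreds, rem = divmod(n, 100)
        word = f"{_ONES[hundreds]} hundred"
        return word if rem == 0 else f"{word} {_int_to_words(rem)}"
    if n < 1_000_000:
        thousands, rem = divmod(n, 1000)
        word = f"{_int_to_words(thousands)} thousand"
        return word if rem == 0 else f"{word} {_int_to_words(rem)}"
    raise ValueError(f"integer {n} too large for word representation")


def number_to_words(token: str) -> str:
    """Spell a numeric token in lowercase English, digits after 'point'."""
    neg = token.startswith("-")
    body = token.lstrip("-")
    if "." in body:
        int_part, frac_part = body.split(".")
    else:
        int_part, frac_part = body, ""
    words = _int_to_words(int(int_part))
    if frac_part:
        words += " point " + " ".join(_ONES[int(d)] for d in frac_part)
    return ("minus " + words) if neg else words


_WORD_VALUES = {w: i for i, w in enumerate(_ONES)}
_WORD_VALUES.update({w: (i + 2) * 10 for i, w in enumerate(_TENS)})


def words_to_number(phrase: str) -> float:
    """Inverse of :func:`number_to_words`."""
    tokens = phrase.split()
    neg = False
    if tokens and tokens[0] == "minus":
        neg = True
        tokens = tokens[1:]
    if "point" in tokens:
        idx = tokens.index("point")
        int_tokens, frac_tokens = tokens[:idx], tokens[idx + 1 :]
    else:
        int_tokens, frac_tokens = tokens, []
    total, current = 0, 0
    for tok in int_tokens:
        if tok == "hundred":
            current = max(current, 1) * 100
        elif tok == "thousand":
            total += max(current, 1) * 1000
            current = 0
        elif tok in _WORD_VALUES:
            current += _WORD_VALUES[tok]
        else:
            raise ValueError(f"cannot parse number word {tok!r}")
    value = float(total + current)
    if frac_tokens:
        digits = []
        for tok in frac_tokens:
            if tok not in _WORD_VALUES or _WORD_VALUES[tok] > 9:
                raise ValueError(f"fractional part must be single digits, got {tok!r}")
            digits.append(str(_WORD_VALUES[tok]))
        value = float(f"{int(total + current)}.{''.join(digits)}")
    return -value if neg else value


# ---------------------------------------------------------------------------
# per-mode token rewrites


def _rewrite_token(token: str, mode: str) -> tuple[str | None, str | None]:
    """Return (rewritten token, warning reason); None rewrite means unchanged."""
    if mode == "original":
        return None, None
    if mode == "replaced_decimal":
        return (token.replace(".", "|"), None) if "." in token else (None, None)
    value = float(token)
    if mode == "consistent_digits":
        if value < 0:
            return None, "negative value not representable in 6-digit format"
        if round(value, 3) >= 1000:
            return None, "value >= 1000 not representable in 6-digit format"
        return f"{value:07.3f}".replace(".", ""), None
    if mode == "scientific":
        return f"{value:.5e}", None
    if mode == "words":
        return number_to_words(token), None
    raise ValueError(f"unknown representation mode {mode!r}; choose from {MODES}")


def transform_text(text: str, mode: str) -> TransformedText:
    """Rewrite every maximal numeric token of ``text`` under ``mode``.

    Non-numeric characters are preserved exactly; each rewrite is recorded
    in the offset map.  ``original`` mode returns the text unchanged with an
    identity map.
    """
    if mode not in MODES:
        raise ValueError(f"unknown representation mode {mode!r}; choose from {MODES}")
    if mode == "original":
        return TransformedText(mode=mode, text=text, original_text=text)

    pieces: list[str] = []
    replacements: list[Replacement] = []
    warnings: list[TransformWarning] = []
    cursor = 0  # position in original
    out_len = 0
    for m in NUMBER_RE.finditer(text):
        o_start, o_end = m.span(1)
        token = m.group(1)
        rewritten, reason = _rewrite_token(token, mode)
        if reason is not None:
            warnings.append(TransformWarning(o_start, o_end, token, reason))
        if rewritten is None or rewritten == token:
            continue
        gap = text[cursor:o_start]
        pieces.append(gap)
        out_len += len(gap)
        pieces.append(rewritten)
        replacements.append(Replacement(out_len, out_len + len(rewritten), o_start, o_end))
        out_len += len(rewritten)
        cursor = o_end
    pieces.append(text[cursor:])
    return TransformedText(
        mode=mode,
        text="".join(pieces),
        original_text=text,
        replacements=tuple(replacements),
        warnings=tuple(warnings),
    )


def invert_value(token: str, mode: str) -> float:
    """Parse a numeric token produced by :func:`transform_text` back to a float."""
    try:
        if mode == "original":
            return float(token)
        if mode == "replaced_decimal":
            return float(token.replace("|", "."))
        if mode == "consistent_digits":
            if len(token) != 6 or not token.isdigit():
                raise ValueError(f"not a 6-digit consistent-digits token: {token!r}")
            return float(f"{token[:3]}.{token[3:]}")
        if mode == "scientific":
            return float(token)
        if mode == "words":
            return words_to_number(token)
    except ValueError as exc:
        raise ValueError(f"cannot invert token {token!r} under mode {mode!r}: {exc}") from None
    raise ValueError(f"unknown representation mode {mode!r}; choose from {MODES}")


def map_span(transformed: TransformedText, span: tuple[int, int]) -> tuple[int, int]:
    """Project a transformed-text span onto the original text."""
    return transformed.to_original_span(span)


def project_annotations(transformed: TransformedText, annotations: Sequence, schema=None):
    """Project standoff annotations (original coordinates) into transformed text.

    Returns new annotations of the same type with start/end in transformed
    coordinates; labels and values are unchanged.
    """
    from dataclasses import replace

    projected = []
    for a in annotations:
        ts, te = transformed.to_transformed_span((a.start, a.end))
        projected.append(replace(a, start=ts, end=te))
    return projected
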