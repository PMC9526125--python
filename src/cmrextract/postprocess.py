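"""From per-token predictions to structured measurements.

Maximal runs of same-labeled tokens become candidate spans; a candidate is
extended over any further significant digits of the same numeric token that
the model missed (digit merging), mapped back from the representation used
at inference onto the original report text, and parsed to a float.  When a
report yields several candidates for one label, the candidate with the
highest mean token score is emitted and the rest are flagged as duplicates.
Finally each value is checked against the physiologic plausibility range of
its measurement type; out-of-range values are flagged, not deleted, so
candidate counts are conserved and the filter is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .numeric import NUMBER_RE, TransformedText
from .schema import Report, Schema

__all__ = [
    "Measurement",
    "merge_digits",
    "consolidate",
    "filter_physiologic",
    "emitted",
    "measurements_to_frame",
]


@dataclass(frozen=True)
class Measurement:
    """One structured extraction from a report."""

    report_id: str
    label: str
    value: float
    span: tuple[int, int]  # character range in the original text
    score: float
    filtered: bool = False
    reason: str | None = None


def merge_digits(
    runs: Sequence[tuple[int, int]], text: str
) -> list[tuple[int, int]]:
    """Extend each character run over the full numeric token it touches.

    A predicted run that covers part of a number (e.g. ``51`` of ``51.01``)
    is extended to the whole maximal numeric token; whitespace or any
    non-numeric character stops the extension, so a run followed by `` ml``
    is unchanged.  Runs already covering a full number are returned as-is
    (the operation is idempotent).
    """
    numbers = [m.span(1) for m in NUMBER_RE.finditer(text)]
    out = []
    for (s, e) in runs:
        ns, ne = s, e
        for (ms, me) in numbers:
            if ms < e and s < me:  # overlap with a numeric token
                ns = min(ns, ms)
                ne = max(ne, me)
        out.append((ns, ne))
    return out


def consolidate(
    labels: Sequence[int],
    scores: np.ndarray | Sequence[float],
    char_offsets: Sequence[tuple[int, int]],
    report: Report,
    schema: Schema,
    transformed: TransformedText | None = None,
) -> list[Measurement]:
    """Turn aligned per-token labels/scores into measurements for one report.

    ``labels`` are label ids in the schema space, aligned 1:1 with
    ``char_offsets`` (character spans in the *transformed* text when
    ``transformed`` is given, else in the original).  ``scores`` is either a
    per-token scalar (the score of the assigned label) or a (T, n_labels)
    array.  Candidates containing no parseable number are dropped with
    reason ``non-numeric``; duplicate labels within the report are resolved
    by highest mean score, losers flagged ``duplicate``.
    """
    labels = list(labels)
    if not (len(labels) == len(char_offsets)):
        raise ValueError("labels and char_offsets must be aligned 1:1")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 2:
        token_scores = scores[np.arange(len(labels)), labels]
    else:
        token_scores = scores
    if len(token_scores) != len(labels):
        raise ValueError("scores must be aligned 1:1 with labels")

    # maximal same-label runs of non-null tokens
    runs: list[tuple[int, int, int]] = []  # (token_start, token_end, label_id)
    i = 0
    while i < len(labels):
        if labels[i] == 0:
            i += 1
            continue
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((i, j, labels[i]))
        i = j

    candidates: list[Measurement] = []
    for (ti, tj, lab_id) in runs:
        span = (char_offsets[ti][0], char_offsets[tj - 1][1])
        if transformed is not None:
            span = transformed.to_original_span(span)
        (span,) = merge_digits([span], report.text)
        snippet = report.text[span[0] : span[1]]
        m = NUMBER_RE.search(snippet)
        mean_score = float(np.mean(token_scores[ti:tj]))
        label = schema.id_to_label(lab_id)
        if m is None:
            candidates.append(
                Measurement(report.report_id, label, float("nan"), span, mean_score,
                            filtered=True, reason="non-numeric")
            )
            continue
        value = float(m.group(1))
        candidates.append(Measurement(report.report_id, label, value, span, mean_score))

    # per-label deduplication by highest mean score (stable for ties)
    best: dict[str, int] = {}
    for idx, cand in enumerate(candidates):
        if cand.filtered:
            continue
        cur = best.get(cand.label)
        if cur is None or cand.score > candidates[cur].score:
            best[cand.label] = idx
    out = []
    for idx, cand in enumerate(candidates):
        if not cand.filtered and best.get(cand.label) != idx:
            cand = replace(cand, filtered=True, reason="duplicate")
        out.append(cand)
    return out


def filter_physiologic(
    measurements: Sequence[Measurement], schema: Schema
) -> list[Measurement]:
    """Flag values outside the physiologic range of their measurement type.

    Nothing is deleted: out-of-range measurements get ``filtered=True`` with
    reason ``out-of-range``; already-flagged measurements pass through, so
    the operation is idempotent and order-independent.
    """
    out = []
    for m in measurements:
        if m.label not in schema:
            raise KeyError(f"measurement label {m.label!r} not in schema")
        if m.filtered:
            out.append(m)
            continue
        lo, hi = schema[m.label].physiologic_range
        if m.value < lo or m.value > hi:
            m = replace(m, filtered=True, reason="out-of-range")
        out.append(m)
    return out


def emitted(measurements: Sequence[Measurement]) -> list[Measurement]:
    """The measurements actually reported: unflagged candidates."""
    return [m for m in measurements if not m.filtered]


def measurements_to_frame(measurements: Sequence[Measurement]) -> pd.DataFrame:
    """Flat table: report id, label, value, span, score, filtered, reason."""
    return pd.DataFrame(
        [
            {
                "report_id": m.report_id,
                "label": m.label,
                "value": m.value,
                "start": m.span[0],
                "end": m.span[1],
                "score": m.score,
                "filtered": m.filtered,
                "reason": m.reason,
            }
            for m in measurements
        ],
        columns=["report_id", "label", "value", "start", "end", "score", "filtered", "reason"],
    )
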