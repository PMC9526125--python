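"""Align character-span labels to subword tokens and cut model windows.

A report is tokenized once; every token whose character span overlaps a gold
annotation receives that annotation's label id (all pieces of an annotated
number are labeled, not just the first), all other tokens the null id 0.
The labeled token sequence is then cut into consecutive non-overlapping
windows of at most ``max_len`` (default 128) tokens.  A window boundary is
never allowed to split a maximal same-label run: when it would, it is moved
back to the end of the last null-labeled stretch before the run, so no gold
annotation is divided across windows.

At inference time there are no gold runs to protect, so windows are cut at
exactly ``max_len`` with a configurable overlap (default 16 tokens) to limit
boundary effects; overlapping predictions are resolved downstream by
keeping the first window's scores for duplicated positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .schema import Report, Schema, SpanAnnotation
from .tokenizer import Encoding, SubwordTokenizer

__all__ = ["LabeledWindow", "tokenize_with_labels", "window", "windows_for_inference"]

MAX_WINDOW = 128


@dataclass
class LabeledWindow:
    """Up to ``max_len`` subword tokens with aligned labels and offsets."""

    report_id: str
    tokens: list[int]
    char_offsets: list[tuple[int, int]]
    labels: list[int]
    window_index: int
    pieces: list[str] | None = None

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.char_offsets) == len(self.labels)):
            raise ValueError("tokens, char_offsets and labels must be aligned 1:1")

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_with_labels(
    report: Report,
    annotations: Sequence[SpanAnnotation],
    tokenizer: SubwordTokenizer,
    schema: Schema,
    text: str | None = None,
) -> tuple[Encoding, list[int]]:
    """Tokenize ``report`` and assign a label id to every token.

    ``text`` overrides ``report.text`` when annotations live in a transformed
    representation of the report.  Assignment is overlap-based: any overlap
    between a token span and an annotation span labels the token.
    """
    src = report.text if text is None else text
    enc = tokenizer.encode(src)
    labels = [0] * len(enc)
    spans = [(a.start, a.end, schema.label_to_id(a.label)) for a in annotations]
    for i, (ts, te) in enumerate(enc.offsets):
        for (s, e, lab) in spans:
            if ts < e and s < te:
                labels[i] = lab
                break
    return enc, labels


def _run_start(labels: Sequence[int], pos: int) -> int:
    """Start index of the maximal same-label run containing ``pos``."""
    lab = labels[pos]
    start = pos
    while start > 0 and labels[start - 1] == lab:
        start -= 1
    return start


def window(
    report_id: str,
    encoding: Encoding,
    labels: Sequence[int],
    max_len: int = MAX_WINDOW,
) -> list[LabeledWindow]:
    """Cut a labeled token sequence into non-overlapping windows.

    Boundaries shift earlier rather than split a non-null run; flattening the
    windows reproduces the input sequence exactly.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    n = len(encoding)
    out: list[LabeledWindow] = []
    start = 0
    idx = 0
    while start < n:
        end = min(start + max_len, n)
        if end < n and labels[end] != 0 and labels[end] == labels[end - 1]:
            run_start = _run_start(labels, end)
            if run_start <= start:
                raise ValueError(
                    f"report {report_id!r}: annotation run at token {run_start} "
                    f"is longer than the window size {max_len}"
                )
            end = run_start
        out.append(
            LabeledWindow(
                report_id=report_id,
                tokens=list(encoding.ids[start:end]),
                char_offsets=list(encoding.offsets[start:end]),
                labels=list(labels[start:end]),
                window_index=idx,
                pieces=list(encoding.pieces[start:end]),
            )
        )
        start = end
        idx += 1
    return out


def windows_for_inference(
    report_id: str,
    encoding: Encoding,
    max_len: int = MAX_WINDOW,
    overlap: int = 16,
) -> list[LabeledWindow]:
    """Cut unlabeled text into fixed-size windows with overlap.

    Labels are filled with 0 placeholders; ``window_index`` records order so
    duplicated positions can be resolved (first window wins).
    """
    if not 0 <= overlap < max_len:
        raise ValueError("overlap must satisfy 0 <= overlap < max_len")
    n = len(encoding)
    out = []
    start = 0
    idx = 0
    step = max_len - overlap
    while start < n or idx == 0:
        end = min(start + max_len, n)
        out.append(
            LabeledWindow(
                report_id=report_id,
                tokens=list(encoding.ids[start:end]),
                char_offsets=list(encoding.offsets[start:end]),
                labels=[0] * (end - start),
                window_index=idx,
                pieces=list(encoding.pieces[start:end]),
            )
        )
        if end >= n:
            break
        start += step
        idx += 1
    return out
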