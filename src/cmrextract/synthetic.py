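"""Seeded synthetic CMR-like report corpus with gold standoff annotations.

Real CMR reports cannot be shared, so every downstream stage is exercised
on generated text that reproduces the variability that makes extraction
hard: measurement ordering varies per report, each measurement appears
under several surface names (abbreviation, full phrase, mixed), units may
be present or absent, the name-value positional relationship differs
between narrative and list styles, values mix integers with 1- and 2-decimal
numbers, a report carries anywhere from 1 to all 21 measurements, and
reports contain distractor numbers (dates, heart rates, slice thickness,
sequence parameters) that must be labeled null.

Three report styles are mixed:

* ``inline``  — narrative sentences: "The RVEF is 56 %."
* ``colon``   — colon lists: "RVEDV: 147.54 ml"
* ``tabular`` — dense value lines with units omitted: "LVEF 55"

Generation is bit-exactly reproducible for a fixed (config, seed): a single
``numpy`` generator drives every choice in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .schema import Report, Schema, SpanAnnotation

__all__ = ["CorpusConfig", "generate_corpus", "render_report"]

STYLES = ("inline", "colon", "tabular")

_INLINE_TEMPLATES = (
    "The {alias} is {value}{unit}.",
    "{alias} measured at {value}{unit}.",
    "There is an estimated {alias} of {value}{unit}.",
    "Calculated {alias} was {value}{unit}.",
)

_HEADERS = ("CARDIAC MRI REPORT.", "CMR FINDINGS:", "Cardiac MRI study.", "")
_FOOTERS = (
    "Overall image quality was adequate.",
    "No significant artifact.",
    "Findings discussed with the referring team.",
    "",
)


@dataclass
class CorpusConfig:
    """Knobs of the generator; defaults define the standard study conditions.

    ``inclusion_probs`` maps measurement label to the probability that a
    report contains it (None: 0.5 for every label, so reports average about
    half of the schema; a report drawing no measurement is assigned one at
    random, keeping the guaranteed 1..21 range).  ``out_of_range_rate`` is
    the fraction of values sampled just outside the physiologic bounds
    (default 0: reports carry plausible values; raise it to exercise the
    physiologic filter).  ``distractor_rate`` is the expected count of
    non-measurement numbers per report (Poisson).
    """

    n_reports: int = 100
    seed: int = 0
    inclusion_probs: dict[str, float] | None = None
    style_weights: dict[str, float] = field(
        default_factory=lambda: {"inline": 1.0, "colon": 1.0, "tabular": 1.0}
    )
    out_of_range_rate: float = 0.0
    distractor_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not 0.0 <= self.out_of_range_rate <= 1.0:
            raise ValueError("out_of_range_rate must be in [0, 1]")
        if self.inclusion_probs is not None:
            for k, v in self.inclusion_probs.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"inclusion probability for {k!r} must be in [0, 1]")


def _sample_value(mt, rng: np.random.Generator, out_of_range: bool) -> str:
    """Sample and format one value; the formatted string is the ground truth."""
    lo, hi = mt.physiologic_range
    width = hi - lo
    ndp = int(rng.choice([0, 1, 2], p=[0.45, 0.3, 0.25]))
    step = 10.0 ** (-ndp)
    if out_of_range:
        delta = float(rng.uniform(0.02, 0.25)) * width
        below = bool(rng.random() < 0.5) and lo - delta - step > 0
        v = lo - delta if below else hi + delta
        formatted = f"{v:.{ndp}f}"
        v = float(formatted)
        if lo <= v <= hi:  # rounding pulled it back inside: push one step out
            v = lo - step if below else hi + step
            formatted = f"{v:.{ndp}f}"
    else:
        v = float(rng.uniform(lo, hi))
        formatted = f"{v:.{ndp}f}"
        v = float(formatted)
        if not lo <= v <= hi:  # rounding crossed the boundary
            v = min(max(v, lo), hi)
            formatted = f"{v:.{ndp}f}"
    return formatted


def _distractor(rng: np.random.Generator) -> str:
    kind = rng.integers(0, 6)
    if kind == 0:
        return f"Heart rate {rng.integers(48, 110)} bpm."
    if kind == 1:
        return f"Slice thickness {rng.integers(6, 11)} mm."
    if kind == 2:
        d = date(2008, 1, 1) + timedelta(days=int(rng.integers(0, 4000)))
        return f"Study performed on {d.month:02d}/{d.day:02d}/{d.year}."
    if kind == 3:
        return f"TR {rng.uniform(2.5, 4.5):.1f} ms."
    if kind == 4:
        return f"Series {rng.integers(1, 13)} reviewed."
    return f"Patient age {rng.integers(25, 90)} years."


def render_report(
    measurements: dict[str, str | float],
    style: str,
    rng: np.random.Generator,
    schema: Schema,
    distractor_rate: float = 0.0,
) -> tuple[str, list[tuple[int, int, str, float]]]:
    """Render a measurement map into report text with exact value spans.

    ``measurements`` maps schema label to a value (float, or an already
    formatted string whose text is used verbatim).  Returns the text and a
    list of (start, end, label, value) gold spans; the substring at each
    span parses exactly to its value.
    """
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}; choose from {STYLES}")
    if not measurements:
        raise ValueError("a report must contain at least one measurement")

    labels = list(measurements)
    rng.shuffle(labels)

    # (text, label, value_str, offset of value within text)
    segments: list[tuple[str, str | None, str | None, int]] = []
    for label in labels:
        mt = schema[label]
        raw = measurements[label]
        value_str = raw if isinstance(raw, str) else f"{raw:g}"
        alias = str(rng.choice(mt.aliases))
        if style == "colon":
            with_unit = mt.unit and rng.random() < 0.7
            prefix = f"{alias}: "
            line = prefix + value_str + (f" {mt.unit}" if with_unit else "")
            segments.append((line, label, value_str, len(prefix)))
        elif style == "tabular":
            prefix = f"{alias} "
            segments.append((prefix + value_str, label, value_str, len(prefix)))
        else:
            template = str(rng.choice(_INLINE_TEMPLATES))
            with_unit = mt.unit and rng.random() < 0.7
            unit_part = f" {mt.unit}" if with_unit else ""
            before, after = template.split("{value}")
            prefix = before.format(alias=alias, unit=unit_part)
            suffix = after.format(alias=alias, unit=unit_part)
            segments.append((prefix + value_str + suffix, label, value_str, len(prefix)))

    n_distract = int(rng.poisson(distractor_rate))
    for _ in range(n_distract):
        pos = int(rng.integers(0, len(segments) + 1))
        segments.insert(pos, (_distractor(rng), None, None, 0))

    header = str(rng.choice(_HEADERS))
    footer = str(rng.choice(_FOOTERS))
    sep = " " if style == "inline" else "\n"
    parts = ([header] if header else []) + [s[0] for s in segments] + ([footer] if footer else [])
    text = sep.join(parts)

    spans: list[tuple[int, int, str, float]] = []
    cursor = 0
    if header:
        cursor = len(header) + len(sep)
    for seg_text, label, value_str, offset in segments:
        if label is not None:
            start = cursor + offset
            spans.append((start, start + len(value_str), label, float(value_str)))
        cursor += len(seg_text) + len(sep)
    return text, spans


def generate_corpus(
    config: CorpusConfig, schema: Schema
) -> tuple[list[Report], list[SpanAnnotation]]:
    """Generate ``config.n_reports`` synthetic reports with gold annotations."""
    probs = (
        {mt.label: 0.5 for mt in schema.measurement_types}
        if config.inclusion_probs is None
        else {mt.label: config.inclusion_probs.get(mt.label, 0.0) for mt in schema.measurement_types}
    )
    if all(p == 0.0 for p in probs.values()):
        raise ValueError("all inclusion probabilities are zero; reports would be empty")

    style_names = [s for s in STYLES if config.style_weights.get(s, 0.0) > 0]
    weights = np.array([config.style_weights[s] for s in style_names], dtype=float)
    if not style_names:
        raise ValueError("all style weights are zero")
    weights = weights / weights.sum()

    rng = np.random.default_rng(config.seed)
    reports: list[Report] = []
    annotations: list[SpanAnnotation] = []
    width = len(str(config.n_reports))
    for i in range(config.n_reports):
        included = [lab for lab, p in probs.items() if rng.random() < p]
        if not included:
            candidates = [lab for lab, p in probs.items() if p > 0]
            included = [candidates[int(rng.integers(0, len(candidates)))]]
        values = {
            lab: _sample_value(schema[lab], rng, bool(rng.random() < config.out_of_range_rate))
            for lab in included
        }
        style = style_names[int(rng.choice(len(style_names), p=weights))]
        text, spans = render_report(
            values, style, rng, schema, distractor_rate=config.distractor_rate
        )
        report_id = f"r{i:0{width}d}"
        report_date = date(2010, 1, 1) + timedelta(days=int(rng.integers(0, 3652)))
        reports.append(
            Report(report_id=report_id, text=text, person_id=f"p{i:0{width}d}",
                   report_date=report_date)
        )
        for (start, end, label, value) in spans:
            annotations.append(
                SpanAnnotation(report_id=report_id, start=start, end=end, label=label, value=value)
            )
    return reports, annotations
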