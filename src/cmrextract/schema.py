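"""Measurement schema, report/annotation containers and standoff I/O.

The extraction task is defined by a *schema*: an ordered list of measurement
types (left/right ventricular volumes, ejection fractions, dimensions, ...),
each with a set of surface aliases used in report text and a physiologic
plausibility range in its canonical unit.  The packaged default schema holds
the 21 quantitative measurements reported in clinical cardiac-MRI (CMR)
documents, giving a 22-way token label space once the null ("everything
else") label is included.

Annotations are stored standoff: a label plus 0-based half-open character
offsets into the unmodified report text, together with the numeric value the
span parses to.  Files are JSON-lines, one record per annotation or report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "MeasurementType",
    "Schema",
    "Report",
    "SpanAnnotation",
    "SchemaError",
    "AnnotationError",
    "load_schema",
    "default_schema",
    "read_reports",
    "write_reports",
    "read_annotations",
    "write_annotations",
    "interannotator_agreement",
]


class SchemaError(ValueError):
    """Raised when a schema document fails validation."""


class AnnotationError(ValueError):
    """Raised when an annotation is inconsistent with its report."""


@dataclass(frozen=True)
class MeasurementType:
    """One extractable quantity: key, surface forms and plausibility range."""

    label: str
    display_name: str
    aliases: tuple[str, ...]
    unit: str
    physiologic_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.label:
            raise SchemaError("measurement type with empty label")
        if not self.aliases:
            raise SchemaError(f"measurement {self.label!r}: aliases must be non-empty")
        lo, hi = self.physiologic_range
        if not lo < hi:
            raise SchemaError(
                f"measurement {self.label!r}: physiologic range ({lo}, {hi}) "
                "must satisfy lower < upper"
            )


@dataclass(frozen=True)
class Schema:
    """Ordered measurement types plus the reserved null label.

    Label ids: the null label is id 0; measurement labels are 1..n in schema
    order.  ``label_space_size`` is therefore ``n + 1`` (22 for the default
    CMR schema).
    """

    measurement_types: tuple[MeasurementType, ...]
    null_label: str = "0"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mt in self.measurement_types:
            if mt.label in seen:
                raise SchemaError(f"duplicate measurement label {mt.label!r}")
            if mt.label == self.null_label:
                raise SchemaError(
                    f"measurement label {mt.label!r} collides with the null label"
                )
            seen.add(mt.label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(mt.label for mt in self.measurement_types)

    @property
    def label_space_size(self) -> int:
        return len(self.measurement_types) + 1

    def label_to_id(self, label: str) -> int:
        """Map a schema key to its integer id (null label -> 0)."""
        if label == self.null_label:
            return 0
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise SchemaError(f"unknown label {label!r}") from None

    def id_to_label(self, label_id: int) -> str:
        if label_id == 0:
            return self.null_label
        if not 1 <= label_id <= len(self.measurement_types):
            raise SchemaError(f"label id {label_id} outside schema")
        return self.measurement_types[label_id - 1].label

    def __getitem__(self, label: str) -> MeasurementType:
        for mt in self.measurement_types:
            if mt.label == label:
                return mt
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(mt.label == label for mt in self.measurement_types)

    def alias_lexicon(self) -> dict[str, list[str]]:
        return {mt.label: list(mt.aliases) for mt in self.measurement_types}


@dataclass(frozen=True)
class Report:
    """A free-text diagnostic report."""

    report_id: str
    text: str
    person_id: str | None = None
    report_date: date | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"report {self.report_id!r}: text must be non-empty")


@dataclass(frozen=True)
class SpanAnnotation:
    """A labeled numeric span: 0-based half-open offsets into report text."""

    report_id: str
    start: int
    end: int
    label: str
    value: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"report {self.report_id!r}: invalid span ({self.start}, {self.end})"
            )

    def validate_against(self, report: Report) -> None:
        """Check offsets and numeric consistency against the report text."""
        if self.end > len(report.text):
            raise AnnotationError(
                f"report {self.report_id!r}: span ({self.start}, {self.end}) "
                f"beyond text length {len(report.text)}"
            )
        snippet = report.text[self.start : self.end]
        try:
            parsed = float(snippet)
        except ValueError:
            raise AnnotationError(
                f"report {self.report_id!r}: span ({self.start}, {self.end}) "
                f"text {snippet!r} is not numeric"
            ) from None
        if abs(parsed - self.value) > 1e-9:
            raise AnnotationError(
                f"report {self.report_id!r}: span text {snippet!r} parses to "
                f"{parsed}, not the recorded value {self.value}"
            )


def _parse_schema_document(doc: Mapping, source: str) -> Schema:
    try:
        entries = doc["measurement_types"]
    except (KeyError, TypeError):
        raise SchemaError(f"{source}: missing 'measurement_types'") from None
    types = []
    for entry in entries:
        try:
            types.append(
                MeasurementType(
                    label=entry["label"],
                    display_name=entry.get("display_name", entry["label"]),
                    aliases=tuple(entry["aliases"]),
                    unit=entry.get("unit", ""),
                    physiologic_range=tuple(float(x) for x in entry["physiologic_range"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(
                f"{source}: entry {entry.get('label', '?')!r} missing field {exc}"
            ) from None
    return Schema(tuple(types), null_label=doc.get("null_label", "0"))


def load_schema(path: str | Path) -> Schema:
    """Load and validate a JSON or YAML schema document."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    return _parse_schema_document(doc, str(path))


def default_schema() -> Schema:
    """The packaged 21-measurement CMR schema (22-way label space)."""
    text = resources.files("cmrextract.data").joinpath("cmr_schema.json").read_text()
    return _parse_schema_document(json.loads(text), "packaged cmr_schema.json")


# ---------------------------------------------------------------------------
# JSON-lines I/O


def write_reports(reports: Iterable[Report], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reports:
            rec = {"report_id": r.report_id, "text": r.text}
            if r.person_id is not None:
                rec["person_id"] = r.person_id
            if r.report_date is not None:
                rec["report_date"] = r.report_date.isoformat()
            fh.write(json.dumps(rec) + "\n")


def read_reports(path: str | Path) -> list[Report]:
    reports = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            rd = rec.get("report_date")
            reports.append(
                Report(
                    report_id=rec["report_id"],
                    text=rec["text"],
                    person_id=rec.get("person_id"),
                    report_date=date.fromisoformat(rd) if rd else None,
                )
            )
    ids = [r.report_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate report ids")
    return reports


def write_annotations(annotations: Iterable[SpanAnnotation], path: str | Path) -> None:
    """Write standoff annotations as JSON-lines, sorted by (report_id, start)."""
    ordered = sorted(annotations, key=lambda a: (a.report_id, a.start))
    with open(path, "w") as fh:
        for a in ordered:
            fh.write(
                json.dumps(
                    {
                        "report_id": a.report_id,
                        "start": a.start,
                        "end": a.end,
                        "label": a.label,
                        "value": a.value,
                    }
                )
                + "\n"
            )


def read_annotations(
    path: str | Path,
    reports: Sequence[Report] | None = None,
    schema: Schema | None = None,
) -> list[SpanAnnotation]:
    """Read standoff annotations; optionally validate against reports/schema."""
    annotations = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            annotations.append(
                SpanAnnotation(
                    report_id=rec["report_id"],
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    label=rec["label"],
                    value=float(rec["value"]),
                )
            )
    if schema is not None:
        for a in annotations:
            if a.label not in schema:
                raise AnnotationError(
                    f"report {a.report_id!r} offset {a.start}: unknown label {a.label!r}"
                )
    if reports is not None:
        by_id = {r.report_id: r for r in reports}
        for a in annotations:
            if a.report_id not in by_id:
                raise AnnotationError(f"annotation references unknown report {a.report_id!r}")
            a.validate_against(by_id[a.report_id])
    return annotations


# ---------------------------------------------------------------------------
# Interannotator agreement


def _spans_overlap(a: SpanAnnotation, b: SpanAnnotation) -> bool:
    return a.start < b.end and b.start < a.end


def _is_match(a: SpanAnnotation, b: SpanAnnotation) -> bool:
    return (
        a.report_id == b.report_id
        and a.label == b.label
        and _spans_overlap(a, b)
        and abs(a.value - b.value) <= 1e-9
    )


@dataclass
class AgreementResult:
    overall: float
    per_label: dict[str, float] = field(default_factory=dict)
    matched: int = 0
    union: int = 0


def interannotator_agreement(
    a: Sequence[SpanAnnotation], b: Sequence[SpanAnnotation]
) -> AgreementResult:
    """Proportion of matched extractions between two annotators.

    A match is an identical extraction: same report, same label, overlapping
    spans, equal parsed value.  The statistic is matched / union where
    union = |a| + |b| - matched (each matched pair counts once).  An empty
    union — neither annotator extracted anything — is defined as agreement 1.
    Matching is greedy one-to-one in (report_id, start) order; gold spans do
    not overlap within one annotator, so the greedy pairing is unambiguous.
    """

    def proportion(sub_a: list[SpanAnnotation], sub_b: list[SpanAnnotation]) -> tuple[int, int]:
        used: set[int] = set()
        matched = 0
        for ann in sorted(sub_a, key=lambda x: (x.report_id, x.start)):
            for j, other in enumerate(sub_b):
                if j not in used and _is_match(ann, other):
                    used.add(j)
                    matched += 1
                    break
        union = len(sub_a) + len(sub_b) - matched
        return matched, union

    matched, union = proportion(list(a), list(b))
    labels = sorted({x.label for x in a} | {x.label for x in b})
    per_label = {}
    for lab in labels:
        m, u = proportion(
            [x for x in a if x.label == lab], [x for x in b if x.label == lab]
        )
        per_label[lab] = m / u if u else 1.0
    return AgreementResult(
        overall=matched / union if union else 1.0,
        per_label=per_label,
        matched=matched,
        union=union,
    )
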