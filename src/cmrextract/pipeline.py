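"""End-to-end orchestration: corpus -> representation -> training ->
prediction -> consolidation -> evaluation / measurement table.

``MeasurementExtractor`` is the high-level scikit-learn style estimator:
``fit(reports, annotations)`` handles representation transform, tokenizer
fitting, label alignment, windowing and classifier training;
``predict(reports)`` returns consolidated, physiologically filtered
measurements.  ``run_end_to_end`` wraps a full seeded experiment with a
manifest, and ``grid_run`` sweeps encoder profiles x numerical
representations, mirroring the usual ablation table layout.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import __version__
from .evaluation import EvalResult, bootstrap_ci, evaluate, learning_curve
from .model import TokenClassifier, decode_argmax, decode_threshold  # noqa: F401 (re-exported surface)
from .numeric import MODES, project_annotations, transform_text
from .postprocess import (
    Measurement,
    consolidate,
    emitted,
    filter_physiologic,
    measurements_to_frame,
)
from .schema import Report, Schema, SpanAnnotation, default_schema
from .synthetic import CorpusConfig, generate_corpus
from .tokenizer import SubwordTokenizer
from .windows import LabeledWindow, tokenize_with_labels, window, windows_for_inference

__all__ = ["MeasurementExtractor", "RunConfig", "run_end_to_end", "grid_run", "learning_curve_run"]


class MeasurementExtractor(BaseEstimator):
    """Train and apply the full report -> measurements workflow.

    Parameters
    ----------
    schema:
        Measurement schema; None uses the packaged 21-measurement default.
    representation:
        Numerical representation applied before tokenization (one of
        ``original``, ``replaced_decimal``, ``consistent_digits``,
        ``scientific``, ``words``).
    encoder_profile, learning_rate, batch_size, max_epochs, seed,
    decode_thr, d_model, n_heads, n_layers, d_ff, max_len:
        Forwarded to :class:`~cmrextract.model.TokenClassifier`.
    dev_fraction:
        Fraction of training reports held out for per-epoch selection of
        the best macro-F1 epoch (0 keeps the final epoch's weights).
    overlap:
        Token overlap between inference windows.
    """

    def __init__(
        self,
        schema: Schema | None = None,
        representation: str = "original",
        encoder_profile: str = "tiny_scratch",
        learning_rate: float = 2e-3,
        batch_size: int = 8,
        max_epochs: int = 60,
        seed: int = 0,
        decode_thr: float = 0.5,
        d_model: int = 64,
        n_heads: int = 4,
        n_layers: int = 2,
        d_ff: int = 128,
        max_len: int = 128,
        dev_fraction: float = 0.15,
        overlap: int = 16,
        verbose: bool = False,
    ):
        self.schema = schema
        self.representation = representation
        self.encoder_profile = encoder_profile
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.seed = seed
        self.decode_thr = decode_thr
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.max_len = max_len
        self.dev_fraction = dev_fraction
        self.overlap = overlap
        self.verbose = verbose

    # -- helpers ------------------------------------------------------------

    def _labeled_windows(
        self,
        reports: Sequence[Report],
        annotations: Sequence[SpanAnnotation],
        tokenizer: SubwordTokenizer,
        schema: Schema,
    ) -> list[LabeledWindow]:
        by_report: dict[str, list[SpanAnnotation]] = {}
        for a in annotations:
            by_report.setdefault(a.report_id, []).append(a)
        out: list[LabeledWindow] = []
        for r in reports:
            tt = transform_text(r.text, self.representation)
            anns = project_annotations(tt, by_report.get(r.report_id, []))
            enc, labels = tokenize_with_labels(r, anns, tokenizer, schema, text=tt.text)
            out.extend(window(r.report_id, enc, labels, max_len=self.max_len))
        return out

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        reports: Sequence[Report],
        annotations: Sequence[SpanAnnotation],
        dev: tuple[Sequence[Report], Sequence[SpanAnnotation]] | None = None,
    ) -> "MeasurementExtractor":
        """Fit tokenizer and token classifier on annotated reports.

        ``dev`` supplies an explicit selection split; otherwise
        ``dev_fraction`` of the training reports (deterministically chosen)
        is held out for epoch selection.
        """
        if self.representation not in MODES:
            raise ValueError(f"unknown representation {self.representation!r}")
        schema = self.schema or default_schema()
        reports = list(reports)
        if not reports:
            raise ValueError("empty training set")

        train_reports = reports
        if dev is None and self.dev_fraction > 0 and len(reports) >= 10:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(reports))
            n_dev = max(1, int(round(self.dev_fraction * len(reports))))
            dev_ids = {reports[i].report_id for i in order[:n_dev]}
            train_reports = [r for r in reports if r.report_id not in dev_ids]
            dev_reports = [r for r in reports if r.report_id in dev_ids]
            dev = (dev_reports, [a for a in annotations if a.report_id in dev_ids])

        texts = [transform_text(r.text, self.representation).text for r in train_reports]
        tokenizer = SubwordTokenizer().fit(texts)
        train_windows = self._labeled_windows(train_reports, annotations, tokenizer, schema)
        dev_windows = (
            self._labeled_windows(dev[0], dev[1], tokenizer, schema) if dev else None
        )
        clf = TokenClassifier(
            n_labels=schema.label_space_size,
            vocab_size=tokenizer.vocab_size_,
            encoder_profile=self.encoder_profile,
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            d_ff=self.d_ff,
            max_len=self.max_len,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=self.seed,
            decode_thr=self.decode_thr,
            verbose=self.verbose,
        )
        clf.fit(train_windows, dev_windows=dev_windows)
        self.schema_ = schema
        self.tokenizer_ = tokenizer
        self.classifier_ = clf
        return self

    # -- inference ----------------------------------------------------------

    def _stitched_scores(self, report: Report):
        """Per-token scores over the full report, first window winning overlaps."""
        tt = transform_text(report.text, self.representation)
        enc = self.tokenizer_.encode(tt.text)
        wins = windows_for_inference(
            report.report_id, enc, max_len=self.max_len, overlap=self.overlap
        )
        L = self.classifier_.n_labels
        scores = np.zeros((len(enc), L))
        filled = np.zeros(len(enc), dtype=bool)
        step = self.max_len - self.overlap
        for w in wins:
            if len(w) == 0:
                continue
            ws = self.classifier_.predict_scores(w)
            start = w.window_index * step
            for j in range(len(w)):
                pos = start + j
                if not filled[pos]:
                    scores[pos] = ws[j]
                    filled[pos] = True
        return tt, enc, scores

    def predict(
        self, reports: Sequence[Report], decode: str = "argmax"
    ) -> list[Measurement]:
        """Structured measurements for each report (flagged ones included)."""
        if not hasattr(self, "classifier_"):
            raise RuntimeError("extractor is not fitted")
        out: list[Measurement] = []
        for r in reports:
            tt, enc, scores = self._stitched_scores(r)
            if decode == "argmax":
                labels = decode_argmax(scores)
            elif decode == "threshold":
                labels = decode_threshold(scores, self.classifier_.decode_thr)
            else:
                raise ValueError(f"unknown decode mode {decode!r}")
            ms = consolidate(labels, scores, enc.offsets, r, self.schema_, transformed=tt)
            out.extend(filter_physiologic(ms, self.schema_))
        return out

    def predict_frame(self, reports: Sequence[Report], decode: str = "argmax") -> pd.DataFrame:
        return measurements_to_frame(self.predict(reports, decode=decode))

    def evaluate_on(
        self,
        reports: Sequence[Report],
        annotations: Sequence[SpanAnnotation],
        bootstrap: int = 0,
        seed: int = 0,
    ) -> EvalResult:
        """Token-level evaluation with threshold decoding on gold labels."""
        by_report: dict[str, list[SpanAnnotation]] = {}
        for a in annotations:
            by_report.setdefault(a.report_id, []).append(a)
        pred_by_report: dict[str, np.ndarray] = {}
        gold_by_report: dict[str, np.ndarray] = {}
        for r in reports:
            tt, enc, scores = self._stitched_scores(r)
            anns = project_annotations(tt, by_report.get(r.report_id, []))
            _, gold = tokenize_with_labels(r, anns, self.tokenizer_, self.schema_, text=tt.text)
            pred_by_report[r.report_id] = decode_threshold(scores, self.classifier_.decode_thr)
            gold_by_report[r.report_id] = np.asarray(gold)
        pred = np.concatenate([pred_by_report[r.report_id] for r in reports])
        gold = np.concatenate([gold_by_report[r.report_id] for r in reports])
        res = evaluate(pred, gold, n_labels=self.schema_.label_space_size)
        if bootstrap:
            res.ci = bootstrap_ci(
                pred_by_report, gold_by_report,
                n_labels=self.schema_.label_space_size, B=bootstrap, seed=seed,
            )
        return res


# ---------------------------------------------------------------------------
# experiment orchestration


@dataclass
class RunConfig:
    """One end-to-end seeded experiment on synthetic data."""

    out_dir: str
    seed: int = 0
    n_train: int = 200
    n_test: int = 100
    representation: str = "original"
    encoder_profile: str = "tiny_scratch"
    learning_rate: float = 2e-3
    batch_size: int = 8
    max_epochs: int = 60
    decode_threshold: float = 0.5
    select_on_test: bool = False
    dev_fraction: float = 0.15
    out_of_range_rate: float = 0.0
    distractor_rate: float = 2.0
    bootstrap: int = 0
    schema_path: str | None = None
    extractor_overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _corpora(config: RunConfig, schema: Schema):
    train = generate_corpus(
        CorpusConfig(
            n_reports=config.n_train,
            seed=config.seed,
            out_of_range_rate=config.out_of_range_rate,
            distractor_rate=config.distractor_rate,
        ),
        schema,
    )
    test = generate_corpus(
        CorpusConfig(
            n_reports=config.n_test,
            seed=config.seed + 1_000_003,
            out_of_range_rate=config.out_of_range_rate,
            distractor_rate=config.distractor_rate,
        ),
        schema,
    )
    return train, test


def run_end_to_end(config: RunConfig) -> dict:
    """Generate data, train, evaluate, extract; write a reproducible run dir.

    Writes ``manifest.json`` (config + seeds + versions + config hash),
    ``metrics.json``, ``history.csv`` (per-epoch), and
    ``measurements.csv`` (argmax-decoded structured extractions on the test
    reports).  Returns the metrics dict.
    """
    from .schema import load_schema

    schema = load_schema(config.schema_path) if config.schema_path else default_schema()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (train_reports, train_anns), (test_reports, test_anns) = _corpora(config, schema)
    extractor = MeasurementExtractor(
        schema=schema,
        representation=config.representation,
        encoder_profile=config.encoder_profile,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        seed=config.seed,
        decode_thr=config.decode_threshold,
        dev_fraction=0.0 if config.select_on_test else config.dev_fraction,
        **config.extractor_overrides,
    )
    dev = (test_reports, test_anns) if config.select_on_test else None
    extractor.fit(train_reports, train_anns, dev=dev)

    res = extractor.evaluate_on(
        test_reports, test_anns, bootstrap=config.bootstrap, seed=config.seed
    )
    frame = extractor.predict_frame(test_reports, decode="argmax")
    frame.to_csv(out / "measurements.csv", index=False)
    pd.DataFrame(extractor.classifier_.history_).to_csv(out / "history.csv", index=False)

    metrics = {
        "macro_f1": res.macro_f1,
        "best_epoch": extractor.classifier_.best_epoch_,
        "n_train_reports": config.n_train,
        "n_test_reports": config.n_test,
        "n_measurements_emitted": int((~frame["filtered"]).sum()),
        "n_measurements_flagged": int(frame["filtered"].sum()),
    }
    if res.ci is not None:
        metrics["macro_f1_ci"] = list(res.ci)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "versions": {
            "cmrextract": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return metrics


def grid_run(
    config: RunConfig,
    profiles: Sequence[str],
    representations: Sequence[str],
) -> pd.DataFrame:
    """Sweep encoder profiles x numerical representations.

    One row per (profile, representation) with the maximum-over-epochs
    macro-F1; a failing cell records its error and the grid continues.
    """
    from dataclasses import replace as dc_replace

    if not profiles or not representations:
        raise ValueError("grid needs at least one profile and one representation")
    rows = []
    for profile in profiles:
        for mode in representations:
            cell = dc_replace(
                config,
                encoder_profile=profile,
                representation=mode,
                out_dir=str(Path(config.out_dir) / f"{profile.replace(':', '_')}__{mode}"),
            )
            try:
                metrics = run_end_to_end(cell)
                rows.append(
                    {
                        "profile": profile,
                        "representation": mode,
                        "macro_f1": metrics["macro_f1"],
                        "best_epoch": metrics["best_epoch"],
                        "error": None,
                    }
                )
            except Exception as exc:  # record and continue
                rows.append(
                    {
                        "profile": profile,
                        "representation": mode,
                        "macro_f1": np.nan,
                        "best_epoch": None,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def learning_curve_run(
    train_reports: Sequence[Report],
    train_annotations: Sequence[SpanAnnotation],
    test_reports: Sequence[Report],
    test_annotations: Sequence[SpanAnnotation],
    sizes: Sequence[int],
    seed: int = 0,
    **extractor_kwargs,
) -> dict[int, float]:
    """Macro-F1 vs number of training reports, nested seeded subsets."""
    anns_by_report: dict[str, list[SpanAnnotation]] = {}
    for a in train_annotations:
        anns_by_report.setdefault(a.report_id, []).append(a)

    def fit_and_score(subset: list[Report]) -> float:
        anns = [a for r in subset for a in anns_by_report.get(r.report_id, [])]
        ex = MeasurementExtractor(seed=seed, **extractor_kwargs)
        ex.fit(subset, anns)
        return ex.evaluate_on(test_reports, test_annotations).macro_f1

    return learning_curve(list(train_reports), sizes, fit_and_score, seed=seed)
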