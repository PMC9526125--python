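"""Digit merging, consolidation, physiologic filtering, gold pass-through."""

import numpy as np
import pytest

from cmrextract.numeric import MODES, project_annotations, transform_text
from cmrextract.postprocess import (
    consolidate,
    emitted,
    filter_physiologic,
    measurements_to_frame,
    merge_digits,
)
from cmrextract.schema import Report
from cmrextract.synthetic import CorpusConfig, generate_corpus
from cmrextract.tokenizer import SubwordTokenizer
from cmrextract.windows import tokenize_with_labels


class TestMergeDigits:
    def test_partial_number_extended(self):
        text = "LVEF: 51.01 ml"
        # predicted run covers only "51"
        assert merge_digits([(6, 8)], text) == [(6, 11)]
        assert text[6:11] == "51.01"

    def test_full_number_unchanged(self):
        text = "LVEF: 51.01 ml"
        assert merge_digits([(6, 11)], text) == [(6, 11)]

    def test_whitespace_stops_extension(self):
        text = "LVEF: 51 01"
        assert merge_digits([(6, 8)], text) == [(6, 8)]

    def test_idempotent(self):
        text = "RVEDV 147.54 and 23"
        once = merge_digits([(6, 9)], text)
        assert merge_digits(once, text) == once


def _tok(texts):
    return SubwordTokenizer().fit(texts)


def test_consolidate_merges_fragmented_value(schema):
    r = Report("r1", "LVEF: 51.01 today")
    tok = _tok([r.text])
    enc = tok.encode(r.text)
    lvef = schema.label_to_id("lvef")
    labels = [lvef if s >= 6 and e <= 11 else 0 for (s, e) in enc.offsets]
    ms = consolidate(labels, np.ones(len(labels)), enc.offsets, r, schema)
    assert len(ms) == 1
    assert ms[0].label == "lvef"
    assert ms[0].value == 51.01
    assert ms[0].span == (6, 11)


def test_consolidate_zero_labels_empty(schema):
    r = Report("r1", "no predictions here 55")
    tok = _tok([r.text])
    enc = tok.encode(r.text)
    assert consolidate([0] * len(enc), np.ones(len(enc)), enc.offsets, r, schema) == []


def test_duplicate_candidates_resolved_by_score(schema):
    r = Report("r1", "LVEF: 55 then LVEF: 60")
    tok = _tok([r.text])
    enc = tok.encode(r.text)
    lvef = schema.label_to_id("lvef")
    labels, scores = [], []
    for (s, e) in enc.offsets:
        if 6 <= s and e <= 8:
            labels.append(lvef); scores.append(0.9)
        elif 20 <= s and e <= 22:
            labels.append(lvef); scores.append(0.6)
        else:
            labels.append(0); scores.append(1.0)
    ms = consolidate(labels, scores, enc.offsets, r, schema)
    assert len(ms) == 2
    kept = [m for m in ms if not m.filtered]
    flagged = [m for m in ms if m.filtered]
    assert len(kept) == 1 and kept[0].value == 55.0
    assert flagged[0].reason == "duplicate" and flagged[0].value == 60.0


def test_non_numeric_candidate_flagged(schema):
    r = Report("r1", "LVEF: normal today")
    tok = _tok([r.text])
    enc = tok.encode(r.text)
    lvef = schema.label_to_id("lvef")
    labels = [lvef if tok_piece == "normal" else 0 for tok_piece in enc.pieces]
    ms = consolidate(labels, np.ones(len(labels)), enc.offsets, r, schema)
    assert len(ms) == 1
    assert ms[0].filtered and ms[0].reason == "non-numeric"
    assert emitted(ms) == []


class TestPhysiologicFilter:
    def _m(self, value, label="lvef"):
        from cmrextract.postprocess import Measurement

        return Measurement("r1", label, value, (0, 2), 1.0)

    def test_in_range_retained(self, schema):
        out = filter_physiologic([self._m(55.0)], schema)
        assert not out[0].filtered

    def test_out_of_range_flagged(self, schema):
        out = filter_physiologic([self._m(150.0)], schema)
        assert out[0].filtered and out[0].reason == "out-of-range"

    def test_unknown_label_errors(self, schema):
        with pytest.raises(KeyError):
            filter_physiologic([self._m(55.0, label="nope")], schema)

    def test_idempotent_and_conserving(self, schema):
        ms = [self._m(55.0), self._m(150.0), self._m(7.0, "co")]
        once = filter_physiologic(ms, schema)
        twice = filter_physiologic(once, schema)
        assert once == twice
        assert len(once) == len(ms)
        assert len(emitted(once)) + sum(m.filtered for m in once) == len(ms)

    def test_flagged_fraction_tracks_generator_rate(self, schema):
        """A corpus drawn with 10% out-of-range values flags ~10%."""
        reports, anns = generate_corpus(
            CorpusConfig(n_reports=400, seed=13, out_of_range_rate=0.1), schema
        )
        from cmrextract.postprocess import Measurement

        ms = [
            Measurement(a.report_id, a.label, a.value, (a.start, a.end), 1.0)
            for a in anns
        ]
        out = filter_physiologic(ms, schema)
        frac = sum(m.filtered for m in out) / len(out)
        assert abs(frac - 0.10) < 0.02


def test_gold_pass_through_reproduces_annotations(midsize_corpus, schema):
    """Consolidation+filtering on gold token labels recovers the gold set
    exactly, in every numerical representation."""
    reports, annotations = midsize_corpus
    tok = _tok([r.text for r in reports])
    by = {}
    for a in annotations:
        by.setdefault(a.report_id, []).append(a)
    for mode in MODES:
        for r in reports:
            tt = transform_text(r.text, mode)
            anns = project_annotations(tt, by.get(r.report_id, []))
            enc, labels = tokenize_with_labels(r, anns, tok, schema, text=tt.text)
            ms = emitted(
                filter_physiologic(
                    consolidate(labels, np.ones(len(labels)), enc.offsets, r, schema,
                                transformed=tt),
                    schema,
                )
            )
            gold = sorted(
                (a.label, a.start, a.end, a.value) for a in by.get(r.report_id, [])
            )
            got = sorted((m.label, m.span[0], m.span[1], m.value) for m in ms)
            assert got == gold, (mode, r.report_id)


def test_measurements_frame_layout(schema):
    from cmrextract.postprocess import Measurement

    df = measurements_to_frame(
        [Measurement("r1", "lvef", 55.0, (6, 8), 0.9)]
    )
    assert list(df.columns) == [
        "report_id", "label", "value", "start", "end", "score", "filtered", "reason"
    ]
    assert df.loc[0, "value"] == 55.0
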