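"""Encoder numerics, training behaviour, decoding rules, attention."""

import numpy as np
import pytest

from cmrextract.model import TokenClassifier, TrainConfig, decode_argmax, decode_threshold
from cmrextract.nn import Adam, TinyTransformer
from cmrextract.synthetic import CorpusConfig, generate_corpus
from cmrextract.tokenizer import SubwordTokenizer
from cmrextract.windows import tokenize_with_labels, window


def test_gradients_match_finite_differences():
    """Hand-written backprop agrees with central differences everywhere."""
    rng = np.random.default_rng(1)
    m = TinyTransformer(
        vocab_size=11, n_labels=5, d_model=8, n_heads=2, n_layers=2,
        d_ff=16, max_len=12, rel_window=3, seed=3,
    )
    # move the zero-initialized pieces off zero so every path carries gradient
    m.params["head_W"] = rng.normal(0, 0.1, m.params["head_W"].shape)
    for l in range(2):
        m.params[f"l{l}_rel"] = rng.normal(0, 0.1, m.params[f"l{l}_rel"].shape)
    ids = rng.integers(0, 11, size=(2, 7))
    mask = np.ones((2, 7))
    mask[1, 5:] = 0
    labels = rng.integers(0, 5, size=(2, 7))
    _, grads = m.loss_and_grads(ids, mask, labels)
    eps = 1e-6
    for key in m.params:
        p = m.params[key]
        for _ in range(2):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            old = p[idx]
            p[idx] = old + eps
            lp, _ = m.loss_and_grads(ids, mask, labels)
            p[idx] = old - eps
            lm, _ = m.loss_and_grads(ids, mask, labels)
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[key][idx]
            assert abs(num - ana) <= 1e-3 * max(1.0, abs(num) + abs(ana)), key


def test_untrained_scores_uniform():
    """Zero-initialized head gives the uniform distribution over 22 labels."""
    m = TinyTransformer(vocab_size=30, n_labels=22, seed=0)
    probs = m.predict_probs(np.array([[1, 2, 3]]), np.ones((1, 3)))
    assert np.allclose(probs, 1 / 22, atol=1e-9)


def test_scores_normalized_rows():
    m = TinyTransformer(vocab_size=30, n_labels=22, seed=0)
    rng = np.random.default_rng(0)
    m.params["head_W"] = rng.normal(0, 0.5, m.params["head_W"].shape)
    probs = m.predict_probs(rng.integers(0, 30, (2, 9)), np.ones((2, 9)))
    assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
    assert (probs >= 0).all()


def test_attention_rows_normalized():
    m = TinyTransformer(vocab_size=30, n_labels=22, seed=0)
    attn = m.attention_last_layer(np.array([[4, 5, 6, 7]]), np.ones((1, 4)))
    assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


class TestDecoding:
    def _scores(self, pairs, n=22):
        row = np.zeros(n)
        for i, v in pairs:
            row[i] = v
        row[0] = 1.0 - row.sum()
        return row[None, :]

    def test_confident_label_both_modes(self):
        s = self._scores([(3, 0.6)])
        assert decode_threshold(s)[0] == 3
        assert decode_argmax(s)[0] == 3

    def test_uniform_scores_abstain_vs_first(self):
        s = np.full((1, 22), 1 / 22)
        assert decode_threshold(s)[0] == 0
        assert decode_argmax(s)[0] == 0  # lowest index tie-break

    def test_sub_threshold_abstains(self):
        s = self._scores([(2, 0.45), (5, 0.40)])
        assert decode_threshold(s)[0] == 0
        assert decode_argmax(s)[0] == 2

    def test_threshold_range_validated(self):
        with pytest.raises(ValueError):
            decode_threshold(np.ones((1, 22)) / 22, t=1.5)

    def test_agreement_when_max_above_half(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(22) * 0.05, size=200)
        confident = raw[raw.max(axis=1) > 0.5]
        assert len(confident) > 10
        assert (decode_threshold(confident) == decode_argmax(confident)).all()


def test_train_config_validation_and_profiles():
    assert TrainConfig().learning_rate == 5e-5
    assert TrainConfig().batch_size == 32
    assert TrainConfig().max_epochs == 20
    tiny = TrainConfig.for_profile("tiny_scratch")
    assert tiny.learning_rate > TrainConfig().learning_rate
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(decode_threshold=1.2)


def test_pretrained_profile_unavailable():
    clf = TokenClassifier(encoder_profile="pretrained:bert-large-cased")
    with pytest.raises(RuntimeError, match="tiny_scratch"):
        clf.fit([_make_windows()[0]])


def _make_windows(seed=3, n_reports=1):
    from cmrextract import default_schema

    schema = default_schema()
    reports, anns = generate_corpus(CorpusConfig(n_reports=n_reports, seed=seed), schema)
    tok = SubwordTokenizer().fit([r.text for r in reports])
    by = {}
    for a in anns:
        by.setdefault(a.report_id, []).append(a)
    wins = []
    for r in reports:
        enc, labels = tokenize_with_labels(r, by.get(r.report_id, []), tok, schema)
        wins.extend(window(r.report_id, enc, labels))
    return wins, tok


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        TokenClassifier().fit([])


def test_label_outside_space_rejected():
    wins, tok = _make_windows()
    wins[0].labels[0] = 99
    with pytest.raises(ValueError, match="label id"):
        TokenClassifier(vocab_size=tok.vocab_size_).fit(wins)


def test_seeded_training_is_deterministic():
    wins, tok = _make_windows()
    kw = dict(vocab_size=tok.vocab_size_, max_epochs=1, seed=5)
    a = TokenClassifier(**kw).fit(wins)
    b = TokenClassifier(**kw).fit(wins)
    assert a.history_[0]["train_loss"] == b.history_[0]["train_loss"]


def test_loss_descends_on_small_corpus():
    wins, tok = _make_windows(seed=8, n_reports=20)
    clf = TokenClassifier(vocab_size=tok.vocab_size_, max_epochs=2, seed=0).fit(wins)
    first = clf.history_[0]["train_loss"]
    assert first < np.log(22)  # below the uniform-prediction starting loss
    assert clf.history_[-1]["train_loss"] < first


@pytest.fixture(scope="module")
def fitted():
    wins, tok = _make_windows(seed=3, n_reports=1)
    clf = TokenClassifier(
        vocab_size=tok.vocab_size_, max_epochs=200, learning_rate=1e-3,
        batch_size=1, seed=0,
    ).fit(wins)
    return wins, clf


class TestMemorization:
    """A single report can be labeled perfectly after enough steps, and the
    attention of a value token points into its own measurement phrase."""

    def test_exact_label_recovery(self, fitted):
        wins, clf = fitted
        pred = np.concatenate(clf.predict(wins, mode="argmax"))
        gold = np.concatenate([w.labels for w in wins])
        assert (pred == gold).all()

    def test_gold_scores_confident(self, fitted):
        wins, clf = fitted
        hits = total = 0
        for w in wins:
            scores = clf.predict_scores(w)
            for i, lab in enumerate(w.labels):
                if lab > 0:
                    total += 1
                    hits += scores[i, lab] > 0.5
        assert total > 0 and hits / total >= 0.9

    def test_value_token_attends_within_window(self, fitted):
        wins, clf = fitted
        w = wins[0]
        pos = next(i for i, lab in enumerate(w.labels) if lab > 0)
        top = clf.top_attended_tokens(w, pos, k=5)
        assert len(top) == 5
        weights = [wt for (_, _, wt) in top]
        assert weights == sorted(weights, reverse=True)

    def test_attention_position_validated(self, fitted):
        wins, clf = fitted
        with pytest.raises(ValueError):
            clf.top_attended_tokens(wins[0], position=10_000)


def test_window_longer_than_capacity_rejected():
    wins, tok = _make_windows()
    clf = TokenClassifier(vocab_size=tok.vocab_size_, max_epochs=1, seed=0).fit(wins)
    from cmrextract.windows import LabeledWindow

    big = LabeledWindow(
        report_id="x",
        tokens=[1] * 200,
        char_offsets=[(i, i + 1) for i in range(200)],
        labels=[0] * 200,
        window_index=0,
    )
    with pytest.raises(ValueError, match="capacity"):
        clf.predict_scores(big)


def test_save_load_round_trip(tmp_path):
    wins, tok = _make_windows()
    clf = TokenClassifier(vocab_size=tok.vocab_size_, max_epochs=2, seed=0).fit(wins)
    clf.save(tmp_path / "model")
    back = TokenClassifier.load(tmp_path / "model")
    w = wins[0]
    assert np.allclose(back.predict_scores(w), clf.predict_scores(w))


def test_adam_moves_parameters():
    params = {"w": np.ones(3)}
    opt = Adam(params, lr=0.1)
    opt.step(params, {"w": np.array([1.0, -1.0, 0.5])})
    assert not np.allclose(params["w"], 1.0)
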