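"""Transformer token classification: training, decoding, attention inspection.

The extractor is a token classifier: every subword token of a report is
assigned one of 22 labels (21 measurement types + null).  Training follows
the standard fine-tuning recipe — token cross-entropy, Adam, fixed learning
rate and batch size, a fixed number of epochs with per-epoch evaluation so
the caller can select the epoch maximizing macro-averaged F1.

Two decoding rules are provided.  Threshold decoding assigns a label when
its score exceeds a cut (default 0.5; since scores are a distribution, at
most one label can pass) and abstains to null otherwise — used for model
evaluation.  Argmax decoding always assigns the highest-scoring label (ties
broken toward the lowest label index) — used when running inference at
scale for downstream analyses.

``TokenClassifier`` is a scikit-learn style estimator: constructor
hyperparameters, ``fit`` producing trailing-underscore attributes,
``get_params``/``set_params`` via ``BaseEstimator``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np
from sklearn.base import BaseEstimator

from .nn import Adam, TinyTransformer
from .windows import LabeledWindow

__all__ = [
    "TrainConfig",
    "TokenClassifier",
    "decode_threshold",
    "decode_argmax",
    "top_attended_tokens",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The defaults (learning rate 5e-5, batch size 32, 20 epochs, 0.5 decode
    threshold) are the standard fine-tuning recipe for pretrained
    transformer encoders.  A from-scratch miniature encoder needs a larger
    step size to converge in a comparable number of epochs;
    :meth:`for_profile` returns the recommended configuration per profile.
    """

    learning_rate: float = 5e-5
    batch_size: int = 32
    max_epochs: int = 20
    seed: int = 0
    encoder_profile: str = "tiny_scratch"
    decode_threshold: float = 0.5
    select_on: str = "dev"  # "dev" (held-out split) or "test" (report faithfully)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 < self.decode_threshold < 1:
            raise ValueError("decode_threshold must be in (0, 1)")

    @classmethod
    def for_profile(cls, profile: str, **overrides) -> "TrainConfig":
        if profile == "tiny_scratch":
            base = dict(learning_rate=2e-3, batch_size=8, max_epochs=60,
                        encoder_profile=profile)
        else:
            base = dict(encoder_profile=profile)
        base.update(overrides)
        return cls(**base)


def _pad_batch(windows: Sequence[LabeledWindow], pad_id: int = 0):
    B = len(windows)
    T = max(len(w) for w in windows)
    ids = np.full((B, T), pad_id, dtype=np.int64)
    mask = np.zeros((B, T))
    labels = np.zeros((B, T), dtype=np.int64)
    for i, w in enumerate(windows):
        n = len(w)
        ids[i, :n] = w.tokens
        mask[i, :n] = 1.0
        labels[i, :n] = w.labels
    return ids, mask, labels


def decode_threshold(scores: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Per-token labels: the label scoring above ``t``, else null (0).

    Scores are rows of a normalized distribution, so at most one label can
    exceed any t >= 0.5; abstention to null happens when none does.
    """
    if not 0 < t < 1:
        raise ValueError("threshold must be in (0, 1)")
    scores = np.asarray(scores)
    best = scores.argmax(axis=-1)
    return np.where(scores.max(axis=-1) > t, best, 0)


def decode_argmax(scores: np.ndarray) -> np.ndarray:
    """Per-token labels: highest score, ties to the lowest label index."""
    return np.asarray(scores).argmax(axis=-1)


class TokenClassifier(BaseEstimator):
    """Transformer token classifier over the measurement label space.

    Parameters
    ----------
    n_labels:
        Size of the label space including null (22 for the default schema).
    vocab_size:
        Tokenizer vocabulary size; inferred from the training windows when
        None (pass the tokenizer's value in normal use).
    encoder_profile:
        ``"tiny_scratch"`` — the built-in miniature encoder trained from
        random initialization.  ``"pretrained:<name>"`` profiles describe
        full-scale pretrained encoders and require a deep-learning backend.
    d_model, n_heads, n_layers, d_ff, max_len:
        Encoder dimensions (tiny_scratch profile).
    learning_rate, batch_size, max_epochs, seed, decode_thr:
        Training recipe; see :class:`TrainConfig`.

    Attributes
    ----------
    model_ : TinyTransformer
        Encoder + head with the selected epoch's weights.
    history_ : list of dict
        Per-epoch loss and (when a selection split is given) macro-F1.
    best_epoch_ : int
        1-based epoch whose weights ``model_`` holds.
    """

    def __init__(
        self,
        n_labels: int = 22,
        vocab_size: int | None = None,
        encoder_profile: str = "tiny_scratch",
        d_model: int = 64,
        n_heads: int = 4,
        n_layers: int = 2,
        d_ff: int = 128,
        max_len: int = 128,
        learning_rate: float = 2e-3,
        batch_size: int = 8,
        max_epochs: int = 60,
        seed: int = 0,
        decode_thr: float = 0.5,
        verbose: bool = False,
    ):
        self.n_labels = n_labels
        self.vocab_size = vocab_size
        self.encoder_profile = encoder_profile
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.max_len = max_len
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.seed = seed
        self.decode_thr = decode_thr
        self.verbose = verbose

    @classmethod
    def from_config(cls, config: TrainConfig, **kwargs) -> "TokenClassifier":
        return cls(
            encoder_profile=config.encoder_profile,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            seed=config.seed,
            decode_thr=config.decode_threshold,
            **kwargs,
        )

    # -- fitting ------------------------------------------------------------

    def _check_profile(self) -> None:
        if self.encoder_profile == "tiny_scratch":
            return
        if self.encoder_profile.startswith("pretrained:"):
            raise RuntimeError(
                f"encoder profile {self.encoder_profile!r} needs pretrained "
                "transformer weights and a deep-learning backend; this "
                "installation provides the self-contained 'tiny_scratch' encoder"
            )
        raise ValueError(f"unknown encoder profile {self.encoder_profile!r}")

    def fit(
        self,
        windows: Sequence[LabeledWindow],
        y=None,
        dev_windows: Sequence[LabeledWindow] | None = None,
    ) -> "TokenClassifier":
        """Train on labeled windows; select the best epoch on ``dev_windows``.

        With no dev split the final epoch's weights are kept.  Per-epoch
        metrics land in ``history_`` so callers can plot or re-select.
        """
        from .evaluation import evaluate  # local import: avoid cycle at module load

        self._check_profile()
        windows = list(windows)
        if not windows:
            raise ValueError("empty training set")
        for w in windows:
            if any(not 0 <= lab < self.n_labels for lab in w.labels):
                raise ValueError(
                    f"report {w.report_id!r}: label id outside the "
                    f"{self.n_labels}-label space"
                )
        vocab_size = self.vocab_size
        if vocab_size is None:
            vocab_size = max((max(w.tokens, default=0) for w in windows), default=0) + 1
        self.vocab_size_ = int(vocab_size)

        model = TinyTransformer(
            vocab_size=self.vocab_size_,
            n_labels=self.n_labels,
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            d_ff=self.d_ff,
            max_len=self.max_len,
            seed=self.seed,
        )
        opt = Adam(model.params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed)
        order = np.arange(len(windows))

        self.history_ = []
        best_metric = -np.inf
        best_state = model.state_dict()
        best_epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            rng.shuffle(order)
            losses = []
            for lo in range(0, len(order), self.batch_size):
                batch = [windows[i] for i in order[lo : lo + self.batch_size]]
                ids, mask, labels = _pad_batch(batch)
                loss, grads = model.loss_and_grads(ids, mask, labels)
                opt.step(model.params, grads)
                losses.append(loss)
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if dev_windows is not None:
                self.model_ = model  # scores for selection use current weights
                pred, gold = [], []
                for w in dev_windows:
                    scores = self.predict_scores(w)
                    pred.extend(decode_threshold(scores, self.decode_thr))
                    gold.extend(w.labels)
                res = evaluate(pred, gold, n_labels=self.n_labels)
                record["macro_f1"] = res.macro_f1
                metric = res.macro_f1
            else:
                metric = -record["train_loss"]
            self.history_.append(record)
            if self.verbose:
                print(f"epoch {epoch}: {record}")
            if metric > best_metric:
                best_metric = metric
                best_state = model.state_dict()
                best_epoch = epoch
        model.load_state_dict(best_state)
        self.model_ = model
        self.best_epoch_ = best_epoch
        self.classes_ = np.arange(self.n_labels)
        return self

    # -- inference ----------------------------------------------------------

    def predict_scores(self, window: LabeledWindow) -> np.ndarray:
        """Per-token normalized scores, shape (len(window), n_labels)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        if len(window) == 0:
            return np.zeros((0, self.n_labels))
        if len(window) > self.model_.max_len:
            raise ValueError(
                f"window of {len(window)} tokens exceeds model capacity "
                f"{self.model_.max_len}"
            )
        ids = np.clip(np.asarray([window.tokens]), 0, self.model_.vocab_size - 1)
        mask = np.ones_like(ids, dtype=float)
        return self.model_.predict_probs(ids, mask)[0]

    def predict(self, windows: Sequence[LabeledWindow], mode: str = "threshold") -> list[np.ndarray]:
        """Decoded per-token labels for each window."""
        out = []
        for w in windows:
            scores = self.predict_scores(w)
            if mode == "threshold":
                out.append(decode_threshold(scores, self.decode_thr))
            elif mode == "argmax":
                out.append(decode_argmax(scores))
            else:
                raise ValueError(f"unknown decode mode {mode!r}")
        return out

    # -- attention inspection -----------------------------------------------

    def top_attended_tokens(
        self, window: LabeledWindow, position: int, k: int = 4
    ) -> list[tuple[int, str, float]]:
        """Tokens most attended by ``position`` in the last encoder layer.

        Weights are averaged over heads (they sum to 1 across the window);
        returns up to ``k`` (token index, piece, weight) triples sorted by
        descending weight.  Useful for inspecting why a value token was or
        was not labeled — e.g. whether it attends to its measurement-name
        phrase.
        """
        if not 0 <= position < len(window):
            raise ValueError(f"position {position} out of range for window of {len(window)}")
        ids = np.clip(np.asarray([window.tokens]), 0, self.model_.vocab_size - 1)
        mask = np.ones_like(ids, dtype=float)
        row = self.model_.attention_last_layer(ids, mask)[0][position]
        order = np.argsort(-row)[:k]
        pieces = window.pieces or [str(t) for t in window.tokens]
        return [(int(i), pieces[int(i)], float(row[int(i)])) for i in order]

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "params": self.get_params(),
            "vocab_size_": self.vocab_size_,
            "best_epoch_": getattr(self, "best_epoch_", None),
            "history_": getattr(self, "history_", []),
            "encoder_config": self.model_.get_config(),
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "weights.npz", **self.model_.state_dict())

    @classmethod
    def load(cls, directory: str | Path) -> "TokenClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        est = cls(**meta["params"])
        est.vocab_size_ = meta["vocab_size_"]
        est.best_epoch_ = meta.get("best_epoch_")
        est.history_ = meta.get("history_", [])
        cfg = meta["encoder_config"]
        est.model_ = TinyTransformer(seed=0, **cfg)
        with np.load(directory / "weights.npz") as npz:
            est.model_.load_state_dict({k: npz[k] for k in npz.files})
        est.classes_ = np.arange(est.n_labels)
        return est


def top_attended_tokens(model: TokenClassifier, window: LabeledWindow, position: int, k: int = 4):
    """Functional wrapper over :meth:`TokenClassifier.top_attended_tokens`."""
    return model.top_attended_tokens(window, position, k)
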