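"""A deterministic vocabulary-based subword tokenizer with character offsets.

The token classifier needs a tokenizer satisfying one contract: text in,
(token ids, per-token character offsets) out.  This implementation mimics
the behaviour of wordpiece vocabularies that motivates alternative numeric
representations:

* alphabetic words are matched greedily against a fitted vocabulary and
  fall back to single-character pieces (continuations carry a ``##`` mark in
  the piece string, offsets stay exact), so no word is ever out-of-vocabulary;
* runs of digits split into single-digit pieces and the decimal point is its
  own token — a decimal number fragments into many pieces, exactly the
  behaviour the replaced-decimal representation is designed to avoid;
* a digits-pipe-digits pattern (``51|01``, the replaced-decimal encoding) is
  kept intact as one pre-token and mapped to a dedicated ``<num>`` vocabulary
  id, so the whole number is a single token;
* any other non-space character is a single-character token.

``fit`` builds the vocabulary from a corpus (sorted, hence reproducible);
``encode`` never fails on unseen text thanks to the character fallback.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["SubwordTokenizer", "Encoding"]

_PRETOKEN_RE = re.compile(r"[A-Za-z]+|\d+\|\d+|\d|\S")

_SPECIAL_TOKENS = ("<pad>", "<unk>", "<num>")


@dataclass
class Encoding:
    """Tokenized text: ids, human-readable pieces, half-open char offsets."""

    ids: list[int]
    pieces: list[str]
    offsets: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.ids)


class SubwordTokenizer:
    """Greedy-longest-match subword tokenizer (scikit-learn style).

    Parameters
    ----------
    lowercase:
        Lowercase alphabetic pieces before vocabulary lookup (default True);
        offsets always index the original text.
    max_word_piece:
        Longest alphabetic piece kept whole in the vocabulary.

    Attributes
    ----------
    vocab_ : dict[str, int]
        Piece -> id mapping, built by :meth:`fit`.
    """

    def __init__(self, lowercase: bool = True, max_word_piece: int = 20):
        self.lowercase = lowercase
        self.max_word_piece = max_word_piece

    # -- fitting ------------------------------------------------------------

    def fit(self, texts: Iterable[str]) -> "SubwordTokenizer":
        """Build the vocabulary from a corpus of texts."""
        pieces: set[str] = set()
        for text in texts:
            for m in _PRETOKEN_RE.finditer(text):
                tok = m.group(0)
                for piece in self._split_pretoken(tok, None):
                    pieces.add(piece)
        # guaranteed fallbacks: all single chars seen + ascii letters/digits
        for ch in "abcdefghijklmnopqrstuvwxyz0123456789":
            pieces.add(ch)
            pieces.add("##" + ch)
        vocab = {tok: i for i, tok in enumerate(_SPECIAL_TOKENS)}
        for piece in sorted(pieces):
            vocab.setdefault(piece, len(vocab))
        self.vocab_ = vocab
        return self

    @property
    def vocab_size_(self) -> int:
        return len(self.vocab_)

    @property
    def pad_id(self) -> int:
        return 0

    # -- encoding -----------------------------------------------------------

    def _norm(self, piece: str) -> str:
        return piece.lower() if self.lowercase else piece

    def _split_pretoken(self, tok: str, vocab: dict | None) -> list[str]:
        """Split one pre-token into pieces (``##`` marks continuations)."""
        if re.fullmatch(r"\d+\|\d+", tok):
            return ["<num>"]
        if tok.isdigit():  # single digit by the pre-token regex
            return [tok]
        if not tok.isalpha():
            return [self._norm(tok)]
        word = self._norm(tok)
        if vocab is None:
            # fitting pass: store the whole word (capped) plus char fallbacks
            return [word[: self.max_word_piece]]
        pieces = []
        pos = 0
        while pos < len(word):
            limit = min(len(word), pos + self.max_word_piece)
            for end in range(limit, pos, -1):
                cand = word[pos:end]
                if pos > 0:
                    cand = "##" + cand
                if cand in vocab:
                    pieces.append(cand)
                    pos = end
                    break
            else:  # pragma: no cover - single chars are always in vocab
                pieces.append(word[pos])
                pos += 1
        return pieces

    def encode(self, text: str) -> Encoding:
        """Tokenize ``text`` into vocabulary ids with exact char offsets."""
        if not hasattr(self, "vocab_"):
            raise RuntimeError("tokenizer is not fitted; call fit() first")
        ids: list[int] = []
        pieces: list[str] = []
        offsets: list[tuple[int, int]] = []
        for m in _PRETOKEN_RE.finditer(text):
            tok, start = m.group(0), m.start()
            if re.fullmatch(r"\d+\|\d+", tok):
                ids.append(self.vocab_["<num>"])
                pieces.append(tok)
                offsets.append((start, m.end()))
                continue
            if tok.isalpha():
                pos = 0
                for piece in self._split_pretoken(tok, self.vocab_):
                    plain = piece[2:] if piece.startswith("##") else piece
                    ids.append(self.vocab_.get(piece, self.vocab_["<unk>"]))
                    pieces.append(piece)
                    offsets.append((start + pos, start + pos + len(plain)))
                    pos += len(plain)
                continue
            piece = self._norm(tok)
            ids.append(self.vocab_.get(piece, self.vocab_["<unk>"]))
            pieces.append(piece)
            offsets.append((start, m.end()))
        enc = Encoding(ids=ids, pieces=pieces, offsets=offsets)
        for (s, e) in enc.offsets:
            if not (0 <= s < e <= len(text)):
                raise RuntimeError("tokenizer produced offsets inconsistent with text")
        return enc

    # -- persistence ---------------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {"lowercase": self.lowercase, "max_word_piece": self.max_word_piece}

    def set_params(self, **params) -> "SubwordTokenizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"params": self.get_params(), "vocab": self.vocab_})
        )

    @classmethod
    def load(cls, path: str | Path) -> "SubwordTokenizer":
        doc = json.loads(Path(path).read_text())
        tok = cls(**doc["params"])
        tok.vocab_ = {k: int(v) for k, v in doc["vocab"].items()}
        return tok
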