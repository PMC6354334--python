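"""Tokenization, vocabulary and numeric encoding of (entity, TE) pairs.

Tokenization is character-level for Chinese with an ASCII fallback: runs of
ASCII letters/digits (optionally joined by ``-:/.``, so a date literal like
``2012-02-03`` is one token) form single tokens, whitespace is skipped, and
every other character is its own token.  The target annotation (entity or
TE) is collapsed to a single token whose string is its surface form, since
the input representation assumes one target word per sentence.

Positions are the signed offsets d_t = t - k from the target token, clipped
to +/-(max_len - 1); sentences longer than max_len are truncated to a window
centred on the target, shorter ones padded at the end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ..corpus import ClinicalNote, SentenceSpan, Span

PAD, UNK = "<PAD>", "<UNK>"
PAD_ID, UNK_ID = 0, 1

_ASCII_TOKEN = re.compile(r"[A-Za-z0-9]+(?:[-:/.][A-Za-z0-9]+)*")


def tokenize(text: str, offset: int = 0) -> list[tuple[str, int, int]]:
    """Character tokens with ASCII-run fallback; returns (token, start, end)."""
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        m = _ASCII_TOKEN.match(text, i)
        if m:
            tokens.append((m.group(), offset + i, offset + m.end()))
            i = m.end()
        else:
            tokens.append((ch, offset + i, offset + i + 1))
            i += 1
    return tokens


@dataclass
class Vocabulary:
    """Token -> id table with PAD (0) and UNK (1) reserved."""

    index: dict[str, int] = field(
        default_factory=lambda: {PAD: PAD_ID, UNK: UNK_ID}
    )

    def __len__(self) -> int:
        return len(self.index)

    def add(self, token: str) -> int:
        return self.index.setdefault(token, len(self.index))

    def get(self, token: str) -> int:
        return self.index.get(token, UNK_ID)

    def tokens(self) -> list[str]:
        return sorted(self.index, key=self.index.get)

    def to_dict(self) -> dict:
        return {"tokens": self.tokens()}

    @classmethod
    def from_dict(cls, doc: dict) -> "Vocabulary":
        return cls(index={tok: i for i, tok in enumerate(doc["tokens"])})


@dataclass
class SentenceEncoding:
    """One sentence, target-collapsed and windowed to the maximum length."""

    token_ids: np.ndarray  # (n,) int64
    positions: np.ndarray  # (n,) signed offsets, d_k = 0
    target: int            # index k of the target token


def collapse_target(
    tokens: list[tuple[str, int, int]], target_span: Span, surface: str
) -> tuple[list[str], int]:
    """Replace the tokens overlapping the target span by one surface token."""
    before = [t for t in tokens if t[2] <= target_span.start]
    after = [t for t in tokens if t[1] >= target_span.end]
    if len(before) + len(after) == len(tokens):  # span between tokens
        raise ValueError(
            f"target span ({target_span.start},{target_span.end}) "
            "covers no token"
        )
    words = [t[0] for t in before] + ["".join(surface.split())] + [t[0] for t in after]
    return words, len(before)


class PairEncoder:
    """Maps annotated pairs to the numeric arrays the classifier consumes."""

    def __init__(self, vocab: Vocabulary, max_len: int = 100):
        self.vocab = vocab
        self.max_len = max_len

    # -- vocabulary -----------------------------------------------------
    @classmethod
    def fit(
        cls,
        sentences_with_targets: list[tuple[list[str], int]],
        max_len: int = 100,
    ) -> "PairEncoder":
        vocab = Vocabulary()
        for words, _ in sentences_with_targets:
            for w in words:
                vocab.add(w)
        return cls(vocab, max_len=max_len)

    # -- encoding -------------------------------------------------------
    def encode_sentence(self, words: list[str], target: int) -> SentenceEncoding:
        if not words:
            raise ValueError("cannot encode an empty token sequence")
        if not 0 <= target < len(words):
            raise ValueError(f"target {target} outside sentence of {len(words)}")
        if len(words) > self.max_len:
            half = self.max_len // 2
            start = min(max(target - half, 0), len(words) - self.max_len)
            words = words[start : start + self.max_len]
            target = target - start
        ids = np.array([self.vocab.get(w) for w in words], dtype=np.int64)
        clip = self.max_len - 1
        pos = np.clip(np.arange(len(words)) - target, -clip, clip)
        return SentenceEncoding(token_ids=ids, positions=pos, target=target)

    def position_row(self, offset: int) -> int:
        """Row of E_d for a signed offset; the last row is the PAD position."""
        return int(offset) + self.max_len - 1

    @property
    def n_position_rows(self) -> int:
        return 2 * self.max_len  # offsets -(L-1)..(L-1) plus PAD

    @property
    def pad_position_row(self) -> int:
        return 2 * self.max_len - 1


def sentence_words_for_span(
    note: ClinicalNote, sentence: SentenceSpan, target_span: Span, surface: str
) -> tuple[list[str], int]:
    """Tokenize a sentence and collapse the target annotation.

    Tokens straddling a span edge are absorbed into the target token.
    """
    text = note.text[sentence.span.start : sentence.span.end]
    tokens = tokenize(text, offset=sentence.span.start)
    return collapse_target(tokens, target_span, surface)


def batch_arrays(
    encodings: list[SentenceEncoding],
    pad_position_row: int,
    position_offset: int,
    min_len: int,
    dtype=np.int64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack encodings into padded (ids, position rows, mask, real_len)."""
    T = max(max(len(e.token_ids) for e in encodings), min_len)
    B = len(encodings)
    ids = np.full((B, T), PAD_ID, dtype=dtype)
    pos = np.full((B, T), pad_position_row, dtype=dtype)
    mask = np.zeros((B, T), dtype=np.float64)
    lens = np.zeros(B, dtype=np.int64)
    for i, enc in enumerate(encodings):
        n = len(enc.token_ids)
        ids[i, :n] = enc.token_ids
        pos[i, :n] = enc.positions + position_offset
        mask[i, :n] = 1.0
        lens[i] = n
    return ids, pos, mask, lens
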