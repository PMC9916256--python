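"""Sentence preprocessing for DDI text classification.

A sentence mentioning n drugs yields ``n(n-1)/2`` candidate drug pairs
(the triangular sum ``max(0, sum_{i=1..n} (i-1))``). For each pair the
sentence is *drug-blinded*: the earlier focal mention becomes "DrugA",
the later "DrugB", and every other drug mention "DrugN", so a classifier
learns relational cues rather than memorizing drug names. Blinded tokens
are then mapped through an embedding matrix ``WEMB`` (shape ds x |V|,
token i picked out as column ``v_i``) into fixed-length ``T x ds``
sequences, post-padded with the PAD vector or truncated.

Cleaning is deliberately light: lowercasing, punctuation stripping and a
small rule-based English lemmatizer (plural/-ing/-ed suffixes); drug
placeholders are exempt from cleaning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AnnotatedSentence",
    "BlindedSentence",
    "EmbeddingMatrix",
    "count_drug_pairs",
    "blind_drugs",
    "clean_tokens",
    "build_vocab",
    "embed_sentence",
    "read_sentence_corpus",
    "read_word2vec_text",
    "write_word2vec_text",
]

PAD = "<pad>"
UNK = "<unk>"
PLACEHOLDERS = ("DrugA", "DrugB", "DrugN")

_punct_re = re.compile(r"[^\w]+", flags=re.UNICODE)


@dataclass(frozen=True)
class AnnotatedSentence:
    """Tokenized sentence with 0-based half-open drug-mention spans."""

    tokens: tuple[str, ...]
    drug_mentions: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        spans = sorted((s, e) for s, e, _ in self.drug_mentions)
        for s, e, name in self.drug_mentions:
            if not (0 <= s < e <= n):
                raise ValueError(f"mention span ({s}, {e}) outside token range 0..{n}")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping mention spans ({s1},{e1}) and ({s2},{e2})")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_mentions)


@dataclass(frozen=True)
class BlindedSentence:
    """Sentence with the focal pair blinded to DrugA/DrugB, others to DrugN."""

    tokens: tuple[str, ...]
    pair: tuple[str, str]


def count_drug_pairs(n: int) -> int:
    """Number of candidate drug pairs in a sentence with n drug mentions.

    Evaluates the triangular sum ``max(0, sum_{i=1..n} (i-1))``, which
    equals ``n(n-1)/2``.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise TypeError(f"n must be an integer, got {type(n).__name__}")
    if n < 0:
        raise ValueError("n must be >= 0")
    return max(0, sum(i - 1 for i in range(1, n + 1)))


def blind_drugs(sentence: AnnotatedSentence) -> list[BlindedSentence]:
    """Enumerate blinded sentences, one per unordered focal drug pair.

    Mentions are taken in token order; for the pair (a, b) with a earlier,
    a's span collapses to the single token "DrugA", b's to "DrugB", and
    every non-focal mention to "DrugN". Sentences with fewer than two
    mentions yield an empty list.
    """
    mentions = sorted(sentence.drug_mentions, key=lambda m: (m[0], m[1]))
    n = len(mentions)
    out: list[BlindedSentence] = []
    for ai in range(n):
        for bi in range(ai + 1, n):
            tokens: list[str] = []
            t = 0
            span_map = {}
            for k, (s, e, _name) in enumerate(mentions):
                label = "DrugA" if k == ai else "DrugB" if k == bi else "DrugN"
                span_map[s] = (e, label)
            while t < len(sentence.tokens):
                if t in span_map:
                    e, label = span_map[t]
                    tokens.append(label)
                    t = e
                else:
                    tokens.append(sentence.tokens[t])
                    t += 1
            out.append(BlindedSentence(tuple(tokens), (mentions[ai][2], mentions[bi][2])))
    return out


_LEMMA_RULES = (
    ("sses", "ss"), ("ies", "y"), ("ied", "y"),
    ("ing", ""), ("edly", ""), ("ed", ""), ("s", ""),
)


def _lemmatize(token: str) -> str:
    """Tiny rule-based suffix lemmatizer for English content words."""
    for suffix, repl in _LEMMA_RULES:
        if token.endswith(suffix) and len(token) - len(suffix) + len(repl) >= 3:
            return token[: len(token) - len(suffix)] + repl
    return token


def clean_tokens(tokens) -> list[str]:
    """Lowercase, strip punctuation and lemmatize; placeholders pass through."""
    out = []
    for tok in tokens:
        if tok in PLACEHOLDERS:
            out.append(tok)
            continue
        t = _punct_re.sub("", tok.lower())
        if t:
            out.append(_lemmatize(t))
    return out


def build_vocab(corpus, min_count: int = 1) -> dict[str, int]:
    """Frequency-filtered vocabulary with reserved PAD (0) and UNK (1).

    Tokens with corpus frequency >= min_count get contiguous indices in
    first-appearance order after the two specials.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be non-empty")
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = {PAD: 0, UNK: 1}
    for tok, cnt in counts.items():
        if cnt >= min_count and tok not in vocab:
            vocab[tok] = len(vocab)
    return vocab


@dataclass
class EmbeddingMatrix:
    """Word embedding matrix WEMB of shape ds x |V| with its vocabulary.

    Token i's vector is column i. PAD's column is fixed at zero; UNK is
    the lookup for out-of-vocabulary tokens.
    """

    matrix: np.ndarray
    vocab: dict[str, int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.vocab):
            raise ValueError(
                f"matrix must be ds x |V| = ds x {len(self.vocab)}, got {self.matrix.shape}"
            )
        if PAD not in self.vocab or UNK not in self.vocab:
            raise ValueError("vocab must contain the PAD and UNK specials")
        if self.vocab[PAD] == self.vocab[UNK]:
            raise ValueError("PAD and UNK indices must be distinct")
        idx = sorted(self.vocab.values())
        if idx != list(range(len(self.vocab))):
            raise ValueError("vocab indices must be contiguous from 0")

    @property
    def ds(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def random(cls, vocab: dict[str, int], ds: int, seed: int = 0) -> "EmbeddingMatrix":
        rng = np.random.default_rng(seed)
        mat = rng.normal(0.0, 0.1, size=(ds, len(vocab)))
        mat[:, vocab[PAD]] = 0.0
        return cls(mat, dict(vocab))

    def lookup(self, token: str) -> np.ndarray:
        return self.matrix[:, self.vocab.get(token, self.vocab[UNK])]


def embed_sentence(blinded: BlindedSentence, emb: EmbeddingMatrix, T: int) -> np.ndarray:
    """Map a blinded sentence to a fixed-length T x ds real sequence.

    Token i becomes column ``v_i`` of WEMB (UNK for out-of-vocabulary
    tokens); sequences shorter than T are post-padded with the PAD
    column, longer ones truncated.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    out = np.tile(emb.matrix[:, emb.vocab[PAD]], (T, 1))
    for i, tok in enumerate(blinded.tokens[:T]):
        out[i] = emb.lookup(tok)
    return out


def read_sentence_corpus(path: str | Path) -> list[AnnotatedSentence]:
    """Read a UTF-8 TSV corpus: sentence_id, text, mentions.

    ``mentions`` is a semicolon-separated list of ``start:end:name``
    triples over whitespace tokens of ``text`` (0-based, half-open); an
    empty field means no mentions.
    """
    sentences = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sentence_id", "text", "mentions"]:
            raise ValueError(f"{path}: expected header sentence_id\\ttext\\tmentions")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: ragged row")
            text = parts[1]
            mention_field = parts[2] if len(parts) > 2 else ""
            mentions = []
            if mention_field:
                for triple in mention_field.split(";"):
                    try:
                        s, e, name = triple.split(":", 2)
                        mentions.append((int(s), int(e), name))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: bad mention triple {triple!r}"
                        ) from exc
            sentences.append(
                AnnotatedSentence(tuple(text.split()), tuple(mentions))
            )
    return sentences


def read_word2vec_text(path: str | Path) -> EmbeddingMatrix:
    """Load an embedding from word2vec text format ("count dim" header)."""
    with open(path, encoding="utf-8") as fh:
        head = fh.readline().split()
        if len(head) != 2:
            raise ValueError(f"{path}: expected 'count dim' header")
        count, dim = int(head[0]), int(head[1])
        vocab: dict[str, int] = {}
        mat = np.empty((dim, count))
        for i in range(count):
            parts = fh.readline().rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: row {i} has {len(parts) - 1} values, expected {dim}")
            if parts[0] in vocab:
                raise ValueError(f"{path}: duplicate token {parts[0]!r}")
            vocab[parts[0]] = i
            mat[:, i] = [float(v) for v in parts[1:]]
    return EmbeddingMatrix(mat, vocab)


def write_word2vec_text(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Write an embedding in word2vec text format; inverse of the reader."""
    inv = {i: tok for tok, i in emb.vocab.items()}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb.vocab)} {emb.ds}\n")
        for i in range(len(emb.vocab)):
            vec = " ".join(repr(float(v)) for v in emb.matrix[:, i])
            fh.write(f"{inv[i]} {vec}\n")
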