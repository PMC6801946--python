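"""Per-token feature channels: word embeddings, char-CNN vectors, POS one-hots.

Three independent channels, each of which can be switched off for ablation
runs, concatenated in the fixed order word ‖ char ‖ POS.  Word vectors come
from plain-text word2vec/GloVe files (or random initialization for tokens
the file lacks); character vectors from :class:`hner.nn.CharCNN`; POS
one-hots from a pluggable Penn-Treebank tagger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .nn import CharCNN

__all__ = [
    "PTB_TAGS",
    "EmbeddingTable",
    "CharConvSpec",
    "FeatureConfig",
    "load_embeddings",
    "save_embeddings",
    "char_features",
    "pos_features",
    "concat_features",
    "RuleBasedPosTagger",
    "StubPosTagger",
]

#: Penn Treebank tagset (word-level tags), plus an unknown bucket.
PTB_TAGS = (
    "CC CD DT EX FW IN JJ JJR JJS LS MD NN NNS NNP NNPS PDT POS PRP PRP$ "
    "RB RBR RBS RP SYM TO UH VB VBD VBG VBN VBP VBZ WDT WP WP$ WRB UNK"
).split()

UNK_TOKEN = "<unk>"
PAD_TOKEN = "<pad>"


@dataclass
class EmbeddingTable:
    """Word-vector lookup with reserved unknown/padding rows."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # (|V|, d_w)
    trainable: bool = True

    def __post_init__(self):
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError("vocabulary size does not match vector rows")
        for special in (PAD_TOKEN, UNK_TOKEN):
            if special not in self.vocabulary:
                raise ValueError(f"missing reserved row {special!r}")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def index(self, token: str) -> int:
        return self.vocabulary.get(token, self.vocabulary[UNK_TOKEN])

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors[self.index(token)]

    @classmethod
    def random(cls, vocab: Sequence[str], dim: int, seed: int,
               trainable: bool = True) -> "EmbeddingTable":
        """Uniform[-0.25, 0.25] table over a vocabulary (no pre-trained file)."""
        rng = np.random.default_rng(seed)
        words = [PAD_TOKEN, UNK_TOKEN] + [w for w in vocab
                                          if w not in (PAD_TOKEN, UNK_TOKEN)]
        vecs = rng.uniform(-0.25, 0.25, size=(len(words), dim))
        vecs[0] = 0.0  # padding row stays zero
        return cls({w: i for i, w in enumerate(words)}, vecs, trainable)


def load_embeddings(path: str | Path, vocab: Sequence[str], seed: int,
                    trainable: bool = True) -> EmbeddingTable:
    """Read a word2vec/GloVe plain-text embedding file for a vocabulary.

    Both dialects are auto-detected: a first line of exactly two integers is
    treated as the word2vec ``count dim`` header, otherwise every line is
    ``token v1 ... vd``.  Tokens absent from the file are initialized
    uniform in [-0.25, 0.25] from ``seed``; the padding row is zero.

    Raises ``ValueError`` naming the offending line on inconsistent vector
    lengths.
    """
    wanted = set(vocab)
    file_vecs: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2 and all(
                    p.lstrip("-").isdigit() for p in parts):
                dim = int(parts[1])  # word2vec header
                continue
            token, floats = parts[0], parts[1:]
            if dim is None:
                dim = len(floats)
            if len(floats) != dim:
                raise ValueError(
                    f"{path}: line {lineno}: expected {dim} floats, "
                    f"got {len(floats)}")
            if token in wanted:
                file_vecs[token] = np.asarray(floats, dtype=np.float64)
    if dim is None:
        raise ValueError(f"{path}: no vectors found")
    rng = np.random.default_rng(seed)
    words = [PAD_TOKEN, UNK_TOKEN] + [w for w in vocab
                                      if w not in (PAD_TOKEN, UNK_TOKEN)]
    vecs = np.empty((len(words), dim))
    vecs[0] = 0.0
    vecs[1] = rng.uniform(-0.25, 0.25, size=dim)
    for i, w in enumerate(words[2:], start=2):
        if w in file_vecs:
            vecs[i] = file_vecs[w]
        else:
            vecs[i] = rng.uniform(-0.25, 0.25, size=dim)
    return EmbeddingTable({w: i for i, w in enumerate(words)}, vecs, trainable)


def save_embeddings(table: EmbeddingTable, path: str | Path,
                    header: bool = True) -> None:
    """Write an EmbeddingTable as word2vec text (float32-round-trippable)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(table.vocabulary)} {table.dim}\n")
        for w, i in sorted(table.vocabulary.items(), key=lambda kv: kv[1]):
            vals = " ".join(repr(float(np.float32(v))) for v in table.vectors[i])
            fh.write(f"{w} {vals}\n")


@dataclass
class CharConvSpec:
    """Topology of the character CNN (width-3, three layers, 50 outputs)."""

    char_vocab: dict[str, int] = field(default_factory=CharCNN.default_vocab)
    char_dim: int = 25
    conv_width: int = 3
    n_layers: int = 3
    out_channels: int = 50

    def build(self, rng: np.random.Generator) -> CharCNN:
        return CharCNN(self.char_vocab, self.char_dim, self.out_channels,
                       self.conv_width, self.n_layers, rng)


def char_features(token: str, cnn: CharCNN) -> np.ndarray:
    """Character-CNN feature vector for a single token (inference only)."""
    if not token:
        raise ValueError("char_features requires a non-empty token")
    return cnn(cnn.encode_tokens([token])).data[0]


class RuleBasedPosTagger:
    """Deterministic suffix/lexicon Penn-Treebank tagger.

    A lightweight stand-in good enough to provide the auxiliary POS channel:
    a small closed-class lexicon plus suffix heuristics, defaulting to NN.
    """

    LEXICON = {
        "if": "IN", "in": "IN", "on": "IN", "at": "IN", "of": "IN",
        "for": "IN", "with": "IN", "after": "IN", "into": "IN",
        "you": "PRP", "i": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
        "we": "PRP", "they": "PRP",
        "your": "PRP$", "my": "PRP$", "his": "PRP$", "her": "PRP$",
        "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
        "and": "CC", "or": "CC", "but": "CC",
        "ever": "RB", "never": "RB", "not": "RB", "very": "RB", "way": "NN",
        "to": "TO", "is": "VBZ", "are": "VBP", "was": "VBD", "be": "VB",
        "feel": "VBP", "have": "VBP", "has": "VBZ",
        "unwell": "JJ", "can": "MD", "will": "MD", "may": "MD",
    }
    SUFFIXES = [
        ("ing", "VBG"), ("ed", "VBD"), ("ly", "RB"), ("est", "JJS"),
        ("ous", "JJ"), ("ful", "JJ"), ("able", "JJ"), ("ive", "JJ"),
        ("s", "NNS"),
    ]

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        tags = []
        for tok in tokens:
            low = tok.lower()
            if low.isdigit():
                tags.append("CD")
            elif low in self.LEXICON:
                tags.append(self.LEXICON[low])
            else:
                for suf, tag in self.SUFFIXES:
                    if len(low) > len(suf) + 2 and low.endswith(suf):
                        tags.append(tag)
                        break
                else:
                    tags.append("NN")
        return tags


class StubPosTagger:
    """Maps every token to one fixed tag; deterministic test double."""

    def __init__(self, tag: str = "NN"):
        self.tag = tag

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        return [self.tag] * len(tokens)


def pos_features(tokens: Sequence[str],
                 tagger: Callable[[Sequence[str]], Sequence[str]],
                 tagset: Sequence[str] = PTB_TAGS) -> np.ndarray:
    """One-hot POS matrix (n_tokens, |tagset|); unknown tags hit the UNK bucket."""
    tags = list(tagger(tokens))
    if len(tags) != len(tokens):
        raise ValueError(
            f"tagger returned {len(tags)} tags for {len(tokens)} tokens")
    index = {t: i for i, t in enumerate(tagset)}
    unk = index["UNK"]
    out = np.zeros((len(tokens), len(tagset)))
    for r, tag in enumerate(tags):
        out[r, index.get(tag, unk)] = 1.0
    return out


@dataclass
class FeatureConfig:
    """Which channels feed the encoder; the ablation grid is their product."""

    use_word: bool = True
    use_char: bool = True
    use_pos: bool = True
    finetune_embeddings: bool = True

    def __post_init__(self):
        if not (self.use_word or self.use_char or self.use_pos):
            raise ValueError("at least one feature channel must be enabled")

    @property
    def label(self) -> str:
        parts = [n for n, on in (("word", self.use_word), ("char", self.use_char),
                                 ("POS", self.use_pos)) if on]
        return " + ".join(parts)


def concat_features(word: np.ndarray | None, char: np.ndarray | None,
                    pos: np.ndarray | None) -> np.ndarray:
    """Concatenate enabled channels in fixed word ‖ char ‖ POS order.

    Disabled channels are passed as ``None`` and contribute zero width.
    """
    parts = [p for p in (word, char, pos) if p is not None]
    if not parts:
        raise ValueError("no feature channel enabled")
    return np.concatenate(parts, axis=-1)
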