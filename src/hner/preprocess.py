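"""Cleaning, tokenization and filtering of short noisy messages.

The cleaning pipeline mirrors what is commonly done to tweets before
dictionary-based concept matching: drop URLs and hashtag tokens whole,
strip every character outside ``[A-Za-z0-9 ]``, lowercase, and collapse
whitespace.  Tokenization is plain whitespace splitting on the cleaned
string, with character offsets kept so spans can be mapped back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Token",
    "Document",
    "clean_text",
    "tokenize",
    "make_document",
    "filter_min_words",
    "filter_has_entity",
    "read_corpus",
    "write_corpus",
]

_URL_RE = re.compile(r"^http", re.IGNORECASE)
_NON_ALNUM_RE = re.compile(r"[^a-z0-9 ]")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class Token:
    """A surface token with half-open character offsets into clean_text."""

    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.surface):
            raise ValueError(f"offset span {self.start}:{self.end} does not "
                             f"match surface {self.surface!r}")


@dataclass
class Document:
    """A single message: raw text, cleaned text, and offset-bearing tokens."""

    doc_id: str
    raw_text: str
    clean_text: str
    tokens: list[Token] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


def clean_text(raw: str, *, keep_digits: bool = True) -> str:
    """Normalize a raw message to a lowercase alphanumeric-and-space string.

    Rules, applied in order: drop whitespace-delimited tokens starting with
    ``http``/``https`` (URLs) or ``#`` (hashtags); remove every remaining
    character outside the kept alphabet; lowercase; collapse whitespace runs
    to single spaces and strip the ends.  Idempotent by construction.

    Parameters
    ----------
    raw
        Arbitrary unicode input; the empty string maps to itself.
    keep_digits
        If False, digits are treated as out-of-alphabet characters and
        removed along with punctuation.
    """
    pieces = []
    for tok in raw.split():
        if _URL_RE.match(tok) or tok.startswith("#"):
            continue
        pieces.append(tok)
    text = " ".join(pieces).lower()
    text = _NON_ALNUM_RE.sub("", text)
    if not keep_digits:
        text = re.sub(r"[0-9]", "", text)
    return _WS_RE.sub(" ", text).strip()


def tokenize(clean: str) -> list[Token]:
    """Split cleaned text on spaces, attaching character offsets.

    Requires input in `clean_text` form (single spaces, no leading or
    trailing whitespace), so offsets can be recovered by simple arithmetic.
    """
    tokens: list[Token] = []
    pos = 0
    for part in clean.split(" ") if clean else []:
        tokens.append(Token(part, pos, pos + len(part)))
        pos += len(part) + 1
    return tokens


def make_document(doc_id: str, raw_text: str, *, keep_digits: bool = True) -> Document:
    """Clean and tokenize one raw message into a Document."""
    cleaned = clean_text(raw_text, keep_digits=keep_digits)
    return Document(doc_id=doc_id, raw_text=raw_text, clean_text=cleaned,
                    tokens=tokenize(cleaned))


def filter_min_words(docs: Iterable[Document], min_words: int = 5) -> list[Document]:
    """Keep documents with at least ``min_words`` tokens, preserving order."""
    return [d for d in docs if len(d.tokens) >= min_words]


def filter_has_entity(docs: Sequence[Document],
                      annotations: Sequence[Sequence]) -> list[Document]:
    """Keep documents whose annotation span list is non-empty.

    ``annotations`` is aligned with ``docs`` (one span list per document).
    """
    if len(docs) != len(annotations):
        raise ValueError("docs and annotations must be aligned")
    return [d for d, spans in zip(docs, annotations) if spans]


def read_corpus(path: str | Path, *, keep_digits: bool = True) -> list[Document]:
    """Read a one-document-per-line UTF-8 corpus.

    A leading ``doc_id<TAB>`` column is honoured when present; otherwise
    line numbers (0-based) become document ids.
    """
    docs = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" in line:
                doc_id, text = line.split("\t", 1)
            else:
                doc_id, text = str(i), line
            docs.append(make_document(doc_id, text, keep_digits=keep_digits))
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path,
                 *, clean: bool = True, with_ids: bool = True) -> None:
    """Write documents one per line, optionally with a doc_id column."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            text = d.clean_text if clean else d.raw_text
            fh.write(f"{d.doc_id}\t{text}\n" if with_ids else text + "\n")
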