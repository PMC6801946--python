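"""Distant-supervision annotation against a medical concept dictionary.

Documents are scanned with a sliding window of 1..``window`` consecutive
tokens; each window surface is compared to every dictionary term by Jaccard
similarity over character 3-gram sets.  Candidates above the threshold are
resolved greedily by score, filtered through per-type stoplists, and emitted
as typed, token-indexed entity spans (the UMLS semantic types used here are
T047 "disease or syndrome", T184 "sign or symptom" and T121 "pharmacologic
substance").  Spans convert to and from per-token BIO tag sequences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .preprocess import Document

__all__ = [
    "SEMANTIC_TYPES",
    "ConceptDictionary",
    "EntitySpan",
    "ngram_set",
    "jaccard",
    "match_candidates",
    "resolve_overlaps",
    "apply_stoplist",
    "normalize_term",
    "spans_to_bio",
    "bio_to_spans",
    "annotate_document",
    "annotate_corpus",
    "read_dictionary",
    "write_annotations_jsonl",
    "write_conll",
    "read_conll",
]

logger = logging.getLogger(__name__)

#: UMLS semantic types accepted for the health-NER task.
SEMANTIC_TYPES = ("T047", "T184", "T121")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed entity mention over a token range [token_start, token_end)."""

    token_start: int
    token_end: int
    type_id: str
    score: float = 1.0
    matched_term: str = ""
    surface: str = ""
    canonical: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.token_start < self.token_end):
            raise ValueError(f"bad span bounds {self.token_start}:{self.token_end}")

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.token_start < other.token_end and other.token_start < self.token_end

    @property
    def key(self) -> tuple[int, int, str]:
        """Exact-match identity: boundaries plus type."""
        return (self.token_start, self.token_end, self.type_id)


class ConceptDictionary:
    """Surface term -> semantic type + canonical form, with per-type stoplists.

    Stands in for the join of UMLS MRCONSO (terms) and MRSTY (semantic
    types).  Terms are lowercase; one term may carry several types.
    """

    def __init__(self,
                 entries: Iterable[tuple[str, str, str]] = (),
                 stoplist: Iterable[tuple[str, str]] = ()) -> None:
        self.entries: set[tuple[str, str, str]] = set()
        self.stoplist: dict[str, set[str]] = {t: set() for t in SEMANTIC_TYPES}
        for term, type_id, canonical in entries:
            self.add(term, type_id, canonical)
        for term, type_id in stoplist:
            self.add_stop(term, type_id)

    def add(self, term: str, type_id: str, canonical: str | None = None) -> None:
        term = term.strip().lower()
        if not term:
            raise ValueError("dictionary terms must be non-empty")
        self.entries.add((term, type_id, (canonical or term).strip().lower()))

    def add_stop(self, term: str, type_id: str) -> None:
        self.stoplist.setdefault(type_id, set()).add(term.strip().lower())

    @property
    def terms(self) -> set[str]:
        return {t for t, _, _ in self.entries}

    def types_of(self, term: str) -> set[str]:
        return {ty for t, ty, _ in self.entries if t == term}

    def is_stopped(self, surface: str, type_id: str) -> bool:
        return surface in self.stoplist.get(type_id, set())

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(sorted(self.entries))


def ngram_set(s: str, n: int = 3) -> frozenset[str]:
    """Set of all contiguous length-``n`` substrings of ``s``.

    Strings shorter than ``n`` contribute themselves as a single gram, so
    similarity remains defined for very short terms.
    """
    if not s:
        raise ValueError("ngram_set requires a non-empty string")
    if len(s) < n:
        return frozenset((s,))
    return frozenset(s[i:i + n] for i in range(len(s) - n + 1))


def jaccard(a: str, b: str, n: int = 3) -> float:
    """Jaccard similarity |G(a) ∩ G(b)| / |G(a) ∪ G(b)| over character n-grams."""
    ga, gb = ngram_set(a, n), ngram_set(b, n)
    return len(ga & gb) / len(ga | gb)


def match_candidates(doc: Document, dictionary: ConceptDictionary,
                     window: int = 5, threshold: float = 0.7,
                     n: int = 3) -> list[EntitySpan]:
    """Enumerate every dictionary hit over token windows of width 1..window.

    A window surface (tokens joined with single spaces) matching a term with
    Jaccard strictly above ``threshold`` yields one candidate per (span,
    term, type).  Candidates may overlap; see :func:`resolve_overlaps`.
    """
    if len(dictionary) == 0:
        raise ValueError("empty concept dictionary")
    surfaces = doc.surfaces
    # Precompute gram sets per term once; grouped by term length band for a
    # cheap pruning bound: |A∩B|/|A∪B| ≤ min/max of the set sizes.
    term_grams = {term: ngram_set(term, n) for term in dictionary.terms}
    cands: list[EntitySpan] = []
    for i in range(len(surfaces)):
        for j in range(i + 1, min(i + window, len(surfaces)) + 1):
            surface = " ".join(surfaces[i:j])
            sg = ngram_set(surface, n)
            for term, type_id, canonical in dictionary.entries:
                tg = term_grams[term]
                bound = min(len(sg), len(tg)) / max(len(sg), len(tg))
                if bound <= threshold:
                    continue
                score = len(sg & tg) / len(sg | tg)
                if score > threshold:
                    cands.append(EntitySpan(i, j, type_id, score, term,
                                            surface, canonical))
    return cands


def resolve_overlaps(cands: Sequence[EntitySpan],
                     criterion: str = "score") -> list[EntitySpan]:
    """Greedy non-overlapping selection by score.

    Candidates are ranked by (score desc, span length desc, leftmost first,
    type id asc) and accepted when they share no token with an already
    accepted span.  Output is sorted by token_start and pairwise disjoint;
    the function is idempotent on its own output.
    """
    if criterion != "score":
        raise ValueError(f"unknown overlapping criterion {criterion!r}")
    ranked = sorted(
        cands,
        key=lambda s: (-s.score, -(s.token_end - s.token_start),
                       s.token_start, s.type_id),
    )
    accepted: list[EntitySpan] = []
    for cand in ranked:
        if not any(cand.overlaps(a) for a in accepted):
            accepted.append(cand)
    return sorted(accepted, key=lambda s: s.token_start)


def apply_stoplist(spans: Iterable[EntitySpan],
                   dictionary: ConceptDictionary) -> list[EntitySpan]:
    """Drop spans whose surface is stoplisted for their semantic type."""
    return [s for s in spans if not dictionary.is_stopped(s.surface, s.type_id)]


def normalize_term(surface: str, dictionary: ConceptDictionary,
                   threshold: float = 0.7, n: int = 3) -> str:
    """Map a surface form to the canonical form of its closest dictionary term.

    Returns the canonical form of the highest-Jaccard term when that
    similarity is strictly above ``threshold``; ties break lexicographically
    on the canonical form; below threshold the surface is returned unchanged.
    """
    if not surface:
        raise ValueError("normalize_term requires a non-empty surface")
    best_sim, best_canon = threshold, None
    for term, _type_id, canonical in sorted(dictionary.entries,
                                            key=lambda e: e[2]):
        sim = jaccard(surface, term, n)
        if sim > best_sim:
            best_sim, best_canon = sim, canonical
    return best_canon if best_canon is not None else surface


def spans_to_bio(doc_or_len: Document | int,
                 spans: Sequence[EntitySpan]) -> list[str]:
    """Encode non-overlapping spans as one BIO tag per token.

    The first token of a span gets ``B-<type>``, later tokens ``I-<type>``,
    everything else ``O``.  Overlapping spans are a caller error.
    """
    n_tokens = doc_or_len if isinstance(doc_or_len, int) else len(doc_or_len)
    tags = ["O"] * n_tokens
    ordered = sorted(spans, key=lambda s: s.token_start)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping spans {a.key} and {b.key}")
    for s in ordered:
        if s.token_end > n_tokens:
            raise ValueError(f"span {s.key} exceeds document length {n_tokens}")
        tags[s.token_start] = f"B-{s.type_id}"
        for t in range(s.token_start + 1, s.token_end):
            tags[t] = f"I-{s.type_id}"
    return tags


def bio_to_spans(tags: Sequence[str]) -> list[EntitySpan]:
    """Decode BIO tags to maximal spans, repairing dangling I- tags.

    An ``I-T`` not preceded by a same-type ``B-T``/``I-T`` is treated as
    ``B-T`` (a warning is logged): the decoder therefore always returns a
    legal, non-overlapping span set, even for ill-formed tag sequences.
    """
    spans: list[EntitySpan] = []
    start, cur_type = None, None
    for idx, tag in enumerate(tags):
        if tag == "O":
            prefix, ttype = "O", None
        elif tag.startswith(("B-", "I-")) and len(tag) > 2:
            prefix, ttype = tag[0], tag[2:]
        else:
            raise ValueError(f"unknown BIO tag {tag!r} at position {idx}")
        if prefix == "I" and cur_type == ttype and start is not None:
            continue  # extend the open span
        if start is not None:
            spans.append(EntitySpan(start, idx, cur_type))
            start, cur_type = None, None
        if prefix == "B":
            start, cur_type = idx, ttype
        elif prefix == "I":  # dangling I- : repair to B-
            logger.warning("repairing dangling I-%s at position %d", ttype, idx)
            start, cur_type = idx, ttype
    if start is not None:
        spans.append(EntitySpan(start, len(tags), cur_type))
    return spans


def annotate_document(doc: Document, dictionary: ConceptDictionary,
                      window: int = 5, threshold: float = 0.7,
                      normalize: bool = True) -> list[EntitySpan]:
    """Full per-document annotation: match, resolve, stoplist, normalize."""
    cands = match_candidates(doc, dictionary, window=window, threshold=threshold)
    spans = apply_stoplist(resolve_overlaps(cands), dictionary)
    if normalize:
        spans = [
            EntitySpan(s.token_start, s.token_end, s.type_id, s.score,
                       s.matched_term, s.surface,
                       normalize_term(s.surface, dictionary, threshold))
            for s in spans
        ]
    return spans


def annotate_corpus(docs: Sequence[Document], dictionary: ConceptDictionary,
                    window: int = 5, threshold: float = 0.7) -> list[list[EntitySpan]]:
    """Annotate every document; returns one span list per document."""
    return [annotate_document(d, dictionary, window, threshold) for d in docs]


# ---------------------------------------------------------------------------
# File formats


def read_dictionary(dict_path: str | Path,
                    stoplist_path: str | Path | None = None) -> ConceptDictionary:
    """Read a TSV concept dictionary (term / type_id / canonical).

    Lines starting with ``#`` are comments.  A missing canonical column
    defaults to the term itself.  The optional stoplist file is TSV with
    columns term / type_id.
    """
    d = ConceptDictionary()
    with open(dict_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"dictionary line needs >=2 columns: {line!r}")
            term, type_id = cols[0], cols[1]
            canonical = cols[2] if len(cols) > 2 and cols[2] else term
            d.add(term, type_id, canonical)
    if stoplist_path is not None:
        with open(stoplist_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term, type_id = line.split("\t")[:2]
                d.add_stop(term, type_id)
    return d


def write_dictionary(dictionary: ConceptDictionary, dict_path: str | Path,
                     stoplist_path: str | Path | None = None) -> None:
    with open(dict_path, "w", encoding="utf-8") as fh:
        fh.write("# term\ttype_id\tcanonical\n")
        for term, type_id, canonical in dictionary:
            fh.write(f"{term}\t{type_id}\t{canonical}\n")
    if stoplist_path is not None:
        with open(stoplist_path, "w", encoding="utf-8") as fh:
            fh.write("# term\ttype_id\n")
            for type_id in sorted(dictionary.stoplist):
                for term in sorted(dictionary.stoplist[type_id]):
                    fh.write(f"{term}\t{type_id}\n")


def write_annotations_jsonl(docs: Sequence[Document],
                            spans_per_doc: Sequence[Sequence[EntitySpan]],
                            path: str | Path) -> None:
    """One JSON object per document: doc_id, tokens, typed scored spans."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc, spans in zip(docs, spans_per_doc):
            obj = {
                "doc_id": doc.doc_id,
                "tokens": doc.surfaces,
                "spans": [
                    {"token_start": s.token_start, "token_end": s.token_end,
                     "type_id": s.type_id, "score": round(s.score, 6),
                     "canonical": s.canonical or s.matched_term}
                    for s in spans
                ],
            }
            fh.write(json.dumps(obj) + "\n")


def read_annotations_jsonl(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_conll(docs: Sequence[Document],
                spans_per_doc: Sequence[Sequence[EntitySpan]],
                path: str | Path) -> None:
    """Two-column token<TAB>tag export, blank line between documents."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc, spans in zip(docs, spans_per_doc):
            tags = spans_to_bio(doc, spans)
            for tok, tag in zip(doc.surfaces, tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def read_conll(path: str | Path) -> list[tuple[list[str], list[str]]]:
    """Read token<TAB>tag data; returns (tokens, tags) per document."""
    out: list[tuple[list[str], list[str]]] = []
    toks: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if toks:
                    out.append((toks, tags))
                    toks, tags = [], []
                continue
            tok, tag = line.split("\t")
            toks.append(tok)
            tags.append(tag)
    if toks:
        out.append((toks, tags))
    return out
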