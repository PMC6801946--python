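"""Synthetic concept dictionary and tweet-like corpus with gold annotations.

Provides a fully self-contained stand-in for the ontology-derived data the
pipeline normally consumes: a dictionary of pronounceable pseudo-terms
assigned round-robin to the three semantic types (plus a small stoplist and
a few multi-token terms), and short documents of filler words with 1–3
planted dictionary terms.  Planted terms can be corrupted by one terminal
character edit (final-character deletion or duplication — the error forms
that term normalization is meant to repair), while gold spans always record
the uncorrupted canonical entry.  Everything is deterministic under the
spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import (SEMANTIC_TYPES, ConceptDictionary, EntitySpan,
                       spans_to_bio, write_annotations_jsonl, write_conll,
                       write_dictionary)
from .preprocess import Document, tokenize

__all__ = ["SynthSpec", "SynthDoc", "gen_dictionary", "gen_corpus",
           "split_corpus", "write_fixtures"]

_CONSONANTS = list("bcdfghjklmnpqrstvz")
_VOWELS = list("aeiou")

#: Filler vocabulary: frequent tweet-like words; generation re-rolls any
#: pseudo-term that collides with these, so gold spans are unambiguous.
FILLER_WORDS = (
    "the and you for with that this from have just like what about when "
    "they will your more some time good know going really think today great "
    "news people love life back need want look feel made them over then "
    "other after first well work still never say said week year day very"
).split()

#: Surfaces planted occasionally so the per-type stoplists have work to do.
STOP_TERMS = {"T047": ("condition", "disease"), "T184": ("fit", "weight"),
              "T121": ("water", "program")}


@dataclass
class SynthSpec:
    """Generator settings: corpus size, corruption rate, split fractions."""

    n_terms_per_type: int = 10
    n_docs: int = 200
    misspell_rate: float = 0.1
    min_words: int = 5
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stop_plant_rate: float = 0.05
    min_term_len: int = 4
    max_term_len: int = 14

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0.0 <= self.misspell_rate <= 1.0):
            raise ValueError("misspell_rate must be a probability")
        if min(self.n_terms_per_type, self.n_docs) < 1:
            raise ValueError("counts must be positive")


@dataclass
class SynthDoc:
    """A generated document with its gold annotation."""

    doc: Document
    spans: list[EntitySpan]

    @property
    def tags(self) -> list[str]:
        return spans_to_bio(self.doc, self.spans)


def _pseudo_word(rng: np.random.Generator, min_len: int = 4,
                 max_len: int = 14) -> str:
    """Pronounceable CV-syllable word of length in [min_len, max_len]."""
    target = int(rng.integers(min_len, max_len + 1))
    chars = []
    while len(chars) < target:
        chars.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        chars.append(_VOWELS[rng.integers(len(_VOWELS))])
    return "".join(chars[:target])


def gen_dictionary(spec: SynthSpec) -> ConceptDictionary:
    """Build the toy concept dictionary: round-robin types, a few
    multi-token terms, and per-type stoplists."""
    rng = np.random.default_rng(spec.seed)
    forbidden = set(FILLER_WORDS)
    d = ConceptDictionary()
    n_total = spec.n_terms_per_type * len(SEMANTIC_TYPES)
    made: list[str] = []
    while len(made) < n_total:
        # every 5th term is multi-token (2-3 words) to exercise the window
        if (len(made) + 1) % 5 == 0:
            n_words = 2 + int(rng.integers(0, 2))
            term = " ".join(
                _pseudo_word(rng, spec.min_term_len,
                             max(spec.min_term_len, 8))
                for _ in range(n_words))
        else:
            term = _pseudo_word(rng, spec.min_term_len, spec.max_term_len)
        if term in forbidden or any(w in forbidden for w in term.split()):
            continue
        forbidden.add(term)
        made.append(term)
    for i, term in enumerate(made):
        d.add(term, SEMANTIC_TYPES[i % len(SEMANTIC_TYPES)], term)
    for type_id, stops in STOP_TERMS.items():
        for s in stops:
            d.add(s, type_id, s)
            d.add_stop(s, type_id)
    return d


def _corrupt(term: str, rng: np.random.Generator) -> str:
    """One terminal-character edit: delete or duplicate the final character."""
    last_word = term.split(" ")[-1]
    if rng.random() < 0.5 and len(last_word) > 1:
        return term[:-1]
    return term + term[-1]


def gen_corpus(dictionary: ConceptDictionary,
               spec: SynthSpec) -> list[SynthDoc]:
    """Generate documents of filler words with planted, optionally
    misspelled dictionary terms and exact gold spans.

    Every document has 5-20 filler words and 1-3 planted terms, so the
    minimum-length and has-entity corpus filters are satisfied by
    construction.  Stoplisted surfaces are planted at a small rate and are
    *not* gold spans (they are exactly the false positives the stoplist is
    there to suppress).
    """
    if len(dictionary) == 0:
        raise ValueError("dictionary must be non-empty")
    rng = np.random.default_rng(spec.seed + 1)
    plantable = sorted(set(dictionary.entries)
                       - {(t, ty, c) for t, ty, c in dictionary.entries
                          if dictionary.is_stopped(t, ty)})
    stop_pool = sorted((t, ty) for ty, terms in dictionary.stoplist.items()
                       for t in terms)
    docs: list[SynthDoc] = []
    for i in range(spec.n_docs):
        n_fill = int(rng.integers(max(spec.min_words, 5), 21))
        words = [FILLER_WORDS[rng.integers(len(FILLER_WORDS))]
                 for _ in range(n_fill)]
        n_plant = int(rng.integers(1, 4))
        inserts: list[tuple[str, str | None]] = []  # (surface words, type or None)
        for _ in range(n_plant):
            term, type_id, canonical = plantable[rng.integers(len(plantable))]
            surface = term
            if rng.random() < spec.misspell_rate:
                surface = _corrupt(term, rng)
            inserts.append((surface, type_id, canonical))
        if stop_pool and rng.random() < spec.stop_plant_rate:
            t, ty = stop_pool[rng.integers(len(stop_pool))]
            inserts.append((t, None, t))
        positions = sorted(rng.integers(0, len(words) + 1, size=len(inserts)))
        tokens: list[str] = []
        spans: list[EntitySpan] = []
        prev = 0
        for (surface, type_id, canonical), pos in zip(inserts, positions):
            tokens.extend(words[prev:pos])
            start = len(tokens)
            tokens.extend(surface.split(" "))
            if type_id is not None:
                spans.append(EntitySpan(start, len(tokens), type_id, 1.0,
                                        canonical, surface, canonical))
            prev = pos
        tokens.extend(words[prev:])
        clean = " ".join(tokens)
        doc = Document(doc_id=f"synth-{spec.seed}-{i}", raw_text=clean,
                       clean_text=clean, tokens=tokenize(clean))
        docs.append(SynthDoc(doc, spans))
    return docs


def split_corpus(docs: Sequence[SynthDoc], spec: SynthSpec
                 ) -> tuple[list[SynthDoc], list[SynthDoc], list[SynthDoc]]:
    """Seeded shuffle then contiguous split into train/validation/test."""
    rng = np.random.default_rng(spec.seed + 2)
    order = rng.permutation(len(docs))
    n = len(docs)
    n_train = int(round(spec.split_fractions[0] * n))
    n_val = int(round(spec.split_fractions[1] * n))
    cut2 = n_train + n_val
    parts = ([docs[i] for i in order[:n_train]],
             [docs[i] for i in order[n_train:cut2]],
             [docs[i] for i in order[cut2:]])
    if any(len(p) == 0 for p in parts):
        raise ValueError("a split is empty at the given sizes/fractions")
    return parts


def split_summary(parts: tuple[list[SynthDoc], ...]) -> dict[str, dict[str, int]]:
    """Per-subset, per-type span counts (corpus distribution table)."""
    out: dict[str, dict[str, int]] = {}
    for name, docs in zip(("train", "validation", "test"), parts):
        row = {t: 0 for t in SEMANTIC_TYPES}
        for sd in docs:
            for s in sd.spans:
                row[s.type_id] += 1
        row["docs"] = len(docs)
        out[name] = row
    return out


def write_fixtures(outdir: str | Path, spec: SynthSpec) -> dict:
    """Generate and write the full fixture set; returns the split summary.

    Writes corpus.txt, dict.tsv, stoplist.tsv, gold.jsonl, gold.conll and
    train/val/test .conll splits under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dictionary = gen_dictionary(spec)
    docs = gen_corpus(dictionary, spec)
    write_dictionary(dictionary, outdir / "dict.tsv", outdir / "stoplist.tsv")
    with open(outdir / "corpus.txt", "w", encoding="utf-8") as fh:
        for sd in docs:
            fh.write(f"{sd.doc.doc_id}\t{sd.doc.clean_text}\n")
    write_annotations_jsonl([sd.doc for sd in docs],
                            [sd.spans for sd in docs], outdir / "gold.jsonl")
    write_conll([sd.doc for sd in docs], [sd.spans for sd in docs],
                outdir / "gold.conll")
    parts = split_corpus(docs, spec)
    for name, part in zip(("train", "val", "test"), parts):
        write_conll([sd.doc for sd in part], [sd.spans for sd in part],
                    outdir / f"{name}.conll")
    return split_summary(parts)
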