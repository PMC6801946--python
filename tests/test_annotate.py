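import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hner.annotate import (ConceptDictionary, EntitySpan, annotate_document,
                           apply_stoplist, bio_to_spans, jaccard,
                           match_candidates, ngram_set, normalize_term,
                           read_dictionary, resolve_overlaps, spans_to_bio,
                           write_dictionary)
from hner.preprocess import make_document


# -- character n-grams and Jaccard -----------------------------------------

def test_ngram_set_enumeration():
    assert ngram_set("diabet", 3) == {"dia", "iab", "abe", "bet"}
    assert ngram_set("aaa", 3) == {"aaa"}
    assert ngram_set("ab", 3) == {"ab"}
    with pytest.raises(ValueError):
        ngram_set("")


@pytest.mark.parametrize("a,b,expected", [
    ("diabet", "diabeta", 0.80),
    ("alzheime", "alzheimer", 0.86),
    ("obesit", "obesity", 0.80),
    ("strains", "strain", 0.80),
    ("grimaced", "grimace", 0.83),
    ("illnesss", "illness", 0.83),
    ("marijuan", "marijuana", 0.86),
])
def test_jaccard_normalization_pairs(a, b, expected):
    """Similarities of known truncation/duplication misspelling pairs."""
    assert round(jaccard(a, b), 2) == expected


@given(st.text(alphabet="abcdef", min_size=1, max_size=12),
       st.text(alphabet="abcdef", min_size=1, max_size=12))
def test_jaccard_symmetric_bounded(a, b):
    s = jaccard(a, b)
    assert s == jaccard(b, a)
    assert 0.0 <= s <= 1.0
    assert jaccard(a, a) == 1.0


# -- candidate matching and overlap resolution ------------------------------

def _dict(*entries, stops=()):
    return ConceptDictionary(entries, stops)


def test_match_candidates_exact_and_fuzzy():
    d = _dict(("swine flu", "T047", "swine flu"), ("diabeta", "T121", "diabeta"))
    doc = make_document("x", "swine flu shot")
    cands = match_candidates(doc, d)
    assert any(c.token_start == 0 and c.token_end == 2 and c.score == 1.0
               and c.type_id == "T047" for c in cands)

    doc2 = make_document("y", "diabet")
    cands2 = match_candidates(doc2, d)
    assert len(cands2) == 1
    assert round(cands2[0].score, 2) == 0.80

    doc3 = make_document("z", "nothing matches here")
    assert match_candidates(doc3, d) == []


def test_match_candidates_respects_window():
    d = _dict(("a b c d e f", "T047", "x"))
    doc = make_document("w", "a b c d e f")
    for c in match_candidates(doc, d, window=5):
        assert c.token_end - c.token_start <= 5


def test_resolve_overlaps_greedy_by_score():
    a = EntitySpan(0, 2, "T047", 0.9)
    b = EntitySpan(1, 3, "T047", 0.8)
    assert resolve_overlaps([a, b]) == [a]

    disjoint = [EntitySpan(3, 4, "T121", 0.8), EntitySpan(0, 2, "T047", 0.9)]
    assert resolve_overlaps(disjoint) == sorted(disjoint,
                                                key=lambda s: s.token_start)

    nested_long = EntitySpan(0, 3, "T047", 0.8)
    nested_short = EntitySpan(1, 2, "T047", 0.8)
    assert resolve_overlaps([nested_short, nested_long]) == [nested_long]


def test_resolve_overlaps_idempotent_and_disjoint():
    cands = [EntitySpan(i, i + 2, t, s) for i, (t, s) in
             enumerate([("T047", .9), ("T184", .85), ("T121", .95),
                        ("T047", .8), ("T184", .99)])]
    out = resolve_overlaps(cands)
    for x, y in itertools.combinations(out, 2):
        assert not x.overlaps(y)
    assert resolve_overlaps(out) == out
    assert all(o in cands for o in out)


def _reference_greedy(cands):
    """Independently coded greedy-by-score selection."""
    chosen = []
    for c in sorted(cands, key=lambda s: (-s.score,
                                          -(s.token_end - s.token_start),
                                          s.token_start, s.type_id)):
        if all(c.token_end <= o.token_start or o.token_end <= c.token_start
               for o in chosen):
            chosen.append(c)
    return sorted(chosen, key=lambda s: s.token_start)


@given(st.data())
def test_resolve_overlaps_matches_reference_on_enumerated_candidates(data):
    """Greedy resolution agrees with an independent reference on small
    documents with exhaustively enumerated candidates."""
    words = data.draw(st.lists(
        st.text(alphabet="abcdegh", min_size=3, max_size=6),
        min_size=1, max_size=8))
    terms = data.draw(st.lists(
        st.text(alphabet="abcdegh", min_size=3, max_size=8),
        min_size=1, max_size=10))
    d = ConceptDictionary()
    for i, t in enumerate(terms):
        d.add(t, ["T047", "T184", "T121"][i % 3], t)
    doc = make_document("h", " ".join(words))
    if not doc.tokens:
        return
    cands = match_candidates(doc, d)
    assert resolve_overlaps(cands) == _reference_greedy(cands)


# -- stoplist and normalization ---------------------------------------------

def test_apply_stoplist_is_type_specific():
    d = _dict(("water", "T121", "water"), ("disease", "T047", "disease"),
              ("diabetes", "T047", "diabetes"),
              stops=[("water", "T121"), ("disease", "T047")])
    spans = [EntitySpan(0, 1, "T121", 1.0, surface="water"),
             EntitySpan(1, 2, "T047", 1.0, surface="disease"),
             EntitySpan(2, 3, "T047", 1.0, surface="diabetes"),
             EntitySpan(3, 4, "T047", 1.0, surface="water")]
    kept = apply_stoplist(spans, d)
    # "water" is only stoplisted for T121, so the T047 reading survives
    assert [s.surface for s in kept] == ["diabetes", "water"]


def test_normalize_term_picks_best_match():
    d = _dict(("marijuana", "T121", "marijuana"), ("illness", "T184", "illness"))
    assert normalize_term("marijuan", d) == "marijuana"
    assert normalize_term("illnesss", d) == "illness"
    assert normalize_term("marijuana", d) == "marijuana"
    assert normalize_term("zzzzz", d) == "zzzzz"  # below threshold: unchanged


def test_normalize_term_tie_breaks_lexicographically():
    d = _dict(("abcx", "T047", "abcx"), ("abcy", "T121", "abcy"))
    # "abcd" has equal similarity to both; lexicographically first canonical
    assert normalize_term("abc", d, threshold=0.2) == "abcx"


# -- BIO conversion ----------------------------------------------------------

def test_spans_to_bio_basic():
    assert spans_to_bio(3, [EntitySpan(0, 2, "T047")]) == \
        ["B-T047", "I-T047", "O"]
    assert spans_to_bio(3, []) == ["O", "O", "O"]
    with pytest.raises(ValueError):
        spans_to_bio(3, [EntitySpan(0, 2, "T047"), EntitySpan(1, 3, "T121")])


def test_bio_to_spans_decodes_and_repairs():
    assert [s.key for s in bio_to_spans(["B-T121", "I-T121", "O"])] == \
        [(0, 2, "T121")]
    assert bio_to_spans(["O", "O"]) == []
    repaired = bio_to_spans(["I-T047", "O"])
    assert [s.key for s in repaired] == [(0, 1, "T047")]
    with pytest.raises(ValueError):
        bio_to_spans(["B-T047", "X"])


@given(st.lists(st.sampled_from(
    ["O", "B-T047", "I-T047", "B-T184", "I-T184", "B-T121", "I-T121"]),
    max_size=12))
def test_bio_round_trip_from_any_tags(tags):
    """Decoding any tag sequence yields disjoint spans; re-encoding and
    re-decoding is then a fixed point."""
    spans = bio_to_spans(tags)
    for a, b in itertools.combinations(spans, 2):
        assert not a.overlaps(b)
    again = bio_to_spans(spans_to_bio(len(tags), spans))
    assert [s.key for s in again] == [s.key for s in spans]


# -- full annotation and file formats ---------------------------------------

def test_annotate_document_end_to_end():
    d = _dict(("swine flu", "T047", "swine flu"),
              ("marijuana", "T121", "marijuana"),
              stops=[("water", "T121")])
    d.add("water", "T121", "water")
    doc = make_document("t", "got swine flu after marijuan and water")
    spans = annotate_document(doc, d)
    assert [(s.key, s.canonical) for s in spans] == \
        [((1, 3, "T047"), "swine flu"), ((4, 5, "T121"), "marijuana")]


def test_dictionary_tsv_round_trip(tmp_path):
    d = _dict(("flu", "T047", "influenza"), ("aspirin", "T121", "aspirin"),
              stops=[("water", "T121")])
    write_dictionary(d, tmp_path / "d.tsv", tmp_path / "s.tsv")
    back = read_dictionary(tmp_path / "d.tsv", tmp_path / "s.tsv")
    assert back.entries == d.entries
    assert back.stoplist["T121"] == {"water"}
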