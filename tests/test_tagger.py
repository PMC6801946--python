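import numpy as np
import pytest

from hner.annotate import bio_to_spans
from hner.autograd import Tensor
from hner.evaluation import report
from hner.features import EmbeddingTable, FeatureConfig
from hner.nn import LSTMLayer
from hner.tagger import HnerTagger, TagSet, TrainConfig, train


def _pairs(docs):
    return [(sd.doc.surfaces, sd.tags) for sd in docs]


def _model(pairs, seed=1, **cfg_kw):
    cfg = TrainConfig(lstm_state=16, word_dim=16, seed=seed, **cfg_kw)
    vocab = sorted({t for toks, _ in pairs for t in toks})
    table = EmbeddingTable.random(vocab, cfg.word_dim, cfg.seed)
    return HnerTagger(TagSet.for_types(), table, cfg), cfg


# -- tag set -------------------------------------------------------------------

def test_tagset_layout_and_coding():
    ts = TagSet.for_types()
    assert ts.tags == ("O", "B-T047", "I-T047", "B-T184", "I-T184",
                       "B-T121", "I-T121")
    assert len(ts) == 7
    np.testing.assert_array_equal(ts.encode(["O", "B-T121", "I-T121"]),
                                  [0, 5, 6])
    assert ts.decode([0, 1, 2]) == ["O", "B-T047", "I-T047"]
    with pytest.raises(ValueError):
        ts.encode(["B-XXX"])


# -- encoder -------------------------------------------------------------------

def test_encoder_output_shapes(tiny_synth):
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    model, _ = _model(pairs)
    T = len(pairs[0][0])
    assert model.encode(pairs[0][0]).shape == (T, 32)

    uni, _ = _model(pairs, bidirectional=False)
    assert uni.encode(pairs[0][0]).shape == (T, 16)
    with pytest.raises(ValueError):
        uni.encode(pairs[0][0], direction="bidirectional")
    with pytest.raises(ValueError):
        uni.encode([])


def test_lstm_reverse_pass_mirrors_reversed_input(rng):
    """Running the backward direction equals running the forward direction
    on the reversed sequence, state for state (shared parameters)."""
    layer = LSTMLayer(d_in=5, d_hidden=7, rng=rng)
    x = rng.normal(size=(2, 6, 5))
    mask = np.ones((2, 6))
    rev = layer(Tensor(x), mask, reverse=True).data
    fwd_on_reversed = layer(Tensor(x[:, ::-1]), mask).data
    np.testing.assert_allclose(rev, fwd_on_reversed[:, ::-1], atol=1e-12)


def test_lstm_masking_freezes_state(rng):
    """Padding positions leave the carried state untouched, so a padded
    batch gives the same per-sequence states as unpadded processing."""
    layer = LSTMLayer(d_in=4, d_hidden=3, rng=rng)
    x_short = rng.normal(size=(1, 3, 4))
    x_padded = np.concatenate([x_short, rng.normal(size=(1, 2, 4))], axis=1)
    mask = np.array([[1.0, 1.0, 1.0, 0.0, 0.0]])
    h_padded = layer(Tensor(x_padded), mask).data
    h_short = layer(Tensor(x_short), np.ones((1, 3))).data
    np.testing.assert_allclose(h_padded[:, :3], h_short, atol=1e-12)
    # frozen state is carried into the padded tail
    np.testing.assert_allclose(h_padded[:, 3], h_short[:, 2], atol=1e-12)


# -- training ------------------------------------------------------------------

def test_training_overfits_small_corpus(tiny_synth):
    """Capacity check: the tagger memorizes a 12-document corpus."""
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    model, cfg = _model(pairs, learning_rate=0.01, epochs=60, patience=60)
    hist = train(model, pairs, pairs, cfg)
    gold = [bio_to_spans(tags) for _, tags in pairs]
    pred = model.predict_spans([toks for toks, _ in pairs])
    assert report(gold, pred).micro["F"] == 1.0
    assert hist.epoch_loss[-1] < hist.epoch_loss[0]


def test_training_is_deterministic_under_seed(tiny_synth):
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    losses = []
    for _ in range(2):
        model, cfg = _model(pairs, seed=5, epochs=1, patience=5)
        hist = train(model, pairs, pairs, cfg)
        losses.append(hist.epoch_loss[0])
    assert losses[0] == losses[1]


def test_early_stopping_patience(tiny_synth):
    """With a validation set that has no entities, weighted F1 stays zero
    and training stops after exactly `patience` stalled epochs."""
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    val = [(["just", "filler", "words", "here", "now"], ["O"] * 5)]
    model, cfg = _model(pairs, epochs=50, patience=3)
    hist = train(model, pairs, val, cfg)
    # epoch 0 improves over the initial -inf; epochs 1..3 stall
    assert len(hist.epoch_loss) == 4
    assert hist.stopped_epoch == 3


def test_train_input_validation(tiny_synth):
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    model, cfg = _model(pairs)
    with pytest.raises(ValueError):
        train(model, [], pairs, cfg)
    with pytest.raises(ValueError):
        train(model, pairs, [], cfg)


def test_predict_outputs_legal_spans_untrained(tiny_synth):
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    model, _ = _model(pairs)
    assert model.predict([]) == []
    spans = model.predict(pairs[0][0])
    for a in spans:
        assert 0 <= a.token_start < a.token_end <= len(pairs[0][0])
        for b in spans:
            assert a is b or not a.overlaps(b)
    one = model.predict([pairs[0][0][0]])
    assert all(s.key[:2] == (0, 1) for s in one)


def test_transition_masking_forbids_illegal_decodes(tiny_synth):
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    model, _ = _model(pairs, mask_illegal=True)
    for tags in model.predict_tags([toks for toks, _ in pairs[:6]]):
        prev = "O"
        for t in tags:
            if t.startswith("I-"):
                assert prev in (f"B-{t[2:]}", f"I-{t[2:]}")
            prev = t


# -- feature ablations ---------------------------------------------------------

@pytest.mark.parametrize("fc", [
    FeatureConfig(True, False, False),
    FeatureConfig(False, True, False),
    FeatureConfig(False, False, True),
    FeatureConfig(True, True, False),
])
def test_ablated_models_run(tiny_synth, fc):
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    cfg = TrainConfig(lstm_state=8, word_dim=8, seed=0)
    vocab = sorted({t for toks, _ in pairs for t in toks})
    table = EmbeddingTable.random(vocab, 8, 0) if fc.use_word else None
    model = HnerTagger(TagSet.for_types(), table, cfg, fc)
    tags = model.predict_tags([pairs[0][0]])[0]
    assert len(tags) == len(pairs[0][0])


def test_frozen_embeddings_do_not_move(tiny_synth):
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    cfg = TrainConfig(lstm_state=8, word_dim=8, seed=0, epochs=2, patience=5)
    vocab = sorted({t for toks, _ in pairs for t in toks})
    table = EmbeddingTable.random(vocab, 8, 0, trainable=False)
    model = HnerTagger(TagSet.for_types(), table, cfg,
                       FeatureConfig(finetune_embeddings=False))
    before = model.E_word.data.copy()
    train(model, pairs, pairs, cfg)
    np.testing.assert_array_equal(model.E_word.data, before)

    tuned = HnerTagger(TagSet.for_types(),
                       EmbeddingTable.random(vocab, 8, 0), cfg)
    before_t = tuned.E_word.data.copy()
    train(tuned, pairs, pairs, cfg)
    assert not np.array_equal(tuned.E_word.data, before_t)


# -- persistence ---------------------------------------------------------------

def test_checkpoint_round_trip(tmp_path, tiny_synth):
    _, _, docs = tiny_synth
    pairs = _pairs(docs)
    model, cfg = _model(pairs, epochs=2, patience=5)
    train(model, pairs, pairs, cfg)
    preds = model.predict_tags([toks for toks, _ in pairs])
    path = tmp_path / "model.npz"
    model.save(path)
    back = HnerTagger.load(path)
    assert back.tagset == model.tagset
    assert back.config == model.config
    assert back.predict_tags([toks for toks, _ in pairs]) == preds
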