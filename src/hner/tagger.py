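"""Char-CNN + (Bi)LSTM + CRF sequence tagger and its training loop.

The model maps token sequences to BIO tag sequences over the three medical
semantic types.  Per-token features (word embedding ‖ char-CNN ‖ POS
one-hot) pass through a dropout mask, a stacked uni- or bidirectional LSTM,
and a linear projection to per-tag emission scores; a linear-chain CRF
scores tag sequences globally and Viterbi decoding returns the argmax
sequence.  Training minimizes the CRF negative log-likelihood with Nadam
(Adam with Nesterov momentum) and early-stops on validation support-weighted
exact-match F1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import evaluation
from .annotate import SEMANTIC_TYPES, EntitySpan, bio_to_spans
from .autograd import Tensor, concat
from .crf import CRFParams, crf_nll_batch, viterbi_decode
from .features import (PTB_TAGS, CharConvSpec, EmbeddingTable, FeatureConfig,
                       RuleBasedPosTagger, pos_features)
from .nn import Dropout, Linear, LSTMLayer, Module, Nadam, Parameter, uniform

__all__ = ["TagSet", "TrainConfig", "HnerTagger", "TrainHistory", "train"]

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class TagSet:
    """Ordered BIO tag inventory; O first, then B-/I- per semantic type."""

    tags: tuple[str, ...]

    @classmethod
    def for_types(cls, types: Sequence[str] = SEMANTIC_TYPES) -> "TagSet":
        tags = ["O"]
        for t in types:
            tags += [f"B-{t}", f"I-{t}"]
        return cls(tuple(tags))

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tags)}

    def __len__(self) -> int:
        return len(self.tags)

    def encode(self, bio: Sequence[str]) -> np.ndarray:
        idx = self.index
        try:
            return np.array([idx[t] for t in bio], dtype=int)
        except KeyError as e:
            raise ValueError(f"tag {e.args[0]!r} not in tag set") from None

    def decode(self, indices: Sequence[int]) -> list[str]:
        return [self.tags[i] for i in indices]


@dataclass
class TrainConfig:
    """Training and encoder hyperparameters.

    Defaults are the reference configuration for the task: 2 recurrent
    layers of state size 250, learning rate 0.001, at most 100 epochs with
    early-stopping patience 20, dropout 0.5 on the concatenated embedding,
    batch size 100.  All overridable; small synthetic corpora train well at
    ``lstm_state=50``.
    """

    lstm_state: int = 250
    lstm_layers: int = 2
    learning_rate: float = 0.001
    epochs: int = 100
    dropout: float = 0.5
    batch_size: int = 100
    patience: int = 20
    seed: int = 0
    bidirectional: bool = True
    word_dim: int = 50          # used when no pre-trained table is given
    grad_clip: float = 5.0
    mask_illegal: bool = False  # hard-mask O->I etc. transitions at decode


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class HnerTagger(Module):
    """The full tagging model; see the module docstring for the architecture."""

    def __init__(self, tagset: TagSet, word_table: EmbeddingTable | None,
                 config: TrainConfig,
                 feature_config: FeatureConfig | None = None,
                 char_spec: CharConvSpec | None = None,
                 pos_tagger: Callable[[Sequence[str]], Sequence[str]] | None = None):
        super().__init__()
        self.tagset = tagset
        self.config = config
        self.features = feature_config or FeatureConfig()
        self.char_spec = char_spec or CharConvSpec()
        self.pos_tagger = pos_tagger or RuleBasedPosTagger()
        rng = np.random.default_rng(config.seed)
        K = len(tagset)

        d_in = 0
        self.word_table = word_table if self.features.use_word else None
        if self.features.use_word:
            if word_table is None:
                raise ValueError("use_word requires an EmbeddingTable")
            trainable = word_table.trainable and self.features.finetune_embeddings
            if trainable:
                self.E_word = Parameter(word_table.vectors.copy())
            else:
                self.E_word = Tensor(word_table.vectors.copy())
            d_in += word_table.dim
        if self.features.use_char:
            self.char_cnn = self.char_spec.build(rng)
            d_in += self.char_spec.out_channels
        if self.features.use_pos:
            d_in += len(PTB_TAGS)

        self.drop = Dropout(config.dropout, np.random.default_rng(config.seed + 1))
        self.lstms: list[tuple[LSTMLayer, LSTMLayer | None]] = []
        H = config.lstm_state
        for layer in range(config.lstm_layers):
            fwd = LSTMLayer(d_in, H, rng)
            setattr(self, f"lstm_f{layer}", fwd)
            bwd = None
            if config.bidirectional:
                bwd = LSTMLayer(d_in, H, rng)
                setattr(self, f"lstm_b{layer}", bwd)
            self.lstms.append((fwd, bwd))
            d_in = H * (2 if config.bidirectional else 1)
        self.emit = Linear(d_in, K, rng)
        self.transitions = Parameter(uniform(rng, (K, K), scale=0.1))
        self.start = Parameter(np.zeros(K))
        self.end = Parameter(np.zeros(K))
        self._shuffle_rng = np.random.default_rng(config.seed + 2)

    # -- feature assembly ---------------------------------------------------

    def _pad_batch(self, token_lists: Sequence[Sequence[str]]):
        if not token_lists or any(len(t) == 0 for t in token_lists):
            raise ValueError("batch must contain non-empty token sequences")
        B = len(token_lists)
        T = max(len(t) for t in token_lists)
        mask = np.zeros((B, T))
        for b, toks in enumerate(token_lists):
            mask[b, :len(toks)] = 1.0
        return B, T, mask

    def _embed(self, token_lists: Sequence[Sequence[str]], B: int, T: int,
               mask: np.ndarray) -> Tensor:
        channels: list[Tensor] = []
        if self.features.use_word:
            idx = np.zeros((B, T), dtype=int)  # 0 = padding row
            for b, toks in enumerate(token_lists):
                for t, tok in enumerate(toks):
                    idx[b, t] = self.word_table.index(tok)
            channels.append(self.E_word[idx])
        if self.features.use_char:
            flat = [tok for toks in token_lists for tok in toks]
            feats = self.char_cnn(self.char_cnn.encode_tokens(flat))
            zero = Tensor(np.zeros((1, self.char_spec.out_channels)))
            feats = concat([feats, zero], axis=0)
            gather = np.full((B, T), len(flat), dtype=int)  # default: zero row
            k = 0
            for b, toks in enumerate(token_lists):
                for t in range(len(toks)):
                    gather[b, t] = k
                    k += 1
            channels.append(feats[gather])
        if self.features.use_pos:
            pos = np.zeros((B, T, len(PTB_TAGS)))
            for b, toks in enumerate(token_lists):
                pos[b, :len(toks)] = pos_features(toks, self.pos_tagger)
            channels.append(Tensor(pos))
        return concat(channels, axis=2) if len(channels) > 1 else channels[0]

    def _encode(self, token_lists: Sequence[Sequence[str]]):
        """Emission scores for a batch: Tensor (B, T, K), plus the mask."""
        B, T, mask = self._pad_batch(token_lists)
        x = self.drop(self._embed(token_lists, B, T, mask))
        for fwd, bwd in self.lstms:
            h_f = fwd(x, mask)
            x = concat([h_f, bwd(x, mask, reverse=True)], axis=2) if bwd else h_f
        K = len(self.tagset)
        emissions = self.emit(x.reshape(B * T, -1)).reshape(B, T, K)
        return emissions, mask

    def encode(self, tokens: Sequence[str],
               direction: str | None = None) -> np.ndarray:
        """Context matrix (T, H) for one sequence; inference mode.

        H = 2 * lstm_state for a bidirectional model (forward and backward
        states concatenated), lstm_state for the forward-only baseline.  The
        direction is a build-time property of the model; passing
        ``direction`` asserts it matches.
        """
        if not tokens:
            raise ValueError("cannot encode an empty sequence")
        if direction is not None:
            built = "bidirectional" if self.config.bidirectional else "forward"
            if direction != built:
                raise ValueError(
                    f"model was built {built}; rebuild with "
                    f"TrainConfig(bidirectional=...) to change direction")
        self.set_training(False)
        B, T, mask = self._pad_batch([list(tokens)])
        x = self._embed([list(tokens)], B, T, mask)
        for fwd, bwd in self.lstms:
            h_f = fwd(x, mask)
            x = concat([h_f, bwd(x, mask, reverse=True)], axis=2) if bwd else h_f
        return x.data[0]

    # -- inference ------------------------------------------------------------

    def _crf_params(self, emissions: np.ndarray) -> CRFParams:
        trans = self.transitions.data.copy()
        start = self.start.data.copy()
        if self.config.mask_illegal:
            NEG = -1e9
            idx = self.tagset.index
            for tag_i, i in idx.items():
                for tag_j, j in idx.items():
                    if tag_j.startswith("I-"):
                        ty = tag_j[2:]
                        if tag_i not in (f"B-{ty}", f"I-{ty}"):
                            trans[i, j] = NEG
            for tag_j, j in idx.items():
                if tag_j.startswith("I-"):
                    start[j] = NEG
        return CRFParams(emissions, trans, start, self.end.data)

    def predict_tags(self, token_lists: Sequence[Sequence[str]]) -> list[list[str]]:
        """Viterbi-decoded BIO tags per sequence."""
        self.set_training(False)
        out = []
        for chunk_start in range(0, len(token_lists), self.config.batch_size):
            chunk = [list(t) for t in
                     token_lists[chunk_start:chunk_start + self.config.batch_size]]
            emissions, mask = self._encode(chunk)
            for b, toks in enumerate(chunk):
                params = self._crf_params(emissions.data[b, :len(toks)])
                path, _ = viterbi_decode(params)
                out.append(self.tagset.decode(path))
        return out

    def predict(self, tokens: Sequence[str]) -> list[EntitySpan]:
        """Decode one document into non-overlapping typed spans."""
        if not tokens:
            return []
        return bio_to_spans(self.predict_tags([tokens])[0])

    def predict_spans(self, token_lists: Sequence[Sequence[str]]) -> list[list[EntitySpan]]:
        return [bio_to_spans(tags) for tags in self.predict_tags(token_lists)]

    # -- persistence ------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file .npz checkpoint: weights plus a JSON config record."""
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "tags": list(self.tagset.tags),
            "config": asdict(self.config),
            "features": asdict(self.features),
            "char_vocab": self.char_spec.char_vocab,
            "char_spec": {k: v for k, v in asdict(self.char_spec).items()
                          if k != "char_vocab"},
            "word_vocab": (self.word_table.vocabulary
                           if self.word_table is not None else None),
            "word_trainable": (self.word_table.trainable
                               if self.word_table is not None else None),
        }
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        if self.word_table is not None and "E_word" not in self.state_dict():
            arrays["frozen::E_word"] = self.E_word.data
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path,
             pos_tagger: Callable | None = None) -> "HnerTagger":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
            config = TrainConfig(**meta["config"])
            features = FeatureConfig(**meta["features"])
            char_spec = CharConvSpec(char_vocab=meta["char_vocab"],
                                     **meta["char_spec"])
            table = None
            if meta["word_vocab"] is not None:
                vocab = meta["word_vocab"]
                if "param::E_word" in data:
                    vecs = data["param::E_word"]
                else:
                    vecs = data["frozen::E_word"]
                table = EmbeddingTable(vocab, vecs,
                                       trainable=bool(meta["word_trainable"]))
            model = cls(TagSet(tuple(meta["tags"])), table, config, features,
                        char_spec, pos_tagger)
            state = {k[len("param::"):]: data[k] for k in data.files
                     if k.startswith("param::")}
            model.load_state_dict(state)
            if table is not None and not (table.trainable
                                          and features.finetune_embeddings):
                model.E_word.data = table.vectors.astype(np.float64).copy()
        return model


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(model: HnerTagger,
          train_pairs: Sequence[tuple[Sequence[str], Sequence[str]]],
          val_pairs: Sequence[tuple[Sequence[str], Sequence[str]]],
          config: TrainConfig | None = None,
          verbose: bool = False) -> TrainHistory:
    """Minibatch NLL training with early stopping on validation weighted F1.

    ``train_pairs``/``val_pairs`` are (tokens, BIO tags) per document.  After
    each epoch the validation set is decoded and the support-weighted mean
    of per-type exact-match F1 is monitored; training stops after
    ``patience`` epochs without improvement (or at the epoch cap) and the
    best-validation parameters are restored.
    """
    config = config or model.config
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be non-empty")
    tagset = model.tagset
    enc_train = [(list(toks), tagset.encode(tags)) for toks, tags in train_pairs]
    val_tokens = [list(toks) for toks, _ in val_pairs]
    val_gold = [bio_to_spans(list(tags)) for _, tags in val_pairs]

    opt = Nadam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_f1, best_state, wait = -1.0, model.state_dict(), 0
    rng = model._shuffle_rng

    for epoch in range(config.epochs):
        model.set_training(True)
        losses = []
        for batch_idx in _batches(len(enc_train), config.batch_size, rng):
            toks = [enc_train[i][0] for i in batch_idx]
            T = max(len(t) for t in toks)
            tags = np.zeros((len(batch_idx), T), dtype=int)
            for r, i in enumerate(batch_idx):
                tags[r, :len(enc_train[i][1])] = enc_train[i][1]
            emissions, mask = model._encode(toks)
            loss = crf_nll_batch(emissions, model.transitions, model.start,
                                 model.end, tags, mask)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            _clip_gradients(model, config.grad_clip)
            opt.step()
            losses.append(loss.item())
        history.epoch_loss.append(float(np.mean(losses)))

        pred = model.predict_spans(val_tokens)
        f1 = evaluation.weighted_f1(val_gold, pred)
        history.val_f1.append(f1)
        if verbose:
            print(f"epoch {epoch}: loss {history.epoch_loss[-1]:.4f} "
                  f"val weighted F1 {f1:.4f}")
        if f1 > best_f1 + 1e-12:
            best_f1, best_state, wait = f1, model.state_dict(), 0
            history.best_epoch = epoch
        else:
            wait += 1
            if wait >= config.patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = config.epochs - 1
    model.load_state_dict(best_state)
    return history


def _clip_gradients(model: Module, max_norm: float) -> None:
    grads = [p.grad for p in model.parameters().values() if p.grad is not None]
    if not grads or max_norm <= 0:
        return
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
    if total > max_norm:
        scale = max_norm / total
        for g in grads:
            g *= scale
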