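"""Neural building blocks for the sequence tagger, on the autograd core.

Everything operates on padded batches: sequences of length T in a batch of
B, with a {0,1} mask marking real positions.  The LSTM freezes its hidden
state at padded steps, so a reversed pass over a padded batch is exactly the
backward direction of a bidirectional encoder.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = ["Parameter", "Linear", "LSTMLayer", "CharCNN", "Dropout", "Nadam",
           "orthogonal", "uniform"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def uniform(rng: np.random.Generator, shape, scale: float | None = None,
            gain: float = 2.0) -> np.ndarray:
    """Glorot-style uniform init, scale = gain * sqrt(6 / (fan_in + fan_out)).

    The default gain of 2 compensates for the small dynamic range of the
    embedding channels feeding the network (word vectors in [-0.25, 0.25],
    one-hot POS rows): it puts gate pre-activations in a useful range from
    the first epoch, which matters at the configured learning rate.
    """
    if scale is None:
        scale = gain * np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-scale, scale, size=shape)


def orthogonal(rng: np.random.Generator, shape) -> np.ndarray:
    """Orthogonal init for recurrent weight blocks."""
    a = rng.standard_normal((max(shape), max(shape)))
    q, _ = np.linalg.qr(a)
    return q[: shape[0], : shape[1]].copy()


class Module:
    """Base class: parameter registry plus train/eval mode flag."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> dict[str, Parameter]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    def set_training(self, mode: bool):
        self.training = mode
        for child in self._children.values():
            child.set_training(mode)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if set(state) != set(params):
            raise ValueError("state dict keys do not match model parameters")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(uniform(rng, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep


class LSTMLayer(Module):
    """One direction, one layer; standard LSTM cell with forget-gate bias 1.

    Input (B, T, D) with mask (B, T); returns hidden states (B, T, H).  At
    masked steps the (h, c) state is carried through unchanged, so padding
    never leaks into real positions.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.d_hidden = d_hidden
        self.W = Parameter(uniform(rng, (d_in, 4 * d_hidden)))
        u = np.concatenate([orthogonal(rng, (d_hidden, d_hidden))
                            for _ in range(4)], axis=1)
        self.U = Parameter(u)
        bias = np.zeros(4 * d_hidden)
        bias[d_hidden:2 * d_hidden] = 1.0  # forget gate
        self.b = Parameter(bias)

    def __call__(self, x: Tensor, mask: np.ndarray, reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        H = self.d_hidden
        order = range(T - 1, -1, -1) if reverse else range(T)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor | None] = [None] * T
        xw = x.reshape(B * T, -1) @ self.W  # precompute input projections
        xw = xw.reshape(B, T, 4 * H)
        for t in order:
            gates = xw[:, t, :] + h @ self.U + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = mask[:, t].reshape(B, 1)
            h = h_new * m + h * (1.0 - m)
            c = c_new * m + c * (1.0 - m)
            outs[t] = h.reshape(B, 1, H)
        return concat(outs, axis=1)


class CharCNN(Module):
    """Character-level token features: embed, stacked convolutions, max-pool.

    Tokens are embedded per character, padded with begin/end-of-word
    boundary symbols, passed through ``n_layers`` stacked width-``width``
    ReLU convolutions with ``channels`` filters each, and max-pooled over
    positions into a fixed-size vector per token.
    """

    PAD, UNK, BOW, EOW = 0, 1, 2, 3

    def __init__(self, char_vocab: dict[str, int], char_dim: int,
                 channels: int, width: int, n_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.char_vocab = char_vocab
        self.char_dim = char_dim
        self.channels = channels
        self.width = width
        self.n_layers = n_layers
        n_chars = max(char_vocab.values()) + 1
        self.E = Parameter(uniform(rng, (n_chars, char_dim), scale=0.25))
        self.convs: list[Linear] = []
        d_in = char_dim
        for k in range(n_layers):
            conv = Linear(width * d_in, channels, rng)
            setattr(self, f"conv{k}", conv)
            self.convs.append(conv)
            d_in = channels

    @classmethod
    def default_vocab(cls) -> dict[str, int]:
        """Lowercase letters and digits plus pad/unk/boundary symbols."""
        vocab = {"<pad>": cls.PAD, "<unk>": cls.UNK, "<w>": cls.BOW, "</w>": cls.EOW}
        for ch in "abcdefghijklmnopqrstuvwxyz0123456789":
            vocab[ch] = len(vocab)
        return vocab

    def encode_tokens(self, tokens: list[str]) -> np.ndarray:
        """Index matrix (n_tokens, L) with boundary symbols and padding.

        L is chosen so that the stacked valid convolutions keep at least one
        output position for the shortest token.
        """
        if any(not t for t in tokens):
            raise ValueError("char features require non-empty tokens")
        shrink = self.n_layers * (self.width - 1)
        L = max(len(t) for t in tokens) + 2
        L = max(L, shrink + 1)
        idx = np.full((len(tokens), L), self.PAD, dtype=int)
        for r, tok in enumerate(tokens):
            seq = [self.BOW] + [self.char_vocab.get(ch, self.UNK) for ch in tok] \
                + [self.EOW]
            idx[r, :len(seq)] = seq
        return idx

    def __call__(self, char_idx: np.ndarray) -> Tensor:
        """(n_tokens, L) char indices -> (n_tokens, channels) features."""
        N, L = char_idx.shape
        x = self.E[char_idx.reshape(-1)].reshape(N, L, self.char_dim)
        for conv in self.convs:
            Lc = x.shape[1] - self.width + 1
            if Lc < 1:
                raise ValueError("token too short for the convolution stack")
            windows = concat([x[:, k:k + Lc, :] for k in range(self.width)],
                             axis=2)  # (N, Lc, width*d)
            x = conv(windows).relu()
        return x.max(axis=1)


class Nadam:
    """Adam with Nesterov momentum (Dozat 2016)."""

    def __init__(self, params: dict[str, Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** (self.t + 1))
            g_hat = g / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            update = b1 * m_hat + (1 - b1) * g_hat
            p.data -= self.lr * update / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
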