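"""Linear-chain conditional random field: scoring, partition, Viterbi.

A tag sequence y over T tokens and K tags is scored as

    score(y) = start[y_1] + sum_t emissions[t, y_t]
             + sum_{t>1} transitions[y_{t-1}, y_t] + end[y_T]

and P(y) = exp(score(y) - logZ) with logZ the log-partition over all K^T
sequences, computed exactly by the forward recursion in log space.  Decoding
is exact Viterbi with ties broken toward the lowest tag index.

The public functions are plain numpy and serve both as the inference path
and as the reference the differentiable training loss (see
:func:`crf_nll_batch`) is checked against; :func:`nll_gradient_emissions`
gives the analytic gradient (posterior marginals minus the gold indicator)
via the forward-backward algorithm, an independent route from autodiff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .autograd import Tensor

__all__ = [
    "CRFParams",
    "sequence_score",
    "log_partition",
    "nll_loss",
    "viterbi_decode",
    "nll_gradient_emissions",
    "posterior_marginals",
    "crf_nll_batch",
]


@dataclass
class CRFParams:
    """Scores defining a linear-chain CRF over one sequence.

    emissions: (T, K) per-token tag scores (the encoder's confidence scores);
    transitions: (K, K), ``transitions[i, j]`` scores tag j following tag i;
    start/end: (K,) boundary scores (zero vectors recover the matrix-only
    parameterization).
    """

    emissions: np.ndarray
    transitions: np.ndarray
    start: np.ndarray = None
    end: np.ndarray = None

    def __post_init__(self):
        self.emissions = np.asarray(self.emissions, dtype=np.float64)
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        T, K = self.emissions.shape
        if self.transitions.shape != (K, K):
            raise ValueError("transitions must be K x K")
        self.start = (np.zeros(K) if self.start is None
                      else np.asarray(self.start, dtype=np.float64))
        self.end = (np.zeros(K) if self.end is None
                    else np.asarray(self.end, dtype=np.float64))
        if self.start.shape != (K,) or self.end.shape != (K,):
            raise ValueError("start/end must be K-vectors")
        for arr in (self.emissions, self.transitions, self.start, self.end):
            if not np.all(np.isfinite(arr)):
                raise ValueError("CRF scores must be finite")

    @property
    def n_tokens(self) -> int:
        return self.emissions.shape[0]

    @property
    def n_tags(self) -> int:
        return self.emissions.shape[1]


def sequence_score(params: CRFParams, tags: Sequence[int]) -> float:
    """Unnormalized score of one tag sequence."""
    tags = np.asarray(tags, dtype=int)
    T, K = params.emissions.shape
    if tags.shape != (T,):
        raise ValueError(f"tag sequence length {tags.shape} != {T} tokens")
    if tags.min() < 0 or tags.max() >= K:
        raise ValueError("tag index out of range")
    s = params.start[tags[0]] + params.emissions[np.arange(T), tags].sum()
    s += params.transitions[tags[:-1], tags[1:]].sum()
    s += params.end[tags[-1]]
    return float(s)


def log_partition(params: CRFParams) -> float:
    """log sum over all K^T sequences of exp(sequence_score), forward recursion."""
    alpha = params.start + params.emissions[0]
    for t in range(1, params.n_tokens):
        alpha = logsumexp(alpha[:, None] + params.transitions, axis=0) \
            + params.emissions[t]
    return float(logsumexp(alpha + params.end))


def nll_loss(params: CRFParams, gold: Sequence[int]) -> float:
    """Negative log-likelihood −log P(gold) = logZ − score(gold); always ≥ 0."""
    return log_partition(params) - sequence_score(params, gold)


def viterbi_decode(params: CRFParams) -> tuple[list[int], float]:
    """Exact argmax tag sequence and its score.

    Ties break toward the lowest tag index at every backpointer (argmax on
    axis 0 returns the first maximizer).
    """
    T, K = params.emissions.shape
    delta = params.start + params.emissions[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + params.transitions  # (prev, cur)
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + params.emissions[t]
    delta = delta + params.end
    best_last = int(delta.argmax())
    best_score = float(delta[best_last])
    path = [best_last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, best_score


def posterior_marginals(params: CRFParams) -> tuple[np.ndarray, np.ndarray]:
    """Forward-backward: per-token tag marginals and pairwise marginals.

    Returns ``(gamma, xi)`` with gamma (T, K) the posterior P(y_t = k) and
    xi (T-1, K, K) the posterior P(y_t = i, y_{t+1} = j).
    """
    T, K = params.emissions.shape
    log_alpha = np.zeros((T, K))
    log_alpha[0] = params.start + params.emissions[0]
    for t in range(1, T):
        log_alpha[t] = logsumexp(log_alpha[t - 1][:, None] + params.transitions,
                                 axis=0) + params.emissions[t]
    log_beta = np.zeros((T, K))
    log_beta[-1] = params.end
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(params.transitions
                                + (params.emissions[t + 1] + log_beta[t + 1])[None, :],
                                axis=1)
    log_z = logsumexp(log_alpha[-1] + params.end)
    gamma = np.exp(log_alpha + log_beta - log_z)
    xi = np.empty((max(T - 1, 0), K, K))
    for t in range(T - 1):
        xi[t] = np.exp(log_alpha[t][:, None] + params.transitions
                       + (params.emissions[t + 1] + log_beta[t + 1])[None, :]
                       - log_z)
    return gamma, xi


def nll_gradient_emissions(params: CRFParams, gold: Sequence[int]) -> np.ndarray:
    """Analytic d(nll)/d(emissions): posterior marginals minus gold one-hot."""
    gold = np.asarray(gold, dtype=int)
    gamma, _ = posterior_marginals(params)
    grad = gamma.copy()
    grad[np.arange(params.n_tokens), gold] -= 1.0
    return grad


# ---------------------------------------------------------------------------
# Differentiable batched loss used by the training loop


def crf_nll_batch(emissions: Tensor, transitions: Tensor, start: Tensor,
                  end: Tensor, tags: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean per-sequence negative log-likelihood over a padded batch.

    emissions: Tensor (B, T, K); tags: int array (B, T); mask: {0,1} array
    (B, T) with at least one active position per row and left-aligned
    (mask[b] = 1..1 0..0).  Padded positions contribute nothing to either
    the gold score or the partition.
    """
    B, T, K = emissions.shape
    lengths = mask.sum(axis=1).astype(int)
    if np.any(lengths < 1):
        raise ValueError("every sequence in the batch must be non-empty")
    rows = np.arange(B)

    # gold path score
    gold = start[tags[:, 0]] + emissions[rows, 0, tags[:, 0]]
    for t in range(1, T):
        m = mask[:, t][None].T  # (B,1) -> scalar column
        step = transitions[tags[:, t - 1], tags[:, t]] \
            + emissions[rows, t, tags[:, t]]
        gold = gold + step * m[:, 0]
    gold = gold + end[tags[rows, lengths - 1]]

    # forward recursion in log space, frozen at padded steps
    alpha = start.reshape(1, K) + emissions[:, 0, :]
    for t in range(1, T):
        m = mask[:, t].reshape(B, 1)
        nxt = (alpha.reshape(B, K, 1) + transitions.reshape(1, K, K)) \
            .logsumexp(axis=1) + emissions[:, t, :]
        alpha = nxt * m + alpha * (1.0 - m)
    log_z = (alpha + end.reshape(1, K)).logsumexp(axis=1)

    return (log_z - gold).sum() * (1.0 / B)
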