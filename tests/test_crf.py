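"""CRF correctness against exhaustive enumeration on small instances."""

import itertools
import math

import numpy as np
import pytest

from hner.autograd import Tensor
from hner.crf import (CRFParams, crf_nll_batch, log_partition, nll_loss,
                      nll_gradient_emissions, posterior_marginals,
                      sequence_score, viterbi_decode)


def random_instance(rng, T=None, K=None):
    T = T or int(rng.integers(1, 6))
    K = K or int(rng.integers(1, 8))
    return CRFParams(rng.normal(size=(T, K)), rng.normal(size=(K, K)),
                     rng.normal(size=K), rng.normal(size=K))


def enumerate_scores(p):
    """Score every tag sequence by direct summation (independent oracle)."""
    out = {}
    for path in itertools.product(range(p.n_tags), repeat=p.n_tokens):
        s = p.start[path[0]] + p.end[path[-1]]
        for t, y in enumerate(path):
            s += p.emissions[t, y]
        for a, b in zip(path, path[1:]):
            s += p.transitions[a, b]
        out[path] = s
    return out


def test_sequence_score_hand_computed():
    p = CRFParams(emissions=[[1.0, 2.0], [0.5, -1.0], [3.0, 0.0]],
                  transitions=[[0.1, 0.2], [0.3, 0.4]],
                  start=[0.5, -0.5], end=[1.0, 2.0])
    # path (1, 0, 0): -0.5 + 2 + 0.3 + 0.5 + 0.1 + 3 + 1 = 6.4
    assert sequence_score(p, [1, 0, 0]) == pytest.approx(6.4)

    single = CRFParams(emissions=[[1.0, -2.0]], transitions=np.zeros((2, 2)),
                       start=[0.25, 0.0], end=[0.5, 0.0])
    assert sequence_score(single, [0]) == pytest.approx(1.75)

    zero_t = CRFParams(emissions=[[1.0, 4.0], [2.0, 0.0]],
                       transitions=np.zeros((2, 2)))
    assert sequence_score(zero_t, [1, 0]) == pytest.approx(6.0)

    with pytest.raises(ValueError):
        sequence_score(p, [0, 1])  # length mismatch


def test_log_partition_uniform_and_single_tag():
    T, K = 4, 5
    p = CRFParams(np.zeros((T, K)), np.zeros((K, K)))
    assert log_partition(p) == pytest.approx(T * math.log(K))

    p1 = CRFParams(np.array([[0.7], [0.1], [-2.0]]), np.array([[0.3]]),
                   np.array([0.2]), np.array([-0.1]))
    assert log_partition(p1) == pytest.approx(sequence_score(p1, [0, 0, 0]))
    assert nll_loss(p1, [0, 0, 0]) == pytest.approx(0.0, abs=1e-12)


def test_log_partition_and_viterbi_match_enumeration(rng):
    for _ in range(40):
        p = random_instance(rng)
        scores = enumerate_scores(p)
        vals = np.array(list(scores.values()))
        # log-partition
        m = vals.max()
        brute_logz = m + math.log(np.exp(vals - m).sum())
        assert log_partition(p) == pytest.approx(brute_logz, abs=1e-9)
        # viterbi attains the enumerated maximum
        path, sc = viterbi_decode(p)
        assert sc == pytest.approx(vals.max(), abs=1e-9)
        assert sequence_score(p, path) == pytest.approx(sc, abs=1e-9)
        # probabilities normalize
        probs = np.exp(vals - log_partition(p))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)


def test_viterbi_zero_transitions_is_pointwise_argmax(rng):
    em = rng.normal(size=(6, 4))
    p = CRFParams(em, np.zeros((4, 4)))
    path, _ = viterbi_decode(p)
    assert path == list(em.argmax(axis=1))


def test_viterbi_tie_breaks_to_lowest_index():
    p = CRFParams(np.zeros((3, 3)), np.zeros((3, 3)))
    path, _ = viterbi_decode(p)
    assert path == [0, 0, 0]


def test_nll_matches_enumerated_probability(rng):
    for _ in range(10):
        p = random_instance(rng)
        scores = enumerate_scores(p)
        vals = np.array(list(scores.values()))
        m = vals.max()
        logz = m + math.log(np.exp(vals - m).sum())
        gold = list(scores)[int(rng.integers(len(scores)))]
        assert nll_loss(p, list(gold)) == \
            pytest.approx(logz - scores[gold], abs=1e-9)
        assert nll_loss(p, list(gold)) >= -1e-12


def test_posterior_marginals_sum_to_one(rng):
    p = random_instance(rng, T=4, K=3)
    gamma, xi = posterior_marginals(p)
    np.testing.assert_allclose(gamma.sum(axis=1), np.ones(4), atol=1e-10)
    np.testing.assert_allclose(xi.sum(axis=(1, 2)), np.ones(3), atol=1e-10)
    # pairwise marginals are consistent with unary ones
    np.testing.assert_allclose(xi.sum(axis=2), gamma[:-1], atol=1e-10)
    np.testing.assert_allclose(xi.sum(axis=1), gamma[1:], atol=1e-10)


def test_analytic_emission_gradient_matches_numerical(rng):
    eps = 1e-6
    for _ in range(5):
        p = random_instance(rng)
        gold = [int(rng.integers(p.n_tags)) for _ in range(p.n_tokens)]
        analytic = nll_gradient_emissions(p, gold)
        for i in range(p.n_tokens):
            for k in range(p.n_tags):
                hi = p.emissions.copy()
                hi[i, k] += eps
                lo = p.emissions.copy()
                lo[i, k] -= eps
                num = (nll_loss(CRFParams(hi, p.transitions, p.start, p.end), gold)
                       - nll_loss(CRFParams(lo, p.transitions, p.start, p.end),
                                  gold)) / (2 * eps)
                assert analytic[i, k] == pytest.approx(num, abs=1e-5)


def test_batched_loss_equals_per_sequence_numpy_loss(rng):
    """The differentiable padded-batch loss agrees with the reference
    numpy implementation sequence by sequence, and its emission gradient
    matches the analytic forward-backward gradient."""
    B, T, K = 4, 5, 3
    em = rng.normal(size=(B, T, K))
    tr = rng.normal(size=(K, K))
    st = rng.normal(size=K)
    en = rng.normal(size=K)
    lengths = [5, 3, 1, 4]
    mask = np.zeros((B, T))
    tags = np.zeros((B, T), dtype=int)
    for b, L in enumerate(lengths):
        mask[b, :L] = 1
        tags[b, :L] = rng.integers(0, K, size=L)

    tE = Tensor(em, requires_grad=True)
    loss = crf_nll_batch(tE, Tensor(tr), Tensor(st), Tensor(en), tags, mask)
    loss.backward()

    ref = 0.0
    ref_grad = np.zeros_like(em)
    for b, L in enumerate(lengths):
        p = CRFParams(em[b, :L], tr, st, en)
        ref += nll_loss(p, tags[b, :L]) / B
        ref_grad[b, :L] = nll_gradient_emissions(p, tags[b, :L]) / B
    assert loss.data == pytest.approx(ref, abs=1e-10)
    np.testing.assert_allclose(tE.grad, ref_grad, atol=1e-10)


def test_crf_params_validation():
    with pytest.raises(ValueError):
        CRFParams(np.zeros((2, 3)), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        CRFParams(np.full((2, 2), np.nan), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        sequence_score(CRFParams(np.zeros((2, 2)), np.zeros((2, 2))), [0, 5])
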