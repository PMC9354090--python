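"""Linear-chain CRF against its exhaustive-enumeration oracle."""

import numpy as np
import pytest

from mlee.crf import (
    TransitionScores,
    brute_force_decode,
    brute_force_score,
    crf_log_partition,
    crf_nll,
    path_score,
    viterbi,
)


def _random_instance(rng, T=None, L=None):
    T = T or int(rng.integers(1, 6))
    L = L or int(rng.integers(1, 5))
    em = rng.normal(size=(T, L))
    tr = TransitionScores(
        matrix=rng.normal(size=(L, L)),
        start=rng.normal(size=L),
        end=rng.normal(size=L),
    )
    return em, tr


def test_uniform_partition_values():
    em = np.zeros((1, 3))
    assert crf_log_partition(em, TransitionScores.zeros(3)) == pytest.approx(np.log(3))
    em = np.zeros((2, 2))
    assert crf_log_partition(em, TransitionScores.zeros(2)) == pytest.approx(np.log(4))


def test_partition_matches_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(50):
        em, tr = _random_instance(rng)
        assert abs(crf_log_partition(em, tr) - brute_force_score(em, tr)) < 1e-8


def test_nll_uniform_and_degenerate():
    em = np.zeros((3, 2))
    tr = TransitionScores.zeros(2)
    assert crf_nll(em, tr, [0, 1, 0]) == pytest.approx(3 * np.log(2))
    # single-label space: only one path, NLL is exactly zero
    em1 = np.random.default_rng(0).normal(size=(4, 1))
    assert crf_nll(em1, TransitionScores.zeros(1), [0, 0, 0, 0]) == pytest.approx(0.0)


def test_nll_matches_enumeration_and_is_nonnegative():
    rng = np.random.default_rng(12)
    for _ in range(30):
        em, tr = _random_instance(rng)
        T, L = em.shape
        gold = list(rng.integers(0, L, size=T))
        expected = brute_force_score(em, tr) - path_score(em, tr, gold)
        got = crf_nll(em, tr, gold)
        assert abs(got - expected) < 1e-8
        assert got >= -1e-10


def test_viterbi_matches_enumeration():
    rng = np.random.default_rng(13)
    for _ in range(100):
        em, tr = _random_instance(rng)
        path = viterbi(em, tr)
        _, best = brute_force_decode(em, tr)
        assert abs(path_score(em, tr, path) - best) < 1e-8


def test_viterbi_degenerates_to_argmax_without_transitions():
    rng = np.random.default_rng(14)
    em = rng.normal(size=(6, 4))
    assert viterbi(em, TransitionScores.zeros(4)) == list(em.argmax(axis=1))
    # L=1 gives a constant sequence
    assert viterbi(rng.normal(size=(5, 1)), TransitionScores.zeros(1)) == [0] * 5


def test_normalization_over_paths():
    rng = np.random.default_rng(15)
    em, tr = _random_instance(rng, T=3, L=3)
    logz = crf_log_partition(em, tr)
    from itertools import product

    total = sum(
        np.exp(path_score(em, tr, p) - logz) for p in product(range(3), repeat=3)
    )
    assert total == pytest.approx(1.0, abs=1e-8)


def test_emission_shift_invariance():
    rng = np.random.default_rng(16)
    em, tr = _random_instance(rng, T=4, L=3)
    shifted = em.copy()
    shifted[2] += 7.5
    assert crf_log_partition(shifted, tr) == pytest.approx(
        crf_log_partition(em, tr) + 7.5
    )
    assert viterbi(shifted, tr) == viterbi(em, tr)


def test_masking_equals_label_deletion():
    rng = np.random.default_rng(17)
    em, tr = _random_instance(rng, T=4, L=4)
    mask = np.array([True, False, True, True])
    kept = np.nonzero(mask)[0]
    em_sub = em[:, kept]
    tr_sub = TransitionScores(
        matrix=tr.matrix[np.ix_(kept, kept)], start=tr.start[kept], end=tr.end[kept]
    )
    assert crf_log_partition(em, tr, mask) == pytest.approx(
        crf_log_partition(em_sub, tr_sub), abs=1e-8
    )
    assert [int(kept[i]) for i in viterbi(em_sub, tr_sub)] == viterbi(em, tr, mask)


def test_masked_gold_and_bad_shapes_rejected():
    em = np.zeros((2, 3))
    tr = TransitionScores.zeros(3)
    with pytest.raises(ValueError):
        crf_nll(em, tr, [0, 1], mask=np.array([True, False, True]))
    with pytest.raises(ValueError):
        crf_log_partition(em, TransitionScores.zeros(2))
    with pytest.raises(ValueError):
        crf_log_partition(em, tr, mask=np.zeros(3, dtype=bool))


def test_brute_force_refuses_huge_instances():
    with pytest.raises(ValueError):
        brute_force_score(np.zeros((30, 4)), TransitionScores.zeros(4))
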