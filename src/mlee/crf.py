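"""Linear-chain CRF mathematics shared by all tagging heads.

A path ``y_1..y_T`` over ``L`` labels is scored as

    score(y) = start[y_1] + sum_t em[t, y_t] + sum_t tr[y_{t-1}, y_t] + end[y_T]

and normalized over all paths: ``log P(y) = score(y) - log Z``.  Everything is
computed in log-space.  A boolean label mask restricts the decodable label set
for a given sequence (class-conditioned label-space restriction); masked
labels contribute ``-inf`` everywhere.

``brute_force_score`` / ``brute_force_decode`` enumerate all ``L**T`` paths
and exist purely as an independent oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "TransitionScores",
    "crf_log_partition",
    "crf_nll",
    "viterbi",
    "brute_force_score",
    "brute_force_decode",
]

NEG_INF = -1e30  # finite stand-in for -inf; keeps arithmetic NaN-free


@dataclass
class TransitionScores:
    """Pairwise potentials: an (L, L) matrix plus start/end vectors."""

    matrix: np.ndarray
    start: np.ndarray
    end: np.ndarray

    @classmethod
    def zeros(cls, n_labels: int) -> "TransitionScores":
        return cls(
            matrix=np.zeros((n_labels, n_labels)),
            start=np.zeros(n_labels),
            end=np.zeros(n_labels),
        )

    @property
    def n_labels(self) -> int:
        return self.matrix.shape[0]


def _check(em: np.ndarray, tr: TransitionScores, mask: np.ndarray | None) -> np.ndarray:
    em = np.asarray(em, dtype=float)
    if em.ndim != 2 or em.shape[0] < 1:
        raise ValueError(f"emissions must be (T, L), got shape {em.shape}")
    L = em.shape[1]
    if tr.matrix.shape != (L, L) or tr.start.shape != (L,) or tr.end.shape != (L,):
        raise ValueError("transition shapes inconsistent with emissions")
    if mask is None:
        mask = np.ones(L, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (L,):
        raise ValueError("mask must have one entry per label")
    if not mask.any():
        raise ValueError("label mask excludes every label")
    return mask


def _masked_emissions(em: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.array(em, dtype=float, copy=True)
    out[:, ~mask] = NEG_INF
    return out


def crf_log_partition(
    em: np.ndarray, tr: TransitionScores, mask: np.ndarray | None = None
) -> float:
    """log Z via the forward algorithm (log-sum-exp recursion)."""
    mask = _check(em, tr, mask)
    em = _masked_emissions(em, mask)
    alpha = tr.start + em[0]
    for t in range(1, em.shape[0]):
        alpha = logsumexp(alpha[:, None] + tr.matrix, axis=0) + em[t]
    return float(logsumexp(alpha + tr.end))


def path_score(
    em: np.ndarray, tr: TransitionScores, labels: Sequence[int]
) -> float:
    labels = list(labels)
    s = tr.start[labels[0]] + em[0, labels[0]] + tr.end[labels[-1]]
    for t in range(1, len(labels)):
        s += tr.matrix[labels[t - 1], labels[t]] + em[t, labels[t]]
    return float(s)


def crf_nll(
    em: np.ndarray,
    tr: TransitionScores,
    gold: Sequence[int],
    mask: np.ndarray | None = None,
) -> float:
    """Sequence-level negative log-likelihood of the gold path.

    Equals ``log Z - score(gold)``; non-negative up to numerical tolerance.
    With zero transitions this reduces to the sum of per-token cross-entropies.
    """
    mask = _check(em, tr, mask)
    gold = list(gold)
    if len(gold) != em.shape[0]:
        raise ValueError("gold length must equal sequence length")
    if any(not mask[g] for g in gold):
        raise ValueError("gold path uses a masked label")
    return crf_log_partition(em, tr, mask) - path_score(em, tr, gold)


def viterbi(
    em: np.ndarray, tr: TransitionScores, mask: np.ndarray | None = None
) -> list[int]:
    """Globally max-scoring label path; ties break toward the lowest index."""
    mask = _check(em, tr, mask)
    em = _masked_emissions(em, mask)
    T, L = em.shape
    delta = tr.start + em[0]
    back = np.zeros((T, L), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + tr.matrix  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # argmax returns the lowest index on ties
        delta = cand[back[t], np.arange(L)] + em[t]
    delta = delta + tr.end
    best = int(np.argmax(delta))
    path = [best]
    for t in range(T - 1, 0, -1):
        best = int(back[t, best])
        path.append(best)
    return path[::-1]


def _enumerable(em: np.ndarray, mask: np.ndarray) -> list[int]:
    T = em.shape[0]
    allowed = [i for i in range(em.shape[1]) if mask[i]]
    if len(allowed) ** T > 10**6:
        raise ValueError("instance too large for brute-force enumeration")
    return allowed


def brute_force_score(
    em: np.ndarray, tr: TransitionScores, mask: np.ndarray | None = None
) -> float:
    """log Z by exhaustive enumeration over all unmasked label sequences."""
    mask = _check(em, tr, mask)
    allowed = _enumerable(em, mask)
    scores = [
        path_score(em, tr, labels)
        for labels in product(allowed, repeat=em.shape[0])
    ]
    return float(logsumexp(scores))

def brute_force_decode(
    em: np.ndarray, tr: TransitionScores, mask: np.ndarray | None = None
) -> tuple[list[int], float]:
    """(best path, best score) by exhaustive enumeration; ties lexicographic."""
    mask = _check(em, tr, mask)
    allowed = _enumerable(em, mask)
    best_path: list[int] | None = None
    best_score = -np.inf
    for labels in product(allowed, repeat=em.shape[0]):
        s = path_score(em, tr, labels)
        if s > best_score:  # strict: first (lexicographically lowest) wins ties
            best_score, best_path = s, list(labels)
    assert best_path is not None
    return best_path, float(best_score)
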