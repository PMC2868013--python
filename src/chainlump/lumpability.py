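"""Expected conditional mutual information between past and future of an
aggregated Markov chain — the closedness measure behind every aggregation
technique in this package.

Given a stationary chain with distribution pi and a partition into
macro-states s_1..s_n, let P_i be the previous macro-state and F_i the next
macro-state conditioned on currently being in s_i (one step each way).  The
aggregated process is closed (Markov) exactly when P_i and F_i are
conditionally independent for every i, i.e. when

    <I> = sum_i Pr(s_i) * I(P_i; F_i) = 0,

with I(P_i; F_i) = H(P_i) + H(F_i) - H(P_i, F_i).  All entropies are in bits
(log base 2); only the zero-set of <I> matters for lumpability, so the base
is a pure reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotNormalized, ZeroMassBlock
from .markov import Partition, ProbabilityVector, TransitionMatrix, stationary_distribution

#: Partitions with <I> at or below this many bits count as lumpable in exact
#: synthetic settings.
TAU_EXACT = 1e-9

#: Looser default for empirically estimated matrices, which are never exactly
#: lumpable at machine precision.
TAU_EMPIRICAL = 1e-3


def entropy(dist, tol: float = 1e-9) -> float:
    """Shannon entropy in bits of a probability table of any shape.

    Zero cells contribute nothing (0 * log2 0 == 0 by continuity).
    """
    p = np.asarray(dist, dtype=float).ravel()
    if (p < -tol).any():
        raise NotNormalized(f"negative probability {p.min()!r}")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise NotNormalized(f"probabilities sum to {total!r}")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information_state(joint, tol: float = 1e-9) -> float:
    """Mutual information in bits between the two margins of a joint table.

    ``joint[j, k] = Pr(prev = j, next = k | current state)``.  Clipped at
    zero: exact independence can come out as a tiny negative number in
    floating point.
    """
    J = np.asarray(joint, dtype=float)
    h_joint = entropy(J, tol=tol)
    h_prev = entropy(J.sum(axis=1), tol=tol)
    h_next = entropy(J.sum(axis=0), tol=tol)
    return max(h_prev + h_next - h_joint, 0.0)


@dataclass(frozen=True)
class TripleDistribution:
    """Per-macro-state joint law of (previous macro, next macro).

    ``joints[i][j, k] = Pr(prev = s_j, next = s_k | current = s_i)`` under the
    stationary one-step triple law of the micro chain; ``weights[i] =
    Pr(s_i)`` is the stationary block mass.
    """

    macro_labels: tuple[str, ...]
    joints: tuple[np.ndarray, ...]
    weights: np.ndarray

    def mutual_information(self) -> np.ndarray:
        return np.array([mutual_information_state(J) for J in self.joints])

    def expected_mutual_information(self) -> float:
        return float(np.dot(self.weights, self.mutual_information()))


@dataclass(frozen=True)
class LumpabilityReport:
    """Outcome of testing one partition for closedness."""

    partition: Partition
    expected_mi: float
    per_state_mi: np.ndarray
    weights: np.ndarray
    tau: float

    @property
    def lumpable(self) -> bool:
        return self.expected_mi <= self.tau


# ---------------------------------------------------------------------------
# Internal vectorized machinery.  The triple weight of a micro path
# (y, x, z) is pi(y) P(y, x) P(x, z); everything below marginalizes that law
# onto macro triples without materializing the N^3 tensor.


def _prev_next_arrays(P: np.ndarray, pi: np.ndarray, member: np.ndarray, n: int):
    """B[j, x] = sum_{y in s_j} pi_y P_yx  and  F[x, k] = sum_{z in s_k} P_xz,
    plus the micro-state index groups of each block."""
    N = P.shape[0]
    C = np.zeros((N, n))
    C[np.arange(N), member] = 1.0
    B = (C * pi[:, None]).T @ P
    F = P @ C
    groups = [np.flatnonzero(member == i) for i in range(n)]
    return B, F, groups


def _triple_weights(B: np.ndarray, F: np.ndarray, groups) -> np.ndarray:
    """Unnormalized macro triple law W[j, i, k] = Pr(prev in s_j, cur in s_i,
    next in s_k) under stationarity."""
    n = len(groups)
    W = np.empty((n, n, n))
    for i, xs in enumerate(groups):
        W[:, i, :] = B[:, xs] @ F[xs, :]
    return W


def _plogp_sum(a: np.ndarray) -> float:
    a = a[a > 0]
    return float((a * np.log2(a)).sum())


def _emi_from_weights(W: np.ndarray) -> float:
    """<I> in bits from the unnormalized macro triple tensor.

    Uses the decomposition
        <I> = S(W) - S(prev margin) - S(next margin) + S(state margin)
    with S(.) = sum x log2 x over entries, which equals
    sum_i Pr(s_i) [H(P_i) + H(F_i) - H(P_i, F_i)].
    """
    pr_state = W.sum(axis=(0, 2))
    if (pr_state <= 0).any():
        raise ZeroMassBlock("a block has zero stationary mass")
    val = (
        _plogp_sum(W.ravel())
        - _plogp_sum(W.sum(axis=2).ravel())   # (prev, cur) margin
        - _plogp_sum(W.sum(axis=0).ravel())   # (cur, next) margin
        + _plogp_sum(pr_state)
    )
    if val < -1e-9:
        raise AssertionError(f"expected mutual information came out at {val} bits")
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# Public operations


def triple_distribution(
    T: TransitionMatrix,
    pi: ProbabilityVector,
    partition: Partition,
) -> TripleDistribution:
    """Exact stationary triple law of the aggregated process, one step each
    way from the current macro-state."""
    partition.check_covers(T.labels)
    member = partition.membership(T.labels)
    n = partition.n_blocks
    B, F, groups = _prev_next_arrays(T.P, pi.w, member, n)
    W = _triple_weights(B, F, groups)
    weights = W.sum(axis=(0, 2))
    if (weights <= 0).any():
        bad = partition.block_names()[int(np.argmin(weights))]
        raise ZeroMassBlock(f"block {bad!r} has zero stationary mass")
    joints = tuple(W[:, i, :] / weights[i] for i in range(n))
    return TripleDistribution(partition.block_names(), joints, weights / weights.sum())


def expected_mutual_information(
    T: TransitionMatrix,
    pi: ProbabilityVector,
    partition: Partition,
) -> float:
    """<I> in bits: stationary-weighted mutual information between previous
    and next macro-state given the current one.  Zero iff the aggregated
    one-step process is closed."""
    partition.check_covers(T.labels)
    member = partition.membership(T.labels)
    B, F, groups = _prev_next_arrays(T.P, pi.w, member, partition.n_blocks)
    return _emi_from_weights(_triple_weights(B, F, groups))


def is_lumpable(
    T: TransitionMatrix,
    partition: Partition,
    tau: float = TAU_EXACT,
    pi: ProbabilityVector | None = None,
) -> LumpabilityReport:
    """Test whether a partition defines a lumping at tolerance ``tau`` bits.

    The report carries per-macro-state diagnostics: states whose past and
    future remain coupled contribute positive ``per_state_mi``.
    """
    if pi is None:
        pi = stationary_distribution(T)
    trip = triple_distribution(T, pi, partition)
    per_state = trip.mutual_information()
    return LumpabilityReport(
        partition=partition,
        expected_mi=float(np.dot(trip.weights, per_state)),
        per_state_mi=per_state,
        weights=trip.weights,
        tau=tau,
    )
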