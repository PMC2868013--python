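"""Synthetic chains with known aggregation structure.

Everything downstream is testable against ground truth generated here:
exactly lumpable chains with a planted partition, a 4-state worked example
with a closed two-state aggregation, noise perturbation toward generic
(non-lumpable) chains, and a 61-codon chain that is exactly lumpable to the
genetic code and shows a spectral gap after the 21st eigenvalue.

The planted chains satisfy strong lumpability (the Kemeny-Snell condition):
for every micro state x in block I, the total transition mass from x into
block J equals the macro probability P_macro(I, J).  That guarantees the
aggregated process is Markov from any start, hence <I> = 0 for the planted
partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import CodonChain, GeneticCode, code_partition
from .errors import InvalidProbability, InvalidSizes
from .markov import Partition, TransitionMatrix, validate_stochastic


@dataclass(frozen=True)
class PlantedChain:
    """A micro chain with its planted partition and generating macro chain."""

    matrix: TransitionMatrix
    planted: Partition
    macro: TransitionMatrix
    seed: int


def worked_example_matrix(p: float, q: float) -> TransitionMatrix:
    """The 4-state chain over {a, b, c, d} whose only non-trivial
    aggregation is {{a, c}, {b, d}}.

    States a and c jump to b with probability p, else to d; states b and d
    jump to a with probability q, else to c:

        P = [[0, p, 0, 1-p],
             [q, 0, 1-q, 0],
             [0, p, 0, 1-p],
             [q, 0, 1-q, 0]]

    The aggregated two-state process flips deterministically between
    {a, c} and {b, d}, so the spectrum is {1, -1, 0, 0}: the second
    eigenvector is (1, -1, 1, -1) — constant on the two blocks — and the
    kernel is spanned by (r, 0, p, 0) and (0, s, 0, q) with
    r = p(q - 1)/q and s = q(p - 1)/p.  The chain is reversible with
    stationary distribution (q, p, 1-q, 1-p)/2.
    """
    for name, val in (("p", p), ("q", q)):
        if not 0.0 < val < 1.0:
            raise InvalidProbability(f"{name} = {val!r} is not in (0, 1)")
    P = np.array(
        [
            [0.0, p, 0.0, 1.0 - p],
            [q, 0.0, 1.0 - q, 0.0],
            [0.0, p, 0.0, 1.0 - p],
            [q, 0.0, 1.0 - q, 0.0],
        ]
    )
    return validate_stochastic(("a", "b", "c", "d"), P, tol_stochastic=1e-12)


def _state_labels(n: int) -> tuple[str, ...]:
    width = max(2, len(str(n - 1)))
    return tuple(f"s{i:0{width}d}" for i in range(n))


def sample_lumpable_chain(
    block_sizes,
    seed: int = 0,
    separation: float = 0.95,
    macro_matrix: np.ndarray | None = None,
    self_bias: float = 0.3,
    labels=None,
) -> PlantedChain:
    """Draw an exactly lumpable chain with a planted block partition.

    A random k x k macro chain is drawn (diagonally dominant:
    ``(1 - self_bias) I + self_bias R`` with Dirichlet rows R, unless
    ``macro_matrix`` is supplied).  Each micro row then distributes the
    macro mass P_macro(I, J) across block J via a composition that mixes a
    block-shared allocation with a per-row random one:

        alloc = (1 - delta) * shared_J + delta * Dirichlet,  delta = 1 - separation.

    Strong lumpability holds exactly for any ``separation``; ``separation``
    only controls the time-scale separation: near 1 the within-block modes
    shrink toward zero, keeping all k macro eigenvalue magnitudes well above
    the within-block ones so the spectral gap sits at k.  At
    ``separation = 1`` rows within a block are identical.
    """
    block_sizes = [int(s) for s in block_sizes]
    if not block_sizes or any(s < 1 for s in block_sizes):
        raise InvalidSizes(f"block sizes must be positive, got {block_sizes}")
    if not 0.0 < separation <= 1.0:
        raise InvalidProbability(f"separation = {separation!r} is not in (0, 1]")
    rng = np.random.default_rng(seed)
    k = len(block_sizes)
    N = sum(block_sizes)
    if macro_matrix is None:
        R = rng.dirichlet(np.ones(k), size=k)
        macro_matrix = (1.0 - self_bias) * np.eye(k) + self_bias * R
    else:
        macro_matrix = np.asarray(macro_matrix, dtype=float)
        if macro_matrix.shape != (k, k):
            raise InvalidSizes(
                f"macro matrix shape {macro_matrix.shape} does not match {k} blocks"
            )
    delta = 1.0 - separation
    if labels is None:
        labels = _state_labels(N)
    labels = tuple(labels)
    if len(labels) != N:
        raise InvalidSizes(f"{len(labels)} labels for {N} states")

    starts = np.concatenate(([0], np.cumsum(block_sizes)))
    shared = [rng.dirichlet(np.ones(sz)) for sz in block_sizes]
    P = np.zeros((N, N))
    for I in range(k):
        for x in range(starts[I], starts[I + 1]):
            for J in range(k):
                alloc = shared[J]
                if delta > 0.0:
                    alloc = (1.0 - delta) * alloc + delta * rng.dirichlet(
                        np.ones(block_sizes[J])
                    )
                P[x, starts[J]:starts[J + 1]] = macro_matrix[I, J] * alloc

    T = validate_stochastic(labels, P, tol_stochastic=1e-12)
    blocks = [
        frozenset(labels[starts[I]:starts[I + 1]]) for I in range(k)
    ]
    planted = Partition(tuple(blocks))
    # reorder the macro rows/cols to the partition's canonical block order
    names = [min(b) for b in blocks]
    order = sorted(range(k), key=lambda i: names[i])
    macro = validate_stochastic(
        tuple(names[i] for i in order),
        macro_matrix[np.ix_(order, order)],
        tol_stochastic=1e-12,
    )
    return PlantedChain(T, planted, macro, int(seed))


def perturb(T: TransitionMatrix, epsilon: float, seed: int = 0) -> TransitionMatrix:
    """Mix each row with an independent random probability row:
    ``(1 - epsilon) row + epsilon noise``.  At epsilon = 0 the chain is
    unchanged; at 1 it is pure noise and generically not lumpable for any
    non-trivial partition."""
    if not 0.0 <= epsilon <= 1.0:
        raise InvalidProbability(f"epsilon = {epsilon!r} is not in [0, 1]")
    if epsilon == 0.0:
        return T
    rng = np.random.default_rng(seed)
    noise = rng.dirichlet(np.ones(T.n_states), size=T.n_states)
    P = (1.0 - epsilon) * T.P + epsilon * noise
    return validate_stochastic(T.labels, P, tol_stochastic=1e-12)


def _hamming1(a: str, b: str) -> bool:
    return sum(x != y for x, y in zip(a, b)) == 1


def synthetic_codon_matrix(
    seed: int = 0,
    within_weight: float = 50.0,
    between_weight: float = 1.0,
    separation: float = 0.98,
    code: GeneticCode | None = None,
) -> CodonChain:
    """A 61-codon chain exactly lumpable to the genetic-code partition.

    The macro chain runs over the 21 code-partition blocks (serine split):
    block I keeps weight ``within_weight`` on itself and ``between_weight``
    on every block reachable by a single point mutation, rows normalized.
    Micro rows are filled in by :func:`sample_lumpable_chain`, so the code
    partition is exactly lumpable and the spectral gap falls after the 21st
    eigenvalue.
    """
    if not within_weight > between_weight > 0:
        raise InvalidProbability(
            f"need within_weight > between_weight > 0, got "
            f"{within_weight!r}, {between_weight!r}"
        )
    if code is None:
        code = GeneticCode.standard()
    sense = sorted(code.sense_codons)
    # build the code partition on a plain label chain (identity matrix is a
    # convenient stand-in: only the labels matter here)
    dummy = CodonChain(
        TransitionMatrix(tuple(sense), np.eye(len(sense))), code
    )
    part = code_partition(dummy, split_disconnected=True)
    blocks = [sorted(b) for b in part.blocks]
    k = len(blocks)
    W = within_weight * np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if any(_hamming1(x, y) for x in blocks[i] for y in blocks[j]):
                W[i, j] = W[j, i] = between_weight
    macro = W / W.sum(axis=1, keepdims=True)
    labels = tuple(c for b in blocks for c in b)
    planted = sample_lumpable_chain(
        [len(b) for b in blocks],
        seed=seed,
        separation=separation,
        macro_matrix=macro,
        labels=labels,
    )
    return CodonChain(planted.matrix, code)
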