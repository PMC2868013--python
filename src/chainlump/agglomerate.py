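"""Agglomerative aggregation by greedy minimization of the expected mutual
information.

Starting from singletons (or any initial partition), every pairwise merge of
current aggregates is evaluated by the closedness measure <I> and the merge
with the lowest <I> is applied, down to a single block.  At a level with k
aggregates there are k(k-1)/2 merges to test.  The full merge trace is
recorded so any level can be inspected; ``most_significant`` flags the level
preceding the largest single-step jump in <I>, the point where merging
starts to destroy closedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lumpability import _emi_from_weights, _prev_next_arrays, _triple_weights
from .markov import Partition, ProbabilityVector, TransitionMatrix, stationary_distribution


@dataclass(frozen=True)
class MergeStep:
    """One greedy merge: the pair of block names joined, the resulting
    partition, and its <I> in bits."""

    merged_pair: tuple[str, str]
    partition: Partition
    expected_mi: float


@dataclass(frozen=True)
class MergeTrace:
    """Ordered record of an agglomeration run.

    ``levels()`` returns the <I> sequence starting at the initial partition;
    step t (1-based) has ``initial_partition.n_blocks - t`` blocks and the
    partitions nest monotonically.
    """

    initial_partition: Partition
    initial_emi: float
    steps: tuple[MergeStep, ...]
    evaluations: int

    def levels(self) -> np.ndarray:
        return np.array([self.initial_emi] + [s.expected_mi for s in self.steps])

    def partitions(self) -> list[Partition]:
        return [self.initial_partition] + [s.partition for s in self.steps]

    def partition_with(self, n_blocks: int) -> Partition:
        for p in self.partitions():
            if p.n_blocks == n_blocks:
                return p
        raise ValueError(f"no level with {n_blocks} blocks in trace")


def agglomerate(
    T: TransitionMatrix,
    initial: Partition | None = None,
    pi: ProbabilityVector | None = None,
) -> MergeTrace:
    """Greedy <I>-minimizing agglomeration down to one block.

    At every level all pairwise merges are evaluated from scratch; ties on
    <I> are broken toward the lexicographically smallest pair of block
    names, making the trace deterministic.
    """
    if initial is None:
        initial = Partition.singletons(T.labels)
    initial.check_covers(T.labels)
    if pi is None:
        pi = stationary_distribution(T)

    member = initial.membership(T.labels)
    n = initial.n_blocks
    B, F, groups = _prev_next_arrays(T.P, pi.w, member, n)
    blocks = [set(b) for b in initial.blocks]
    names = [min(b) for b in blocks]
    initial_emi = _emi_from_weights(_triple_weights(B, F, groups))

    steps: list[MergeStep] = []
    evaluations = 0
    while len(blocks) > 1:
        k = len(blocks)
        pair_order = sorted(
            ((i, j) for i in range(k) for j in range(i + 1, k)),
            key=lambda ij: tuple(sorted((names[ij[0]], names[ij[1]]))),
        )
        best, best_emi = None, np.inf
        for i, j in pair_order:
            keep = [t for t in range(k) if t not in (i, j)]
            Bm = np.vstack([B[keep, :], (B[i] + B[j])[None, :]])
            Fm = np.hstack([F[:, keep], (F[:, i] + F[:, j])[:, None]])
            gm = [groups[t] for t in keep] + [np.concatenate((groups[i], groups[j]))]
            emi = _emi_from_weights(_triple_weights(Bm, Fm, gm))
            evaluations += 1
            if emi < best_emi:
                best, best_emi = (i, j), emi
        i, j = best
        pair = tuple(sorted((names[i], names[j])))
        B = np.vstack([np.delete(B, (i, j), axis=0), (B[i] + B[j])[None, :]])
        F = np.hstack([np.delete(F, (i, j), axis=1), (F[:, i] + F[:, j])[:, None]])
        groups = [groups[t] for t in range(k) if t not in (i, j)] + [
            np.concatenate((groups[i], groups[j]))
        ]
        merged = blocks[i] | blocks[j]
        blocks = [blocks[t] for t in range(k) if t not in (i, j)] + [merged]
        names = [names[t] for t in range(k) if t not in (i, j)] + [min(merged)]
        steps.append(
            MergeStep(pair, Partition.from_blocks(blocks), float(best_emi))
        )
    return MergeTrace(initial, float(initial_emi), tuple(steps), evaluations)


def most_significant(trace: MergeTrace) -> Partition:
    """The partition immediately before the merge with the largest jump in
    <I> relative to the preceding level.

    Ties go to the latest jump; if no merge increases <I> at all (every
    partition is equally closed, as for an i.i.d. chain) the final one-block
    partition is returned.
    """
    levels = trace.levels()
    jumps = np.diff(levels)
    best_t, best_jump = None, 0.0
    for t, jump in enumerate(jumps):
        if jump >= best_jump and jump > 0:
            best_t, best_jump = t, jump
    if best_t is None:
        return trace.partitions()[-1]
    return trace.partitions()[best_t]


def to_newick(trace: MergeTrace, precision: int = 12) -> str:
    """Serialize the merge trace as a Newick dendrogram.

    Node heights are the <I> values of the merges, made non-decreasing by
    running maxima so every branch length is non-negative.  Leaves are the
    initial partition's block names.
    """
    fmt = f"%.{precision}g"
    subtree = {name: (name, 0.0) for name in trace.initial_partition.block_names()}
    height = 0.0
    node = None
    for step in trace.steps:
        height = max(height, step.expected_mi)
        a, b = step.merged_pair
        (na, ha), (nb, hb) = subtree.pop(a), subtree.pop(b)
        node = f"({na}:{fmt % (height - ha)},{nb}:{fmt % (height - hb)})"
        subtree[min(a, b)] = (node, height)
    if node is None:  # single-leaf trace
        (node, _), = subtree.values()
    return node + ";"
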