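"""Core Markov-chain algebra: labeled transition matrices, stationary
distributions, state restriction, and stationary-weighted lumping.

The central objects are :class:`TransitionMatrix` — a row-stochastic matrix
``P`` with ``P[i, j] = Pr(next = j | current = i)`` over named states — and
:class:`Partition`, a disjoint cover of the state labels into aggregates
(macro-states).  ``lump`` projects a chain onto a partition using
stationary-distribution weights, which reproduces the macro chain exactly
whenever the partition is lumpable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .errors import (
    EmptyRestriction,
    InvalidPartition,
    NegativeEntry,
    NonSquare,
    NonUniqueStationary,
    RowSumViolation,
    ZeroMassBlock,
    ZeroRow,
)

#: Default tolerance on row sums when validating a stochastic matrix.  Kept
#: loose enough for empirical matrices printed with limited precision.
TOL_STOCHASTIC = 1e-6

#: An eigenvalue counts as "equal to 1" within this tolerance when deciding
#: uniqueness of the stationary distribution.
TOL_EIGENVALUE_ONE = 1e-8


@dataclass(frozen=True)
class TransitionMatrix:
    """A validated row-stochastic matrix over named states."""

    labels: tuple[str, ...]
    P: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "P", np.asarray(self.P, dtype=float))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(self.labels), columns=list(self.labels))

    def write(self, path, delimiter: str = "\t") -> None:
        """Write as a labeled matrix: header of state labels, then one row
        per state, label first."""
        self.to_frame().to_csv(path, sep=delimiter, index_label="")


@dataclass(frozen=True)
class ProbabilityVector:
    """A probability distribution over named states."""

    labels: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    def __getitem__(self, label: str) -> float:
        return float(self.w[self.labels.index(label)])


def _canonical_blocks(blocks: Iterable[Iterable[str]]) -> tuple[frozenset, ...]:
    bs = [frozenset(str(x) for x in b) for b in blocks]
    if any(not b for b in bs):
        raise InvalidPartition("empty block")
    return tuple(sorted(bs, key=lambda b: min(b)))


@dataclass(frozen=True)
class Partition:
    """A disjoint cover of state labels into non-empty blocks.

    Blocks are stored in canonical order: sorted by their lexicographically
    smallest member, which also names the block (see :meth:`block_names`).
    """

    blocks: tuple[frozenset, ...]

    def __post_init__(self):
        object.__setattr__(self, "blocks", _canonical_blocks(self.blocks))
        seen: set = set()
        for b in self.blocks:
            if not b:
                raise InvalidPartition("empty block")
            if seen & b:
                raise InvalidPartition(f"labels {sorted(seen & b)} appear in several blocks")
            seen |= b

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[str]]) -> "Partition":
        return cls(tuple(frozenset(b) for b in blocks))

    @classmethod
    def singletons(cls, labels: Iterable[str]) -> "Partition":
        return cls(tuple(frozenset([l]) for l in labels))

    @classmethod
    def one_block(cls, labels: Iterable[str]) -> "Partition":
        return cls((frozenset(labels),))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def labels(self) -> frozenset:
        out: set = set()
        for b in self.blocks:
            out |= b
        return frozenset(out)

    def block_names(self) -> tuple[str, ...]:
        return tuple(min(b) for b in self.blocks)

    def block_of(self, label: str) -> int:
        for i, b in enumerate(self.blocks):
            if label in b:
                return i
        raise KeyError(label)

    def membership(self, labels: Sequence[str]) -> np.ndarray:
        """Block index of each label, in the given label order."""
        lookup = {l: i for i, b in enumerate(self.blocks) for l in b}
        try:
            return np.array([lookup[l] for l in labels], dtype=int)
        except KeyError as e:
            raise InvalidPartition(f"label {e.args[0]!r} not covered by partition") from None

    def check_covers(self, labels: Sequence[str]) -> None:
        if self.labels != frozenset(labels):
            missing = frozenset(labels) - self.labels
            extra = self.labels - frozenset(labels)
            raise InvalidPartition(
                f"partition does not cover state labels (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )

    def refines(self, other: "Partition") -> bool:
        """True if every block of this partition lies inside a block of ``other``."""
        return all(any(b <= o for o in other.blocks) for b in self.blocks)

    def to_json(self) -> str:
        return json.dumps({"blocks": [sorted(b) for b in self.blocks]}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Partition":
        data = json.loads(text)
        return cls.from_blocks(data["blocks"])


# ---------------------------------------------------------------------------
# Construction and validation


def validate_stochastic(
    labels: Sequence[str],
    raw_matrix,
    tol_stochastic: float = TOL_STOCHASTIC,
) -> TransitionMatrix:
    """Validate a labeled square matrix as row-stochastic.

    Rows are renormalized to sum exactly to one only when they are already
    within ``tol_stochastic`` of one; anything worse raises
    :class:`RowSumViolation` reporting the worst row.  Entries more negative
    than ``-tol_stochastic`` raise :class:`NegativeEntry`; tiny negative
    round-off is clipped to zero.
    """
    M = np.asarray(raw_matrix, dtype=float)
    labels = tuple(str(l) for l in labels)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise NonSquare(f"matrix has shape {M.shape}")
    if len(labels) != M.shape[0]:
        raise NonSquare(f"{len(labels)} labels for a {M.shape[0]}x{M.shape[1]} matrix")
    if len(set(labels)) != len(labels):
        raise NonSquare("duplicate state labels")
    if (M < -tol_stochastic).any():
        i, j = np.unravel_index(np.argmin(M), M.shape)
        raise NegativeEntry(f"P[{labels[i]!r}, {labels[j]!r}] = {M[i, j]!r}")
    M = np.clip(M, 0.0, None)
    sums = M.sum(axis=1)
    worst = int(np.argmax(np.abs(sums - 1.0)))
    if abs(sums[worst] - 1.0) > tol_stochastic:
        raise RowSumViolation(labels[worst], float(sums[worst]), tol_stochastic)
    return TransitionMatrix(labels, M / sums[:, None])


def stationary_distribution(T: TransitionMatrix) -> ProbabilityVector:
    """Stationary distribution pi with ``pi P = pi``.

    Computed as the left eigenvector of the eigenvalue closest to 1;
    uniqueness requires exactly one eigenvalue within ``1e-8`` of 1,
    otherwise :class:`NonUniqueStationary` is raised.
    """
    w, vl = sla.eig(T.P, left=True, right=False)
    near_one = np.abs(w - 1.0) < TOL_EIGENVALUE_ONE
    if near_one.sum() != 1:
        raise NonUniqueStationary(
            f"{int(near_one.sum())} eigenvalues within {TOL_EIGENVALUE_ONE} of 1"
        )
    v = vl[:, int(np.flatnonzero(near_one)[0])]
    v = np.real_if_close(v, tol=1e6)
    pi = np.abs(np.real(v))
    pi = pi / pi.sum()
    # refine by one power step to wash out eigensolver round-off
    pi = pi @ T.P
    pi = np.clip(pi, 0.0, None)
    return ProbabilityVector(T.labels, pi / pi.sum())


def restrict(T: TransitionMatrix, keep: Iterable[str]) -> TransitionMatrix:
    """Submatrix over ``keep``, each row renormalized to sum to one.

    Raises :class:`ZeroRow` if a kept state has no probability mass left
    inside ``keep``.
    """
    keep = set(str(k) for k in keep)
    if not keep:
        raise EmptyRestriction("empty keep set")
    unknown = keep - set(T.labels)
    if unknown:
        raise EmptyRestriction(f"unknown labels {sorted(unknown)}")
    idx = [i for i, l in enumerate(T.labels) if l in keep]
    sub = T.P[np.ix_(idx, idx)].copy()
    sums = sub.sum(axis=1)
    dead = np.flatnonzero(sums <= 0)
    if dead.size:
        raise ZeroRow(f"state {T.labels[idx[dead[0]]]!r} has no mass inside the kept set")
    # renormalize only rows that actually need it, so restriction is an
    # exact fixed point on its own output
    needs = np.abs(sums - 1.0) > 1e-13
    sub[needs] /= sums[needs, None]
    return TransitionMatrix(tuple(T.labels[i] for i in idx), sub)


def lump(
    T: TransitionMatrix,
    pi: ProbabilityVector,
    partition: Partition,
) -> TransitionMatrix:
    """Aggregate a chain under a partition with stationary weights.

    The macro transition probability from block I to block J is the
    pi-weighted average over micro states x in I of their total mass into J:

        P_macro(I, J) = sum_{x in I} pi(x)/pi(I) * sum_{y in J} P(x, y)

    For a lumpable partition this equals the (unique) macro chain; in general
    it is the one-step law of the stationary aggregated process.  Macro states
    are labeled by each block's lexicographically smallest member.
    """
    partition.check_covers(T.labels)
    member = partition.membership(T.labels)
    n = partition.n_blocks
    C = np.zeros((T.n_states, n))
    C[np.arange(T.n_states), member] = 1.0
    w = np.asarray(pi.w, dtype=float)
    block_mass = C.T @ w
    empty = np.flatnonzero(block_mass <= 0)
    if empty.size:
        raise ZeroMassBlock(f"block {partition.block_names()[empty[0]]!r} has zero mass")
    M = (C * w[:, None]).T @ T.P @ C / block_mass[:, None]
    M = M / M.sum(axis=1)[:, None]
    return TransitionMatrix(partition.block_names(), M)


def aggregate_vector(pi: ProbabilityVector, partition: Partition) -> ProbabilityVector:
    """Block sums of a probability vector, in canonical block order."""
    partition.check_covers(pi.labels)
    member = partition.membership(pi.labels)
    out = np.zeros(partition.n_blocks)
    np.add.at(out, member, pi.w)
    return ProbabilityVector(partition.block_names(), out)


def is_reversible(T: TransitionMatrix, pi: ProbabilityVector, tol: float = 1e-10) -> bool:
    """Detailed balance check: ``pi_i P_ij == pi_j P_ji`` within ``tol``."""
    F = pi.w[:, None] * T.P
    return bool(np.abs(F - F.T).max() <= tol)


# ---------------------------------------------------------------------------
# Labeled-matrix I/O


def read_labeled_matrix(path, delimiter: str = "\t",
                        tol_stochastic: float = TOL_STOCHASTIC) -> TransitionMatrix:
    """Read a labeled matrix file: first row holds the state labels, each
    following row a label plus N numeric fields.  ``delimiter`` switches
    between TSV and CSV."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise NonSquare(
            f"row labels do not match column labels in {path}"
        )
    return validate_stochastic(labels, df.to_numpy(dtype=float), tol_stochastic)
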