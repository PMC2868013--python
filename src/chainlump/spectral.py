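"""Spectral identification of aggregations.

The right eigenvectors of a transition matrix place the N states as N points
in eigenvector-coordinate space.  If n eigenvectors produce exactly n
clusters of points, those clusters define a candidate aggregation; a gap in
the sorted eigenvalue magnitudes suggests how many eigenvectors to use.
Every candidate found here is re-verified with the expected-mutual-
information criterion, so correctness never rests on the search heuristic.

Degenerate eigenvalues need care: individual eigenvectors inside a repeated
eigenvalue's eigenspace are arbitrary (any basis is as good as any other),
so such a group is treated as one atomic subspace.  Its coordinates are an
orthonormal basis of the corresponding invariant subspace, obtained from a
sorted Schur decomposition; Euclidean distances between states are then
invariant under the basis choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import (
    EigendecompositionFailure,
    NoValidClustering,
    SearchBudgetExceeded,
)
from .lumpability import TAU_EXACT, is_lumpable
from .markov import Partition, TransitionMatrix, stationary_distribution

#: Two eigenvalues closer than this (in the complex plane) are treated as one
#: degenerate group.
TOL_DEGENERATE = 1e-8


def default_epsilon(n_states: int) -> float:
    """Default single-linkage cut for clustering eigenvector elements.

    Eigenvector coordinates are unit-norm, so typical element spacings scale
    like 1/sqrt(N); the cut 0.1/sqrt(N) is scale-free in that sense.
    """
    return 0.1 / np.sqrt(n_states)


@dataclass
class Spectrum:
    """Full eigendecomposition of a transition matrix, sorted by descending
    eigenvalue magnitude.

    ``eigenvalues[i]`` pairs with the unit-norm right eigenvector
    ``vectors[:, i]``; each vector's phase is fixed so its largest-magnitude
    entry is positive real.  ``groups`` lists index tuples of degenerate
    eigenvalues (see module docstring).
    """

    labels: tuple[str, ...]
    eigenvalues: np.ndarray
    vectors: np.ndarray
    groups: tuple[tuple[int, ...], ...] = field(init=False)
    _P: np.ndarray = field(repr=False, default=None)
    _basis_cache: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        self.groups = _degeneracy_groups(self.eigenvalues)

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def magnitudes(self) -> np.ndarray:
        return np.abs(self.eigenvalues)

    def group_of(self, index: int) -> tuple[int, ...]:
        for g in self.groups:
            if index in g:
                return g
        raise IndexError(index)

    def group_basis(self, group: tuple[int, ...]) -> np.ndarray:
        """Real orthonormal coordinate columns for one degeneracy group.

        For a simple real eigenvalue this is just the (real) eigenvector.
        For degenerate or complex eigenvalues an orthonormal basis of the
        invariant subspace is extracted from a sorted Schur decomposition and
        realified, making within-group distances basis-independent.
        """
        group = tuple(group)
        if group not in self._basis_cache:
            self._basis_cache[group] = self._compute_basis(group)
        return self._basis_cache[group]

    def _compute_basis(self, group: tuple[int, ...]) -> np.ndarray:
        lam = self.eigenvalues[list(group)]
        if len(group) == 1 and abs(lam[0].imag) < TOL_DEGENERATE:
            v = self.vectors[:, group[0]]
            if np.abs(v.imag).max() < 1e-8:
                v = v.real
                return (v / np.linalg.norm(v))[:, None]
        if self._P is None:
            raise EigendecompositionFailure(
                "transition matrix unavailable for invariant-subspace extraction"
            )
        sel = lambda x: bool(np.min(np.abs(x - lam)) < 10 * TOL_DEGENERATE)
        Tc, Z, sdim = sla.schur(self._P.astype(complex), output="complex", sort=sel)
        if sdim < len(group):
            raise EigendecompositionFailure(
                f"Schur sorting selected {sdim} < {len(group)} vectors for "
                f"eigenvalue group {lam}"
            )
        Zsel = Z[:, :sdim]
        raw = np.hstack([Zsel.real, Zsel.imag])
        # orthonormalize and drop numerically null directions
        U, s, _ = np.linalg.svd(raw, full_matrices=False)
        return U[:, s > 1e-8]

    def coordinates(self, indices) -> np.ndarray:
        """State coordinates (N x d) in the selected eigenvectors.

        ``indices`` are 1-based (index 1 = the stationary direction).  A
        selection touching part of a degenerate group is expanded to the full
        group, since its individual members are not well defined.
        """
        zero_based = sorted({int(i) - 1 for i in indices})
        if not zero_based or zero_based[0] < 0 or zero_based[-1] >= self.n_states:
            raise IndexError(f"eigenvector indices out of range: {indices}")
        groups, seen = [], set()
        for i in zero_based:
            g = self.group_of(i)
            if g not in seen:
                seen.add(g)
                groups.append(g)
        cols = [self.group_basis(g) for g in sorted(groups, key=lambda g: g[0])]
        return np.hstack(cols)


def _degeneracy_groups(eigenvalues: np.ndarray) -> tuple[tuple[int, ...], ...]:
    n = len(eigenvalues)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in itertools.combinations(range(n), 2):
        if abs(eigenvalues[i] - eigenvalues[j]) < TOL_DEGENERATE:
            parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return tuple(sorted((tuple(sorted(g)) for g in groups.values()), key=lambda g: g[0]))


def spectrum(T: TransitionMatrix) -> Spectrum:
    """Eigendecomposition sorted by descending |lambda| (ties: descending
    real part, then descending imaginary part), with a deterministic phase
    convention per eigenvector."""
    try:
        w, vr = sla.eig(T.P)
    except sla.LinAlgError as e:  # pragma: no cover - scipy rarely fails here
        raise EigendecompositionFailure(str(e)) from e
    # round sort keys so exact ties (e.g. |1| vs |-1|) are not scrambled by
    # last-digit noise; ties in magnitude resolve toward larger real part
    key = lambda x: np.round(x / (10 * TOL_DEGENERATE)) * (10 * TOL_DEGENERATE)
    order = np.lexsort((-key(w.imag), -key(w.real), -key(np.abs(w))))
    w, vr = w[order], vr[:, order]
    if abs(abs(w[0]) - 1.0) > 1e-6:
        raise EigendecompositionFailure(
            f"leading eigenvalue magnitude {abs(w[0])!r} differs from 1"
        )
    for i in range(vr.shape[1]):
        v = vr[:, i]
        v = v / np.linalg.norm(v)
        top = v[np.argmax(np.abs(v))]
        vr[:, i] = v * (top.conj() / abs(top))
    return Spectrum(T.labels, w, vr, _P=T.P)


def detect_gap(spec: Spectrum) -> int:
    """Number of leading eigenvalues before the largest magnitude drop.

    Returns the n (1 <= n < N) maximizing |lambda_n| / |lambda_{n+1}|; a
    magnitude ratio expresses time-scale separation between the aggregated
    and the within-aggregate dynamics.  Ties resolve to the smallest n.
    """
    mags = spec.magnitudes()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = mags[:-1] / mags[1:]
    ratios = np.where(np.isnan(ratios), -np.inf, ratios)
    return int(np.argmax(ratios)) + 1


def _cluster_labels(X: np.ndarray, epsilon: float) -> np.ndarray:
    if X.shape[0] == 1:
        return np.array([1])
    Z = linkage(X, method="single")
    return fcluster(Z, t=epsilon, criterion="distance")


def cluster_elements(
    spec: Spectrum,
    indices,
    epsilon: float | None = None,
) -> Partition:
    """Cluster states by their coordinates in the selected eigenvectors.

    Single-linkage clustering cut at distance ``epsilon``; the clusters
    define an aggregation precisely when their number equals the number of
    selected eigenvectors, otherwise :class:`NoValidClustering` is raised
    (a signal, not a failure).  ``indices`` are 1-based and must include
    index 1, the stationary direction.
    """
    indices = sorted({int(i) for i in indices})
    if 1 not in indices:
        raise ValueError("eigenvector selection must include index 1")
    if epsilon is None:
        epsilon = default_epsilon(spec.n_states)
    X = spec.coordinates(indices)
    cl = _cluster_labels(X, epsilon)
    n_clusters = len(set(cl))
    if n_clusters != len(indices):
        raise NoValidClustering(
            f"{len(indices)} eigenvectors resolve into {n_clusters} clusters"
        )
    blocks = [
        frozenset(np.array(spec.labels)[cl == c]) for c in sorted(set(cl))
    ]
    return Partition(tuple(blocks))


@dataclass(frozen=True)
class CandidateAggregation:
    """An aggregation found spectrally, with the eigenvectors that define it."""

    partition: Partition
    eigenvector_indices: tuple[int, ...]
    cluster_tightness: float
    expected_mi: float


def _tightness(X: np.ndarray, cl: np.ndarray) -> float:
    worst = 0.0
    for c in set(cl):
        pts = X[cl == c]
        if len(pts) > 1:
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            worst = max(worst, float(d.max()))
    return worst


def find_aggregations(
    T: TransitionMatrix,
    max_n: int | None = None,
    epsilon: float | None = None,
    tau: float = TAU_EXACT,
    node_budget: int = 2000,
    ns=None,
    strict_budget: bool = False,
) -> list[CandidateAggregation]:
    """Search subsets of the leading eigenvectors for valid aggregations.

    For each target size n the search grows a subset greedily — always
    containing the stationary direction, adding the eigenvector (or whole
    degenerate group) that least increases the cluster count — and
    backtracks on dead ends.  A subset of n eigenvectors forming exactly n
    clusters yields a candidate partition, which is accepted only if its
    expected mutual information is at most ``tau`` bits.  Results are sorted
    by block count; the one-block aggregation is always present.

    ``node_budget`` bounds the clustering/verification evaluations per
    target size; on exhaustion the size is skipped (or
    :class:`SearchBudgetExceeded` is raised when ``strict_budget``).
    """
    N = T.n_states
    if max_n is None:
        max_n = N
    if not 1 <= max_n <= N:
        raise ValueError(f"max_n must be in [1, {N}], got {max_n}")
    if epsilon is None:
        epsilon = default_epsilon(N)
    spec = spectrum(T)
    pi = stationary_distribution(T)

    # atomic units: degeneracy groups wholly inside the leading max_n indices
    units = [g for g in spec.groups if g[-1] < max_n]
    unit0 = spec.group_of(0)
    if unit0 not in units:
        units = [unit0] + units

    def coords_for(chosen_units):
        idx = [i + 1 for u in chosen_units for i in u]
        return spec.coordinates(idx)

    results: list[CandidateAggregation] = []
    for n in ns if ns is not None else range(1, max_n + 1):
        budget = [node_budget]

        def count_of(chosen):
            if budget[0] <= 0:
                raise SearchBudgetExceeded(f"node budget spent at target size {n}")
            budget[0] -= 1
            X = coords_for(chosen)
            cl = _cluster_labels(X, epsilon)
            return len(set(cl)), X, cl

        def search(chosen, dim, count):
            if dim == n:
                if count != n:
                    return None
                X = coords_for(chosen)
                cl = _cluster_labels(X, epsilon)
                blocks = [frozenset(np.array(spec.labels)[cl == c]) for c in set(cl)]
                part = Partition(tuple(blocks))
                report = is_lumpable(T, part, tau=tau, pi=pi)
                if report.lumpable:
                    idx = tuple(sorted(i + 1 for u in chosen for i in u))
                    return CandidateAggregation(
                        part, idx, _tightness(X, cl), report.expected_mi
                    )
                return None
            children = []
            for u in units:
                if u in chosen or dim + len(u) > n:
                    continue
                c_count, _, _ = count_of(chosen + [u])
                if c_count <= n:
                    children.append((c_count, u[0], u))
            for c_count, _, u in sorted(children):
                hit = search(chosen + [u], dim + len(u), c_count)
                if hit is not None:
                    return hit
            return None

        try:
            start_count, _, _ = count_of([unit0])
            if start_count <= n:
                hit = search([unit0], len(unit0), start_count)
                if hit is not None:
                    results.append(hit)
        except SearchBudgetExceeded:
            if strict_budget:
                raise
    results.sort(key=lambda c: c.partition.n_blocks)
    return results
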