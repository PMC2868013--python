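"""Independent oracles used by the tests.

Everything here is deliberately written the slow, obvious way — explicit
loops over all micro triples, exhaustive enumeration of set partitions —
and shares no code path with the package implementation it checks.
"""

import math
from itertools import combinations

import numpy as np


def brute_expected_mi(P, pi, member, n_blocks):
    """<I> in bits by enumerating all N^3 micro triples (y, x, z) with
    weight pi[y] P[y, x] P[x, z] and marginalizing onto macro triples."""
    N = len(pi)
    W = [[[0.0] * n_blocks for _ in range(n_blocks)] for _ in range(n_blocks)]
    for y in range(N):
        for x in range(N):
            w_yx = pi[y] * P[y][x]
            if w_yx == 0.0:
                continue
            for z in range(N):
                W[member[y]][member[x]][member[z]] += w_yx * P[x][z]
    total = 0.0
    for i in range(n_blocks):
        pr_i = sum(W[j][i][k] for j in range(n_blocks) for k in range(n_blocks))
        if pr_i <= 0.0:
            continue
        joint = [[W[j][i][k] / pr_i for k in range(n_blocks)] for j in range(n_blocks)]
        p_prev = [sum(row) for row in joint]
        p_next = [sum(joint[j][k] for j in range(n_blocks)) for k in range(n_blocks)]

        def h(ps):
            return -sum(p * math.log2(p) for p in ps if p > 0.0)

        flat = [joint[j][k] for j in range(n_blocks) for k in range(n_blocks)]
        total += pr_i * (h(p_prev) + h(p_next) - h(flat))
    return total


def all_set_partitions(items):
    """Every partition of ``items`` as a list of lists (Bell(n) of them)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def random_stochastic(rng, n):
    """Dense random row-stochastic matrix with Dirichlet(1) rows."""
    return rng.dirichlet(np.ones(n), size=n)


def random_membership(rng, n_states, n_blocks):
    """A random surjection of states onto blocks (every block non-empty)."""
    while True:
        member = rng.integers(0, n_blocks, size=n_states)
        if len(set(member.tolist())) == n_blocks:
            return member


def stationary_linear(P):
    """Stationary distribution by solving the linear system pi (I - P) = 0
    with the normalization constraint replacing one equation (independent of
    the eigensolver route)."""
    n = P.shape[0]
    A = (np.eye(n) - P).T
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    return np.linalg.solve(A, b)


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def brute_components(codons):
    """Connected components of the Hamming-1 graph by label propagation."""
    codons = sorted(codons)
    comp = {c: c for c in codons}
    changed = True
    while changed:
        changed = False
        for a, b in combinations(codons, 2):
            if hamming(a, b) == 1 and comp[a] != comp[b]:
                tgt = min(comp[a], comp[b])
                src = max(comp[a], comp[b])
                for c in codons:
                    if comp[c] == src:
                        comp[c] = tgt
                changed = True
    out = {}
    for c in codons:
        out.setdefault(comp[c], set()).add(c)
    return sorted((frozenset(s) for s in out.values()), key=lambda s: (-len(s), min(s)))
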