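import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chainlump import (
    Partition,
    ProbabilityVector,
    TransitionMatrix,
    aggregate_vector,
    is_reversible,
    lump,
    read_labeled_matrix,
    restrict,
    sample_lumpable_chain,
    stationary_distribution,
    validate_stochastic,
)
from chainlump.errors import (
    EmptyRestriction,
    InvalidPartition,
    NegativeEntry,
    NonSquare,
    NonUniqueStationary,
    RowSumViolation,
    ZeroRow,
)

import helpers_oracles as oracle


class TestValidateStochastic:
    def test_identity_is_valid(self):
        T = validate_stochastic(("a", "b"), np.eye(2))
        assert T.labels == ("a", "b")
        assert np.allclose(T.P, np.eye(2))

    def test_bad_row_sum_reports_worst_row(self):
        with pytest.raises(RowSumViolation) as exc:
            validate_stochastic(("a", "b"), [[0.5, 0.4], [0.5, 0.5]], 1e-8)
        assert exc.value.label == "a"
        assert exc.value.row_sum == pytest.approx(0.9)

    def test_worked_example_instance_is_valid(self):
        p, q = 0.3, 0.2
        M = [[0, p, 0, 1 - p], [q, 0, 1 - q, 0], [0, p, 0, 1 - p], [q, 0, 1 - q, 0]]
        T = validate_stochastic(("a", "b", "c", "d"), M)
        assert np.allclose(T.P.sum(axis=1), 1.0)

    @pytest.mark.parametrize(
        "labels,matrix,err",
        [
            (("a", "b"), np.ones((2, 3)) / 3, NonSquare),
            (("a",), np.eye(2) , NonSquare),
            (("a", "a"), np.eye(2), NonSquare),
            (("a", "b"), [[1.2, -0.2], [0.5, 0.5]], NegativeEntry),
        ],
    )
    def test_malformed_input_rejected(self, labels, matrix, err):
        with pytest.raises(err):
            validate_stochastic(labels, matrix)

    def test_near_stochastic_rows_renormalized_exactly(self):
        T = validate_stochastic(("a", "b"), [[0.5, 0.5 + 3e-7], [0.25, 0.75]], 1e-6)
        assert T.P.sum(axis=1) == pytest.approx([1.0, 1.0], abs=1e-15)


class TestStationary:
    def test_doubly_stochastic_gives_uniform(self):
        T = validate_stochastic(("a", "b"), [[0.8, 0.2], [0.2, 0.8]])
        pi = stationary_distribution(T)
        assert pi.w == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_two_state_closed_form(self):
        # pi P = pi for [[0.9, 0.1], [0.5, 0.5]] solves to (5/6, 1/6)
        T = validate_stochastic(("a", "b"), [[0.9, 0.1], [0.5, 0.5]])
        pi = stationary_distribution(T)
        assert pi.w == pytest.approx([5 / 6, 1 / 6], abs=1e-12)

    def test_two_recurrent_classes_rejected(self):
        P = np.zeros((4, 4))
        P[:2, :2] = [[0.5, 0.5], [0.5, 0.5]]
        P[2:, 2:] = [[0.9, 0.1], [0.1, 0.9]]
        T = validate_stochastic(tuple("abcd"), P)
        with pytest.raises(NonUniqueStationary):
            stationary_distribution(T)

    def test_matches_linear_solve(self, make_random_chain):
        T = make_random_chain(6, seed=11)
        pi = stationary_distribution(T)
        ref = oracle.stationary_linear(T.P)
        assert pi.w == pytest.approx(ref, abs=1e-12)


class TestRestrict:
    def test_full_restriction_is_identity(self, make_random_chain):
        T = make_random_chain(3, seed=1)
        R = restrict(T, T.labels)
        assert R.labels == T.labels
        assert np.allclose(R.P, T.P)

    def test_uniform_chain_renormalizes(self):
        T = validate_stochastic(("a", "b", "c"), np.full((3, 3), 1 / 3))
        R = restrict(T, {"a", "b"})
        assert np.allclose(R.P, 0.5)

    def test_dropping_only_target_raises_zero_row(self):
        # state a only transitions to c; dropping c strands a
        T = validate_stochastic(("a", "b", "c"),
                                [[0, 0, 1], [0.5, 0.5, 0], [0, 0.5, 0.5]])
        with pytest.raises(ZeroRow):
            restrict(T, {"a", "b"})

    def test_empty_or_unknown_keep_rejected(self, make_random_chain):
        T = make_random_chain(3, seed=2)
        with pytest.raises(EmptyRestriction):
            restrict(T, set())
        with pytest.raises(EmptyRestriction):
            restrict(T, {"nope"})

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        labels = tuple(f"x{i}" for i in range(n))
        T = validate_stochastic(labels, rng.dirichlet(np.ones(n), size=n))
        keep = set(rng.choice(labels, size=max(2, n // 2), replace=False))
        once = restrict(T, keep)
        twice = restrict(once, keep)
        assert once.labels == twice.labels
        assert np.array_equal(once.P, twice.P)


class TestLump:
    def test_one_block_gives_trivial_chain(self, make_random_chain):
        T = make_random_chain(5, seed=3)
        pi = stationary_distribution(T)
        L = lump(T, pi, Partition.one_block(T.labels))
        assert L.P.shape == (1, 1)
        assert L.P[0, 0] == pytest.approx(1.0, abs=1e-15)

    def test_singletons_give_back_chain(self, make_random_chain):
        T = make_random_chain(5, seed=4)
        pi = stationary_distribution(T)
        L = lump(T, pi, Partition.singletons(T.labels))
        assert L.labels == T.labels  # labels were already sorted
        assert np.allclose(L.P, T.P, atol=1e-14)

    def test_planted_chain_recovers_macro(self):
        planted = sample_lumpable_chain([3, 2, 4], seed=7)
        pi = stationary_distribution(planted.matrix)
        L = lump(planted.matrix, pi, planted.planted)
        assert L.labels == planted.macro.labels
        assert np.abs(L.P - planted.macro.P).max() < 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rows_sum_to_one_and_stationary_aggregates(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        k = int(rng.integers(1, n + 1))
        labels = tuple(f"x{i}" for i in range(n))
        T = validate_stochastic(labels, rng.dirichlet(np.ones(n), size=n))
        member = oracle.random_membership(rng, n, k)
        blocks = [frozenset(np.array(labels)[member == b]) for b in range(k)]
        part = Partition(tuple(blocks))
        pi = stationary_distribution(T)
        L = lump(T, pi, part)
        assert np.abs(L.P.sum(axis=1) - 1.0).max() < 1e-12
        agg = aggregate_vector(pi, part)
        pi_macro = stationary_distribution(L)
        assert np.abs(pi_macro.w - agg.w).max() < 1e-10

    def test_empty_block_rejected(self, make_random_chain):
        T = make_random_chain(3, seed=5)
        with pytest.raises(InvalidPartition):
            Partition.from_blocks([("x00",), (), ("x01", "x02")])


def test_reversible_chain_has_real_spectrum():
    # a random-walk chain P = D^-1 W on a symmetric weight matrix W is
    # reversible with stationary distribution proportional to the degrees
    rng = np.random.default_rng(42)
    W = rng.random((8, 8))
    W = W + W.T
    P = W / W.sum(axis=1, keepdims=True)
    T = validate_stochastic(tuple(f"x{i}" for i in range(8)), P)
    pi = stationary_distribution(T)
    assert is_reversible(T, pi, tol=1e-10)
    eigs = np.linalg.eigvals(T.P)
    assert np.abs(eigs.imag).max() < 1e-8


class TestIO:
    @pytest.mark.parametrize("delim", ["\t", ","])
    def test_roundtrip(self, tmp_path, make_random_chain, delim):
        T = make_random_chain(5, seed=9)
        path = tmp_path / "m.txt"
        T.write(path, delimiter=delim)
        back = read_labeled_matrix(path, delimiter=delim)
        assert back.labels == T.labels
        assert np.abs(back.P - T.P).max() < 1e-12

    def test_partition_json_roundtrip(self):
        part = Partition.from_blocks([("b", "a"), ("c",)])
        back = Partition.from_json(part.to_json())
        assert back == part
        assert back.block_names() == ("a", "c")
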