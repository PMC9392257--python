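import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paircna.markov import (
    PairTree,
    RateParams,
    build_rate_matrix,
    genome_transition,
    pair_index,
    pair_joint_adjacent,
    single_cell_genome_transition,
    steady_state,
    transition_matrix,
)

rates_st = st.builds(
    RateParams,
    alpha=st.floats(0.0, 5.0),
    beta=st.floats(0.01, 5.0),
    gamma=st.floats(0.0, 5.0),
)


class TestRateMatrix:
    def test_entries_k1(self):
        Q = build_rate_matrix(RateParams(1.0, 2.0, 0.5), k=1)
        i, j = pair_index(0, 0, 1), pair_index(1, 1, 1)
        assert Q[i, j] == pytest.approx(0.5 * 3.0)  # joint +1 move
        assert Q[i, pair_index(1, 0, 1)] == pytest.approx(3.0)  # single-bin +1

    def test_different_amount_moves_forbidden(self):
        Q = build_rate_matrix(RateParams(1.3, 0.7, 2.0), k=2)
        assert Q[pair_index(0, 0, 2), pair_index(1, 2, 2)] == 0.0
        assert Q[pair_index(2, 0, 2), pair_index(0, 1, 2)] == 0.0

    @settings(deadline=None, max_examples=25)
    @given(rates_st, st.integers(1, 5))
    def test_rows_sum_to_zero(self, params, k):
        Q = build_rate_matrix(params, k)
        assert np.abs(Q.sum(axis=1)).max() < 1e-9
        off = Q - np.diag(np.diag(Q))
        assert off.min() >= 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_rate_matrix(RateParams(1, 1, 1), k=0)
        with pytest.raises(ValueError):
            RateParams(-1, 1, 1)


class TestTransitionMatrix:
    def test_t0_is_identity(self):
        Q = build_rate_matrix(RateParams(1, 1, 1), k=2)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(9))

    def test_chapman_kolmogorov(self):
        Q = build_rate_matrix(RateParams(0.5, 0.3, 0.8), k=2)
        s, t = 0.4, 1.1
        assert np.allclose(
            transition_matrix(Q, s) @ transition_matrix(Q, t),
            transition_matrix(Q, s + t),
            atol=1e-8,
        )

    def test_small_t_taylor_series(self):
        Q = build_rate_matrix(RateParams(1.0, 2.0, 0.5), k=1)
        t = 1e-4
        series = np.eye(4) + Q * t + Q @ Q * t**2 / 2
        assert np.allclose(transition_matrix(Q, t), series, atol=1e-10)

    def test_negative_time_rejected(self):
        Q = build_rate_matrix(RateParams(1, 1, 1), k=1)
        with pytest.raises(ValueError):
            transition_matrix(Q, -0.1)


class TestPairJoint:
    @pytest.fixture
    def mats(self):
        Q = build_rate_matrix(RateParams(0.4, 0.2, 0.6), k=2)
        return Q, [transition_matrix(Q, t) for t in (0.7, 0.3, 1.2)]

    def test_grand_total_one(self, mats):
        _, (P1, P2, P3) = mats
        assert pair_joint_adjacent(P1, P2, P3, 2).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_private_time_forces_identical_cells(self, mats):
        Q, (P1, _, _) = mats
        I = transition_matrix(Q, 0.0)
        F = pair_joint_adjacent(P1, I, I, 2)
        k1 = 3
        for ciA, ciB, cjA, cjB in itertools.product(range(k1), repeat=4):
            if ciA != ciB or cjA != cjB:
                assert F[pair_index(ciA, ciB, 2), pair_index(cjA, cjB, 2)] == pytest.approx(0.0, abs=1e-12)

    def test_swap_symmetry(self, mats):
        _, (P1, P2, P3) = mats
        F = pair_joint_adjacent(P1, P2, P3, 2)
        G = pair_joint_adjacent(P1, P3, P2, 2)
        k1 = 3
        for ciA, ciB, cjA, cjB in itertools.product(range(k1), repeat=4):
            assert F[pair_index(ciA, ciB, 2), pair_index(cjA, cjB, 2)] == pytest.approx(
                G[pair_index(ciB, ciA, 2), pair_index(cjB, cjA, 2)], abs=1e-12
            )

    def test_brute_force_oracle(self, mats):
        _, (P1, P2, P3) = mats
        F = pair_joint_adjacent(P1, P2, P3, 2)
        k = 2
        anc = pair_index(2, 2, k)
        for ciA, ciB, cjA, cjB in itertools.product(range(k + 1), repeat=4):
            expect = sum(
                P1[anc, pair_index(W, Y, k)]
                * P2[pair_index(W, Y, k), pair_index(ciA, cjA, k)]
                * P3[pair_index(W, Y, k), pair_index(ciB, cjB, k)]
                for W in range(k + 1)
                for Y in range(k + 1)
            )
            got = F[pair_index(ciA, ciB, k), pair_index(cjA, cjB, k)]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_k1_rejected(self):
        Q = build_rate_matrix(RateParams(1, 1, 1), k=1)
        P = transition_matrix(Q, 1.0)
        with pytest.raises(ValueError, match="k"):
            pair_joint_adjacent(P, P, P, 1)


class TestGenomeTransition:
    def test_toy_normalization(self):
        F = np.array([[0.1, 0.3], [0.2, 0.4]])
        M = genome_transition(F)
        assert np.allclose(M, [[0.25, 0.75], [1 / 3, 2 / 3]])

    def test_row_stochastic_and_block_structure(self):
        # vanishing (not exactly zero) private times: at exactly 0 the
        # off-diagonal rows of F vanish and normalization correctly errors
        Q = build_rate_matrix(RateParams(0.4, 0.2, 0.6), k=2)
        P1 = transition_matrix(Q, 0.7)
        I = transition_matrix(Q, 1e-8)
        M = genome_transition(pair_joint_adjacent(P1, I, I, 2))
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-9)
        diag_states = [pair_index(c, c, 2) for c in range(3)]
        off = [pair_index(a, b, 2) for a in range(3) for b in range(3) if a != b]
        for i in diag_states:
            assert M[i, off].sum() == pytest.approx(0.0, abs=1e-6)

    def test_zero_row_rejected(self):
        Q = build_rate_matrix(RateParams(0.4, 0.2, 0.6), k=2)
        P1 = transition_matrix(Q, 0.7)
        I = transition_matrix(Q, 0.0)
        with pytest.raises(ValueError, match="zero"):
            genome_transition(pair_joint_adjacent(P1, I, I, 2))


class TestSingleCellChain:
    def test_rows_sum_to_one(self):
        Q = build_rate_matrix(RateParams(0.3, 0.1, 0.4), k=3)
        M = single_cell_genome_transition(transition_matrix(Q, 0.8), 3)
        assert M.shape == (4, 4)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-9)

    def test_short_time_concentrates_on_diploid(self):
        Q = build_rate_matrix(RateParams(0.3, 0.1, 0.4), k=3)
        M = single_cell_genome_transition(transition_matrix(Q, 1e-6), 3)
        assert M[2, 2] > 0.999

    def test_consistent_with_degenerate_two_cell_chain(self):
        k = 2
        Q = build_rate_matrix(RateParams(0.4, 0.2, 0.6), k=k)
        t = 0.9
        P = transition_matrix(Q, t)
        I = transition_matrix(Q, 1e-9)
        M2 = genome_transition(pair_joint_adjacent(P, I, I, k))
        M1 = single_cell_genome_transition(P, k)
        diag = [pair_index(c, c, k) for c in range(k + 1)]
        sub = M2[np.ix_(diag, diag)]
        sub = sub / sub.sum(axis=1, keepdims=True)
        assert np.allclose(sub, M1, atol=1e-6)


class TestSteadyState:
    def test_symmetric_two_state(self):
        pi = steady_state(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert np.allclose(pi, [0.5, 0.5])

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_fixed_point_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.random((5, 5)) + 0.01
        M /= M.sum(axis=1, keepdims=True)
        pi = steady_state(M)
        assert np.abs(pi @ M - pi).max() < 1e-10
        assert pi.sum() == pytest.approx(1.0)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(7)
        M = rng.random((4, 4)) + 0.05
        M /= M.sum(axis=1, keepdims=True)
        pi = steady_state(M)
        powered = np.linalg.matrix_power(M, 1000)[0]
        assert np.allclose(pi, powered, atol=1e-8)


def test_monotone_divergence():
    """Probability mass on identical-cell transitions falls as t2+t3 grows."""
    Q = build_rate_matrix(RateParams(0.1, 0.02, 1.0), k=2)
    P1 = transition_matrix(Q, 1.0)
    diag = [pair_index(c, c, 2) for c in range(3)]
    prev = np.inf
    for tp in (1e-8, 0.25, 0.5, 1.0, 2.0):
        P = transition_matrix(Q, tp)
        M = genome_transition(pair_joint_adjacent(P1, P, P, 2))
        conc = sum(M[i, i] for i in diag)
        assert conc < prev + 1e-12
        prev = conc
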