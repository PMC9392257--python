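"""Continuous-time Markov model of copy-number evolution.

One lineage is modeled by a CTMC on the copy numbers ``(U, V)`` of two
adjacent genomic bins, each in ``{0, ..., k}``.  Three rates control the
process: ``alpha`` (extra rate of +/-1 events), ``beta`` (rate of events of
any magnitude), and ``gamma`` (relative rate of events spanning both bins).
A +/-1 event on a single bin has rate ``alpha + beta``; a larger jump has
rate ``beta``; events hitting both bins by the same amount are scaled by
``gamma``.  Moves that would leave the state space simply do not occur.

A pair of cells (A, B) shares a branch of length ``t1`` from a diploid
ancestor, then diverges for times ``t2`` and ``t3``.  Marginalizing the
unobserved divergence state yields the joint distribution of adjacent-bin
copy-number pairs in both cells, which row-normalized gives the transition
matrix of the genome-wide chain used as the HMM transition kernel.

State indexing is row-major: ``(U, V) -> U * (k+1) + V``; the two-cell HMM
state ``(cnA, cnB)`` uses the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig, expm

__all__ = [
    "RateParams",
    "PairTree",
    "pair_index",
    "build_rate_matrix",
    "transition_matrix",
    "pair_joint_adjacent",
    "genome_transition",
    "single_cell_genome_transition",
    "steady_state",
]

DEFAULT_K = 10  # maximum copy number, matching the tool's default


@dataclass(frozen=True)
class RateParams:
    """CNA rate parameters of the one-cell adjacent-bin CTMC."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class PairTree:
    """Branch lengths of the two-cell tree: shared t1, private t2 (A), t3 (B)."""

    t1: float
    t2: float
    t3: float

    def __post_init__(self) -> None:
        if min(self.t1, self.t2, self.t3) < 0:
            raise ValueError("branch lengths must be non-negative")


def pair_index(u: int, v: int, k: int) -> int:
    """Row-major index of state (u, v) in the (k+1)^2 pair state space."""
    return u * (k + 1) + v


def build_rate_matrix(params: RateParams, k: int) -> np.ndarray:
    """Instantaneous rate matrix of the adjacent-bin CTMC, ((k+1)^2 square).

    Off-diagonal entries: gamma*(alpha+beta) for joint +/-1 moves of both
    bins, gamma*beta for larger joint moves, alpha+beta for single-bin +/-1,
    beta for larger single-bin moves, 0 otherwise (in particular for moves
    changing the two bins by different amounts).  Diagonal = -row sum.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = (k + 1) ** 2
    a, b, g = params.alpha, params.beta, params.gamma
    Q = np.zeros((m, m))
    for u in range(k + 1):
        for v in range(k + 1):
            i = pair_index(u, v, k)
            # joint moves of both bins by the same signed amount
            for n in range(1, k + 1):
                for sgn in (+1, -1):
                    u2, v2 = u + sgn * n, v + sgn * n
                    if 0 <= u2 <= k and 0 <= v2 <= k:
                        Q[i, pair_index(u2, v2, k)] += g * (
                            (a + b) if n == 1 else b
                        )
            # single-bin moves
            for n in range(1, k + 1):
                rate = (a + b) if n == 1 else b
                for sgn in (+1, -1):
                    u2 = u + sgn * n
                    if 0 <= u2 <= k:
                        Q[i, pair_index(u2, v, k)] += rate
                    v2 = v + sgn * n
                    if 0 <= v2 <= k:
                        Q[i, pair_index(u, v2, k)] += rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); row-stochastic, tiny negative noise clipped."""
    if t < 0:
        raise ValueError("time must be non-negative")
    P = expm(Q * t)
    if P.min() < -1e-12:
        raise ValueError(
            f"matrix exponential produced entry {P.min():.3e} < -1e-12"
        )
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def pair_joint_adjacent(
    P1: np.ndarray, P2: np.ndarray, P3: np.ndarray, k: int
) -> np.ndarray:
    """Joint distribution F of adjacent-bin states in two cells.

    ``F[(ciA,ciB), (cjA,cjB)]`` is the probability that windows i, i+1 carry
    copy numbers (ciA, cjA) in cell A and (ciB, cjB) in cell B, obtained by
    summing over the unobserved divergence state (W, Y) reached from the
    diploid ancestral state (2, 2):

        sum_{W,Y} P1[(2,2),(W,Y)] P2[(W,Y),(ciA,cjA)] P3[(W,Y),(ciB,cjB)]

    All three inputs must be transition matrices of the same adjacent-bin
    chain.  The grand total of F is 1.
    """
    if k < 2:
        raise ValueError("k must be >= 2 so the diploid ancestral state exists")
    m = (k + 1) ** 2
    if not (P1.shape == P2.shape == P3.shape == (m, m)):
        raise ValueError("transition matrices do not match k")
    p1 = P1[pair_index(2, 2, k)]
    # [ (ciA,cjA), (ciB,cjB) ]
    F4 = (p1[:, None] * P2).T @ P3
    k1 = k + 1
    F = (
        F4.reshape(k1, k1, k1, k1)  # [ciA, cjA, ciB, cjB]
        .transpose(0, 2, 1, 3)  # [ciA, ciB, cjA, cjB]
        .reshape(m, m)
    )
    return F


def genome_transition(F: np.ndarray) -> np.ndarray:
    """Row-normalize the joint matrix F into the genome-wide chain M."""
    sums = F.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if bad.size:
        raise ValueError(f"all-zero row(s) in joint matrix at state {bad[0]}")
    return F / sums[:, None]


def single_cell_genome_transition(P: np.ndarray, k: int) -> np.ndarray:
    """Genome-wide chain for a single lineage at divergence time t.

    Conditioning the adjacent-bin distribution reached from the diploid
    state on the copy number of the first bin gives the (k+1)x(k+1)
    row-stochastic matrix m[U, V] = P[(2,2),(U,V)] / sum_V' P[(2,2),(U,V')].
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    row = P[pair_index(2, 2, k)].reshape(k + 1, k + 1)
    sums = row.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if bad.size:
        raise ValueError(f"zero marginal row for copy number {bad[0]}")
    return row / sums[:, None]


def steady_state(M: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Stationary distribution pi of a row-stochastic matrix (pi M = pi).

    Dominant left eigenvector, normalized to sum 1; falls back to power
    iteration when the eigensolver result is unusable.
    """
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("M is not row-stochastic")
    try:
        w, vl = eig(M, left=True, right=False)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(vl[:, i])
        pi = pi * np.sign(pi.sum() or 1.0)
        if pi.min() > -1e-10 and abs(np.abs(w[i]) - 1.0) < 1e-8:
            pi = np.clip(pi, 0.0, None)
            pi /= pi.sum()
            if np.max(np.abs(pi @ M - pi)) < 1e-8:
                return pi
    except np.linalg.LinAlgError:
        pass
    # power iteration fallback
    pi = np.full(M.shape[0], 1.0 / M.shape[0])
    for _ in range(100_000):
        nxt = pi @ M
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - pi)) < tol:
            return nxt
        pi = nxt
    raise ValueError("steady state did not converge (reducible chain?)")
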