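"""HMM engine: scaled forward likelihood, Viterbi decoding, Baum-Welch.

Chromosomes are independent: at the first window of each chromosome the
hidden-state distribution is reset to the chain's initial (steady-state)
vector, and the total log-likelihood is the sum over chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HmmModel", "forward_loglik", "viterbi", "baum_welch_init", "sample_states"]


@dataclass
class HmmModel:
    """A fully specified HMM over one window grid.

    ``log_emissions`` has one row per window and one column per hidden state;
    for a two-cell model the state (cnA, cnB) is indexed cnA*(k+1)+cnB and
    the row is the sum of the two cells' log emission columns.
    """

    transition: np.ndarray  # (S, S), row-stochastic
    initial: np.ndarray  # (S,), sums to 1
    log_emissions: np.ndarray  # (n_windows, S)
    chrom_slices: list = field(default_factory=list)  # [(lo, hi), ...]

    def __post_init__(self) -> None:
        S = self.transition.shape[0]
        if self.transition.shape != (S, S):
            raise ValueError("transition must be square")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if self.initial.shape != (S,) or not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial must be a length-S probability vector")
        if self.log_emissions.shape[1] != S:
            raise ValueError("emission matrix has wrong number of states")
        if not self.chrom_slices:
            self.chrom_slices = [(0, self.log_emissions.shape[0])]


def pair_log_emissions(logEA: np.ndarray, logEB: np.ndarray) -> np.ndarray:
    """Combine two single-cell (n, k+1) matrices into the (n, (k+1)^2) pair grid."""
    n, k1 = logEA.shape
    return (logEA[:, :, None] + logEB[:, None, :]).reshape(n, k1 * k1)


def _forward_chrom(logE, M, pi):
    shift = logE.max(axis=1)
    E = np.exp(logE - shift[:, None])
    alpha = pi * E[0]
    c = alpha.sum()
    if c <= 0 or not np.isfinite(c):
        return -np.inf
    ll = np.log(c) + shift[0]
    alpha = alpha / c
    for t in range(1, logE.shape[0]):
        alpha = (alpha @ M) * E[t]
        c = alpha.sum()
        if c <= 0 or not np.isfinite(c):
            return -np.inf
        ll += np.log(c) + shift[t]
        alpha /= c
    return ll


def forward_loglik(model: HmmModel) -> float:
    """Total forward log-likelihood, summed over independent chromosomes."""
    return float(
        sum(
            _forward_chrom(model.log_emissions[lo:hi], model.transition, model.initial)
            for lo, hi in model.chrom_slices
        )
    )


def viterbi(model: HmmModel) -> np.ndarray:
    """Most likely state path, decoded independently per chromosome.

    Ties are broken toward the smaller state index.
    """
    with np.errstate(divide="ignore"):
        logM = np.log(model.transition)
        logpi = np.log(model.initial)
    path = np.empty(model.log_emissions.shape[0], dtype=np.int64)
    for lo, hi in model.chrom_slices:
        logE = model.log_emissions[lo:hi]
        n = logE.shape[0]
        delta = logpi + logE[0]
        psi = np.empty((n, logE.shape[1]), dtype=np.int64)
        for t in range(1, n):
            mat = delta[:, None] + logM
            psi[t] = np.argmax(mat, axis=0)
            delta = mat[psi[t], np.arange(mat.shape[1])] + logE[t]
        state = int(np.argmax(delta))
        out = np.empty(n, dtype=np.int64)
        out[-1] = state
        for t in range(n - 1, 0, -1):
            state = int(psi[t, state])
            out[t - 1] = state
        path[lo:hi] = out
    return path


def sample_states(
    transition: np.ndarray,
    initial: np.ndarray,
    chrom_slices,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a hidden-state path, restarting from ``initial`` per chromosome."""
    S = transition.shape[0]
    n = max(hi for _, hi in chrom_slices)
    states = np.empty(n, dtype=np.int64)
    cum = np.cumsum(transition, axis=1)
    for lo, hi in chrom_slices:
        s = int(rng.choice(S, p=initial))
        states[lo] = s
        for t in range(lo + 1, hi):
            s = int(np.searchsorted(cum[s], rng.random(), side="right"))
            s = min(s, S - 1)
            states[t] = s
    return states


def _forward_backward_chrom(logE, M, pi):
    """Scaled forward-backward; returns (ll, gamma, xi_sum)."""
    n, S = logE.shape
    shift = logE.max(axis=1)
    E = np.exp(logE - shift[:, None])
    alpha = np.empty((n, S))
    c = np.empty(n)
    a = pi * E[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ M) * E[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((n, S))
    beta[-1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(n - 2, -1, -1):
        b = M @ (E[t + 1] * beta[t + 1])
        beta[t] = b / c[t + 1]
        xi_sum += (
            alpha[t][:, None] * M * (E[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        )
    gamma = alpha * beta
    ll = float(np.sum(np.log(c)) + np.sum(shift))
    return ll, gamma, xi_sum


def baum_welch_init(
    counts: np.ndarray,
    ctx,
    k: int,
    chrom_slices=None,
    max_iter: int = 100,
    rel_tol: float = 1e-6,
    refine_s: bool = True,
):
    """Estimate an unconstrained (k+1)-state genome chain by EM.

    Emissions are fixed by the copy-number structure (state c emits
    NB(c*mu_i/2*s + eps)) except for the library scaling factor ``s``, which
    is refined by one golden-section sweep per EM iteration.  The initial
    state distribution is held uniform.  Returns
    ``(transition, s, loglik_history)``; the log-likelihood sequence is
    non-decreasing up to numerical slack.
    """
    from scipy.optimize import minimize_scalar

    from .emissions import log_emission_matrix

    counts = np.asarray(counts)
    if chrom_slices is None:
        chrom_slices = [(0, len(counts))]
    S = k + 1
    # sticky start: strong self-transition is the right prior for CN tracks
    M = np.full((S, S), 0.01 / (S - 1))
    np.fill_diagonal(M, 0.99)
    pi = np.full(S, 1.0 / S)
    s = ctx.s
    history: list[float] = []
    for _ in range(max_iter):
        cur = ctx.with_s(s)
        logE = log_emission_matrix(counts, cur, k)
        ll = 0.0
        xi_tot = np.zeros((S, S))
        gam_tot = np.zeros(S)
        for lo, hi in chrom_slices:
            ll_c, gamma, xi = _forward_backward_chrom(logE[lo:hi], M, pi)
            ll += ll_c
            xi_tot += xi
            gam_tot += gamma[:-1].sum(axis=0)
        if not np.isfinite(ll):
            raise ValueError("non-finite likelihood in Baum-Welch")
        history.append(ll)
        denom = np.where(gam_tot > 0, gam_tot, 1.0)
        M_new = xi_tot / denom[:, None]
        # states never visited keep a self-loop
        empty = gam_tot <= 0
        M_new[empty] = 0.0
        M_new[empty, empty] = 1.0
        M_new /= M_new.sum(axis=1, keepdims=True)
        M = M_new
        if refine_s:
            def neg(log_s):
                cur2 = ctx.with_s(float(np.exp(log_s)))
                logE2 = log_emission_matrix(counts, cur2, k)
                return -sum(
                    _forward_chrom(logE2[lo:hi], M, pi) for lo, hi in chrom_slices
                )

            res = minimize_scalar(
                neg,
                bounds=(np.log(s) - np.log(3), np.log(s) + np.log(3)),
                method="bounded",
                options={"xatol": 1e-3},
            )
            if res.fun <= neg(np.log(s)):  # never move s downhill
                s = float(np.exp(res.x))
        if len(history) >= 2:
            prev = history[-2]
            if abs(history[-1] - prev) <= rel_tol * max(1.0, abs(prev)):
                break
    return M, s, history
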