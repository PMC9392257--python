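"""Stages 2-3: shared rate estimates and per-pair branch-length fits.

The CNA rates {alpha, beta, gamma} are assumed shared across all cells of a
tumor; per-cell estimates are combined by the component-wise median.  For
each pair of cells only the tree [t1, t2, t3] is then estimated, by BFGS on
the two-cell forward log-likelihood, starting from the single-cell total
branch lengths: t1* = min(tA, tB)/2, t2* = tA - t1*, t3* = tB - t1*.
Library scaling factors and the dispersion constants stay fixed at their
stage-1 values.  Joint Viterbi decoding of the fitted pair model yields one
paired integer profile per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

from . import hmm as hmm_mod
from .emissions import CellEmissionContext, log_emission_matrix
from .io import BinnedDepth, CopyNumberProfile
from .markov import (
    DEFAULT_K,
    PairTree,
    RateParams,
    build_rate_matrix,
    genome_transition,
    pair_joint_adjacent,
    steady_state,
    transition_matrix,
)
from .single_cell import SingleCellFit

__all__ = [
    "SharedRates",
    "PairFit",
    "combine_rates",
    "init_tree",
    "recalibrate_t",
    "fit_pair_tree",
    "run_all_pairs",
]

_T_FLOOR = 1e-6  # keeps the genome chain irreducible during optimization


@dataclass(frozen=True)
class SharedRates:
    alpha: float
    beta: float
    gamma: float

    def as_rate_params(self) -> RateParams:
        return RateParams(self.alpha, self.beta, self.gamma)


@dataclass
class PairFit:
    cell_a: str
    cell_b: str
    tree: PairTree
    loglik: float
    cnp_a: CopyNumberProfile
    cnp_b: CopyNumberProfile


def combine_rates(fits: list[SingleCellFit]) -> SharedRates:
    """Component-wise median of the per-cell rate estimates."""
    if not fits:
        raise ValueError("no fits to combine")
    return SharedRates(
        alpha=float(np.median([f.rates.alpha for f in fits])),
        beta=float(np.median([f.rates.beta for f in fits])),
        gamma=float(np.median([f.rates.gamma for f in fits])),
    )


def init_tree(tA: float, tB: float) -> PairTree:
    """Split the two single-cell total branch lengths into a starting tree."""
    if tA <= 0 or tB <= 0:
        raise ValueError("branch lengths must be positive")
    t1 = min(tA, tB) / 2.0
    return PairTree(t1=t1, t2=tA - t1, t3=tB - t1)


def recalibrate_t(
    cell: BinnedDepth,
    ctx: CellEmissionContext,
    shared: SharedRates,
    k: int = DEFAULT_K,
    t_init: float = 1.0,
) -> float:
    """Re-estimate one cell's total branch length under the shared rates.

    The single-cell likelihood only identifies the products (alpha*t, beta*t),
    so per-cell t estimates live on per-cell rate scales.  Before pairs are
    fitted, each cell's t is re-optimized (1-D) under the median rates so all
    initial tree splits share one time scale.
    """
    from scipy.optimize import minimize_scalar

    from .emissions import log_emission_matrix
    from .markov import single_cell_genome_transition

    Q = build_rate_matrix(shared.as_rate_params(), k)
    chrom_slices = cell.windows.chrom_slices()
    logE = log_emission_matrix(cell.counts, ctx, k)

    def neg(log_t):
        t = float(np.exp(log_t))
        try:
            M = single_cell_genome_transition(transition_matrix(Q, t), k)
            pi = steady_state(M)
            ll = hmm_mod.forward_loglik(hmm_mod.HmmModel(M, pi, logE, chrom_slices))
        except (ValueError, FloatingPointError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    lo, hi = np.log(max(t_init, _T_FLOOR)) - np.log(1e3), np.log(max(t_init, _T_FLOOR)) + np.log(1e3)
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4})
    return float(max(np.exp(res.x), _T_FLOOR))


class _PairModelBuilder:
    """Caches matrix exponentials across likelihood evaluations of one pair."""

    def __init__(self, shared: SharedRates, k: int):
        self.Q = build_rate_matrix(shared.as_rate_params(), k)
        self.k = k
        self._cache: dict = {}

    def P(self, t: float) -> np.ndarray:
        # exact float keys: line searches revisit identical values, while
        # finite-difference steps must see genuinely different matrices
        key = float(t)
        if key not in self._cache:
            self._cache[key] = transition_matrix(self.Q, max(t, 0.0))
        return self._cache[key]

    def chain(self, tree: PairTree):
        F = pair_joint_adjacent(self.P(tree.t1), self.P(tree.t2), self.P(tree.t3), self.k)
        M = genome_transition(F)
        return M, steady_state(M)


def fit_pair_tree(
    cell_a: BinnedDepth,
    cell_b: BinnedDepth,
    ctx_a: CellEmissionContext,
    ctx_b: CellEmissionContext,
    shared: SharedRates,
    t_a: float,
    t_b: float,
    k: int = DEFAULT_K,
    max_restarts: int = 3,
    seed: int = 0,
) -> PairFit:
    """Maximum-likelihood branch lengths and joint decoding for one pair."""
    if not cell_a.windows.same_grid(cell_b.windows):
        raise ValueError("pair members are on different window grids")
    chrom_slices = cell_a.windows.chrom_slices()
    builder = _PairModelBuilder(shared, k)
    logE = hmm_mod.pair_log_emissions(
        log_emission_matrix(cell_a.counts, ctx_a, k),
        log_emission_matrix(cell_b.counts, ctx_b, k),
    )

    def neg_loglik(log_t):
        t1, t2, t3 = np.maximum(np.exp(log_t), _T_FLOOR)
        if not np.all(np.isfinite((t1, t2, t3))):
            return 1e12
        try:
            M, pi = builder.chain(PairTree(t1, t2, t3))
            model = hmm_mod.HmmModel(M, pi, logE, chrom_slices)
            ll = hmm_mod.forward_loglik(model)
        except (ValueError, FloatingPointError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    start_tree = init_tree(t_a, t_b)
    x0 = np.log(np.maximum([start_tree.t1, start_tree.t2, start_tree.t3], _T_FLOOR))
    rng = np.random.default_rng(seed)
    best = None
    start = x0
    for attempt in range(max_restarts + 1):
        res = minimize(
            neg_loglik,
            start,
            method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-9, "gtol": 1e-5},
        )
        if best is None or res.fun < best.fun:
            best = res
        if np.isfinite(res.fun) and res.fun < 1e11:
            break
        start = x0 + rng.normal(scale=0.5, size=3)
    if best is None or best.fun >= 1e11:
        raise ValueError(
            f"pair optimization failed for ({cell_a.cell_id}, {cell_b.cell_id})"
        )

    t1, t2, t3 = np.maximum(np.exp(best.x), _T_FLOOR)
    tree = PairTree(float(t1), float(t2), float(t3))
    M, pi = builder.chain(tree)
    model = hmm_mod.HmmModel(M, pi, logE, chrom_slices)
    path = hmm_mod.viterbi(model)
    k1 = k + 1
    cn_a = (path // k1).astype(float)
    cn_b = (path % k1).astype(float)
    return PairFit(
        cell_a=cell_a.cell_id,
        cell_b=cell_b.cell_id,
        tree=tree,
        loglik=float(-best.fun),
        cnp_a=CopyNumberProfile(cell_a.windows, cn_a, True, cell_a.cell_id),
        cnp_b=CopyNumberProfile(cell_b.windows, cn_b, True, cell_b.cell_id),
    )


def run_all_pairs(
    cells: dict[str, BinnedDepth],
    fits: dict[str, SingleCellFit],
    contexts: dict[str, CellEmissionContext],
    shared: SharedRates,
    pair_list: list[tuple[str, str]] | None = None,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> dict[tuple[str, str], PairFit]:
    """Fit every requested pair independently; keys are (A, B) with A < B."""
    if pair_list is None:
        pair_list = list(combinations(sorted(cells), 2))
    if not pair_list:
        warnings.warn("empty pair list; nothing to fit")
        return {}
    needed = sorted({c for ab in pair_list for c in ab})
    for c in needed:
        if c not in cells:
            raise ValueError(f"unknown cell id {c}")
    # put every cell's total branch length on the shared-rate time scale
    t_shared = {
        c: recalibrate_t(cells[c], contexts[c], shared, k=k, t_init=fits[c].t)
        for c in needed
    }
    out: dict[tuple[str, str], PairFit] = {}
    for a, b in pair_list:
        a, b = sorted((a, b))
        if (a, b) in out:
            continue
        out[(a, b)] = fit_pair_tree(
            cells[a],
            cells[b],
            contexts[a],
            contexts[b],
            shared,
            t_shared[a],
            t_shared[b],
            k=k,
            seed=seed,
        )
    return out
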