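"""Stage 1: diploid baseline estimation and independent per-cell fits.

Matched diploid cells provide the per-window mean depth ``mu_i`` and the
quadratic mean-variance relationship {a, b, c}.  Each tumor cell is then
fitted independently: a modified Baum-Welch pass estimates an unconstrained
copy-number chain and the library scaling factor ``s``; those estimates seed
a BFGS maximization of the forward log-likelihood over {s, alpha, beta,
gamma, t}; Viterbi decoding yields the cell's independent integer profile.
``t`` is the total branch length from the ancestral diploid to the cell and
is the quantity the pairwise stage splits into shared and private parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear, minimize

from . import hmm as hmm_mod
from .emissions import CellEmissionContext, DispersionModel, log_emission_matrix
from .io import BinnedDepth, CopyNumberProfile, GenomicWindows, check_same_grid
from .markov import (
    DEFAULT_K,
    RateParams,
    build_rate_matrix,
    single_cell_genome_transition,
    steady_state,
    transition_matrix,
)

__all__ = ["DiploidProfile", "SingleCellFit", "average_diploid", "fit_dispersion", "fit_cell"]

# starting rates for the moment-matching initialization; the BFGS refinement
# is free to move far from these
_INIT_RATES = RateParams(alpha=0.2, beta=0.02, gamma=0.2)


@dataclass
class DiploidProfile:
    """Per-window mean and across-cell sample variance of diploid read depth."""

    windows: GenomicWindows
    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if not (len(self.mean) == len(self.variance) == len(self.windows)):
            raise ValueError("length mismatch")
        if np.any(self.mean < 0) or np.any(self.variance < 0):
            raise ValueError("mean and variance must be non-negative")


@dataclass
class SingleCellFit:
    """Result of one independent single-cell fit."""

    cell_id: str
    s: float
    rates: RateParams
    t: float
    loglik: float
    cnp: CopyNumberProfile


def average_diploid(cells: list[BinnedDepth]) -> DiploidProfile:
    """Per-window mean and unbiased variance across >= 2 diploid cells."""
    if len(cells) < 2:
        raise ValueError("need at least 2 diploid cells")
    windows = check_same_grid(cells)
    mat = np.stack([c.counts for c in cells]).astype(float)
    return DiploidProfile(windows, mat.mean(axis=0), mat.var(axis=0, ddof=1))


def fit_dispersion(
    diploid: DiploidProfile, epsilon: float = 0.01, min_windows: int = 50
) -> DispersionModel:
    """Fit sigma^2 = a*lambda^2 + b*lambda + c to the diploid (mean, variance)
    pairs by least squares with a >= 0, c >= 0."""
    keep = diploid.mean > 0
    lam = diploid.mean[keep]
    var = diploid.variance[keep]
    if len(lam) < min_windows:
        raise ValueError(f"need >= {min_windows} windows with positive mean")
    if np.ptp(lam) <= 0:
        raise ValueError("degenerate design: all window means are equal")
    X = np.column_stack([lam**2, lam, np.ones_like(lam)])
    res = lsq_linear(X, var, bounds=([0.0, -np.inf, 0.0], np.inf))
    a, b, c = res.x
    return DispersionModel(a=float(a), b=float(b), c=float(c), epsilon=epsilon)


def _single_cell_model(params, ctx, logE_cache, counts, chrom_slices, k):
    """Build the single-cell HMM at (s, alpha, beta, gamma, t)."""
    s, alpha, beta, gamma, t = params
    Q = build_rate_matrix(RateParams(alpha, beta, gamma), k)
    P = transition_matrix(Q, t)
    M = single_cell_genome_transition(P, k)
    pi = steady_state(M)
    key = float(s)
    if key not in logE_cache:
        logE_cache[key] = log_emission_matrix(counts, ctx.with_s(s), k)
    return hmm_mod.HmmModel(M, pi, logE_cache[key], chrom_slices)


def _fill_masked(cn: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace values at masked windows with the nearest unmasked neighbor."""
    if mask.all():
        return cn
    idx = np.arange(len(cn))
    good = idx[mask]
    if good.size == 0:
        return cn
    nearest = good[np.argmin(np.abs(idx[:, None] - good[None, :]), axis=1)]
    out = cn.copy()
    out[~mask] = cn[nearest[~mask]]
    return out


def fit_cell(
    cell: BinnedDepth,
    diploid: DiploidProfile,
    dispersion: DispersionModel,
    k: int = DEFAULT_K,
    max_restarts: int = 3,
    seed: int = 0,
) -> SingleCellFit:
    """Independent maximum-likelihood fit of one tumor cell.

    Pipeline: Baum-Welch initialization of an unconstrained chain and of s;
    moment-matching of the model chain to the Baum-Welch chain over a grid of
    candidate t; L-BFGS-B refinement of log{s, alpha, beta, gamma, t} on the
    forward log-likelihood; Viterbi decoding of the integer profile.
    """
    if not cell.windows.same_grid(diploid.windows):
        raise ValueError("cell and diploid grids differ")
    chrom_slices = cell.windows.chrom_slices()
    ctx = CellEmissionContext(1.0, diploid.mean, dispersion)
    mu_tot = diploid.mean[ctx.mask].sum()
    s0 = float(cell.counts[ctx.mask].sum() / mu_tot) if mu_tot > 0 else 1.0
    s0 = max(s0, 1e-6)

    bw_chain, s_bw, _ = hmm_mod.baum_welch_init(
        cell.counts, ctx.with_s(s0), k, chrom_slices
    )

    # moment-match t: minimize Frobenius distance to the Baum-Welch chain
    t_grid = np.geomspace(1e-3, 10.0, 25)
    r0 = _INIT_RATES
    Q0 = build_rate_matrix(r0, k)
    best_t, best_d = t_grid[0], np.inf
    for t in t_grid:
        Mt = single_cell_genome_transition(transition_matrix(Q0, t), k)
        d = float(np.linalg.norm(Mt - bw_chain))
        if d < best_d:
            best_t, best_d = t, d

    logE_cache: dict = {}

    def neg_loglik(logp):
        p = np.exp(logp)
        if not np.all(np.isfinite(p)):
            return 1e12
        try:
            model = _single_cell_model(p, ctx, logE_cache, cell.counts, chrom_slices, k)
            ll = hmm_mod.forward_loglik(model)
        except (ValueError, FloatingPointError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.log([s_bw, r0.alpha, r0.beta, r0.gamma, best_t])
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
        start = x0 + rng.normal(scale=0.5, size=x0.shape)
    if best is None or best.fun >= 1e11:
        raise ValueError(f"single-cell optimization failed for {cell.cell_id}")

    s, alpha, beta, gamma, t = np.exp(best.x)
    model = _single_cell_model(
        (s, alpha, beta, gamma, t), ctx, logE_cache, cell.counts, chrom_slices, k
    )
    path = hmm_mod.viterbi(model).astype(float)
    path = _fill_masked(path, ctx.mask)
    cnp = CopyNumberProfile(
        cell.windows, path, integer_valued=True, cell_id=cell.cell_id
    )
    return SingleCellFit(
        cell_id=cell.cell_id,
        s=float(s),
        rates=RateParams(float(alpha), float(beta), float(gamma)),
        t=float(t),
        loglik=float(-best.fun),
        cnp=cnp,
    )
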