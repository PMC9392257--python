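"""Negative-binomial read-count emission model.

The expected read count of window i in a cell with copy number ``cn`` is

    lambda_i = (cn * mu_i / 2) * s + epsilon

where ``mu_i`` is the mean diploid read depth of the window, ``s`` the cell's
library size scaling factor, and ``epsilon`` a small constant sequencing
error term that keeps zero-copy states emittable.  Counts follow a negative
binomial with this mean and variance ``a*lambda^2 + b*lambda + c``, the
quadratic mean-variance relationship learned from diploid cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import nbinom

__all__ = [
    "DispersionModel",
    "CellEmissionContext",
    "nb_size_prob",
    "emission_logpmf",
    "pair_emission_logpmf",
    "log_emission_matrix",
    "sample_counts",
]

# overdispersion floor: variance below lambda*(1+_VAR_FLOOR_REL) is lifted
# to it, since a fitted {a,b,c} may dip below the Poisson line at small lambda
_VAR_FLOOR_REL = 1e-6


@dataclass(frozen=True)
class DispersionModel:
    """Coefficients of the variance function sigma^2 = a*l^2 + b*l + c."""

    a: float
    b: float
    c: float
    epsilon: float = 0.01  # constant sequencing error term, in reads

    def __post_init__(self) -> None:
        if self.a < 0 or self.c < 0:
            raise ValueError("a and c must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def variance(self, lam):
        return self.a * lam**2 + self.b * lam + self.c


@dataclass
class CellEmissionContext:
    """Everything needed to score one cell's counts: s, mu, dispersion."""

    s: float
    mu: np.ndarray  # mean diploid depth per window
    dispersion: DispersionModel
    mask: np.ndarray = field(default=None, repr=False)  # windows with mu > 0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("library size scaling factor must be positive")
        mu = np.asarray(self.mu, dtype=float)
        if np.any(mu < 0):
            raise ValueError("mu must be non-negative")
        self.mu = mu
        if self.mask is None:
            self.mask = mu > 0

    def with_s(self, s: float) -> "CellEmissionContext":
        return CellEmissionContext(s, self.mu, self.dispersion, self.mask)


def nb_size_prob(lam, disp: DispersionModel, warn: bool = False):
    """(size, p) parameters of NB(mean=lam, var=a*lam^2+b*lam+c).

    size = lam^2/(var-lam), p = lam/var.  Variance at or below the mean is
    floored just above it (near-Poisson) rather than rejected.
    """
    lam = np.asarray(lam, dtype=float)
    var = disp.variance(lam)
    floor = lam * (1.0 + _VAR_FLOOR_REL)
    low = var <= floor
    if warn and np.any(low):
        warnings.warn("variance at or below the mean; floored to near-Poisson")
    var = np.where(low, floor, var)
    size = lam**2 / (var - lam)
    p = lam / var
    return size, p


def _lambda(cn, ctx: CellEmissionContext, i):
    return (np.asarray(cn, dtype=float) * ctx.mu[i] / 2.0) * ctx.s + ctx.dispersion.epsilon


def emission_logpmf(x, cn, ctx: CellEmissionContext, i) -> float:
    """log P(X_i = x | CN_i = cn) for one cell, one window."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("counts must be non-negative")
    lam = _lambda(cn, ctx, i)
    size, p = nb_size_prob(lam, ctx.dispersion)
    return nbinom.logpmf(x, size, p)


def pair_emission_logpmf(xA, xB, cnA, cnB, ctxA, ctxB, i) -> float:
    """Joint emission of a window in two cells: conditionally independent."""
    return emission_logpmf(xA, cnA, ctxA, i) + emission_logpmf(xB, cnB, ctxB, i)


def log_emission_matrix(counts: np.ndarray, ctx: CellEmissionContext, k: int) -> np.ndarray:
    """(n_windows, k+1) matrix of log NB pmfs, one column per copy number.

    Windows with mu == 0 are masked: their rows are set to 0 so they carry no
    likelihood information.
    """
    counts = np.asarray(counts)
    n = len(counts)
    if len(ctx.mu) != n:
        raise ValueError("counts and mu length mismatch")
    out = np.empty((n, k + 1))
    for cn in range(k + 1):
        lam = (cn * ctx.mu / 2.0) * ctx.s + ctx.dispersion.epsilon
        size, p = nb_size_prob(lam, ctx.dispersion)
        out[:, cn] = nbinom.logpmf(counts, size, p)
    out[~ctx.mask, :] = 0.0
    return out


def sample_counts(cn, ctx: CellEmissionContext, rng: np.random.Generator) -> np.ndarray:
    """Draw one count per window given per-window copy numbers ``cn``."""
    cn = np.asarray(cn, dtype=float)
    lam = (cn * ctx.mu / 2.0) * ctx.s + ctx.dispersion.epsilon
    size, p = nb_size_prob(lam, ctx.dispersion)
    return rng.negative_binomial(size, p)
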