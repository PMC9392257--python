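"""Stage 4: summarize each cell's paired profiles into a consensus profile.

A cell that appears in n-1 pairs has n-1 paired Viterbi profiles; the
consensus takes the per-window mean (default), median, or mode across them.
Mean and median may be fractional, which genuinely reflects CNAs split
across window boundaries; the mode stays integer.  To save computation the
pairs can be restricted to the kappa nearest neighbors of each cell, ranked
by Euclidean distance between the independent single-cell profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CopyNumberProfile, check_same_grid

__all__ = ["ConsensusConfig", "nearest_neighbors", "consensus_profile"]

DEFAULT_KAPPA = 10  # recommended neighborhood size


@dataclass(frozen=True)
class ConsensusConfig:
    summary: str = "mean"  # mean | median | mode
    kappa: int | str = DEFAULT_KAPPA  # int >= 1 or "all"

    def __post_init__(self) -> None:
        if self.summary not in ("mean", "median", "mode"):
            raise ValueError("summary must be mean, median, or mode")
        if self.kappa != "all" and (not isinstance(self.kappa, int) or self.kappa < 1):
            raise ValueError('kappa must be a positive integer or "all"')


def nearest_neighbors(
    target: str, cnps: dict[str, CopyNumberProfile], kappa: int | str
) -> list[str]:
    """The kappa cells closest to ``target`` by Euclidean profile distance.

    Ascending by distance, ties broken lexicographically by cell id.
    """
    check_same_grid(list(cnps.values()))
    if target not in cnps:
        raise ValueError(f"unknown cell id {target}")
    others = [c for c in cnps if c != target]
    if kappa == "all":
        kappa = len(others)
    if kappa >= len(others) and kappa != len(others):
        warnings.warn(
            f"kappa={kappa} >= {len(others)} other cells; returning all"
        )
        kappa = len(others)
    ref = cnps[target].cn
    ranked = sorted(
        others,
        key=lambda c: (float(np.linalg.norm(cnps[c].cn - ref)), c),
    )
    return ranked[:kappa]


def consensus_profile(
    paired_cnps: list[CopyNumberProfile], cfg: ConsensusConfig = ConsensusConfig()
) -> CopyNumberProfile:
    """Per-window summary across the paired profiles of one cell.

    Mode ties break toward the smaller copy number.  The denominator is the
    number of paired profiles actually supplied (pairs excluded by the
    nearest-neighbor selection are simply absent).
    """
    if not paired_cnps:
        raise ValueError("no paired profiles to summarize")
    windows = check_same_grid(paired_cnps)
    mat = np.stack([p.cn for p in paired_cnps])
    if cfg.summary == "mean":
        cn = mat.mean(axis=0)
        integer = bool(np.allclose(cn, np.round(cn)))
    elif cfg.summary == "median":
        cn = np.median(mat, axis=0)
        integer = bool(np.allclose(cn, np.round(cn)))
    else:  # mode over integer profiles; np.argmax picks the smallest CN on ties
        imat = np.round(mat).astype(int)
        top = int(imat.max())
        cn = np.empty(mat.shape[1])
        for j in range(mat.shape[1]):
            cn[j] = np.argmax(np.bincount(imat[:, j], minlength=top + 1))
        integer = True
    cell_id = paired_cnps[0].cell_id
    return CopyNumberProfile(windows, cn, integer_valued=integer, cell_id=cell_id)
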