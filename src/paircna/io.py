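"""Readers and writers for binned depth files, copy-number profiles,
distance matrices and Newick trees.

Coordinate convention is BED-like throughout: 0-based, half-open
``[start, end)`` intervals.  Chromosome order is file order; chromosome
boundaries are derived from changes of the chrom field and drive the
per-chromosome resets of the HMM downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "GenomicWindows",
    "BinnedDepth",
    "CopyNumberProfile",
    "DistanceMatrix",
    "read_depth_file",
    "write_depth_file",
    "read_cnp",
    "write_cnp",
    "read_newick",
    "write_newick",
    "read_matrix",
    "write_matrix",
    "check_same_grid",
]


@dataclass(frozen=True)
class GenomicWindows:
    """An ordered grid of genomic windows shared by all cells of one analysis.

    Within each chromosome windows must be sorted and non-overlapping; they may
    be contiguous or gapped but never reordered.
    """

    chroms: np.ndarray  # dtype=object / str, one per window
    starts: np.ndarray  # int64, 0-based inclusive
    ends: np.ndarray  # int64, exclusive

    def __post_init__(self) -> None:
        chroms = np.asarray(self.chroms, dtype=object)
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if len(chroms) == 0:
            raise ValueError("empty window grid")
        if np.any(ends <= starts):
            raise ValueError("windows must satisfy start < end")
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        # per-chromosome ordering checks
        for lo, hi in self.chrom_slices():
            s, e = starts[lo:hi], ends[lo:hi]
            if np.any(s[1:] < e[:-1]):
                raise ValueError(
                    f"windows overlap or are out of order on {chroms[lo]}"
                )

    def __len__(self) -> int:
        return len(self.chroms)

    def chrom_slices(self) -> list[tuple[int, int]]:
        """(start, stop) index ranges of each chromosome block, in file order."""
        out = []
        lo = 0
        for i in range(1, len(self.chroms) + 1):
            if i == len(self.chroms) or self.chroms[i] != self.chroms[lo]:
                out.append((lo, i))
                lo = i
        # a chromosome name must not reappear after an intervening one
        seen: dict[object, int] = {}
        for j, (a, _) in enumerate(out):
            name = self.chroms[a]
            if name in seen:
                raise ValueError(f"chromosome {name} appears in two blocks")
            seen[name] = j
        return out

    def same_grid(self, other: "GenomicWindows") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )


@dataclass
class BinnedDepth:
    """Per-cell read counts over a shared window grid (the HMM observations)."""

    windows: GenomicWindows
    counts: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if len(counts) != len(self.windows):
            raise ValueError("counts length does not match window grid")
        if np.any(counts < 0):
            raise ValueError("negative read count")
        self.counts = counts


@dataclass
class CopyNumberProfile:
    """Per-window copy number; fractional unless ``integer_valued``."""

    windows: GenomicWindows
    cn: np.ndarray
    integer_valued: bool = False
    cell_id: str = ""

    def __post_init__(self) -> None:
        cn = np.asarray(self.cn, dtype=float)
        if len(cn) != len(self.windows):
            raise ValueError("cn length does not match window grid")
        if np.any(cn < 0) or not np.all(np.isfinite(cn)):
            raise ValueError("copy numbers must be finite and non-negative")
        if self.integer_valued and not np.allclose(cn, np.round(cn)):
            raise ValueError("integer_valued profile holds non-integer values")
        self.cn = cn


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if np.any(d < 0):
            raise ValueError("negative distance")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix is asymmetric beyond 1e-9")
        if not np.allclose(np.diag(d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        self.d = d


def _parse_rows(path, n_value_cols: int, value_parser, what: str):
    chroms, starts, ends, values = [], [], [], []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 + n_value_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= {3 + n_value_cols} "
                    f"tab-separated columns, got {len(fields)}"
                )
            if len(fields) > 3 + n_value_cols and not warned_extra:
                warnings.warn(
                    f"{path}: extra columns after column {3 + n_value_cols} ignored"
                )
                warned_extra = True
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer start/end"
                ) from exc
            try:
                vals = [value_parser(f) for f in fields[3 : 3 + n_value_cols]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed {what} field"
                ) from exc
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            values.append(vals)
    if not chroms:
        raise ValueError(f"{path}: empty file")
    windows = GenomicWindows(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )
    return windows, np.array(values)


def read_depth_file(path, cell_id: str | None = None) -> BinnedDepth:
    """Read a 4-column depth TSV (chrom, start, end, count), bedtools-style.

    Rejects negative or non-integer counts with an error naming the line.
    """

    def _count(f: str) -> int:
        v = int(f)
        if v < 0:
            raise ValueError("negative count")
        return v

    windows, vals = _parse_rows(path, 1, _count, "count")
    cid = cell_id if cell_id is not None else str(path)
    return BinnedDepth(windows, vals[:, 0].astype(np.int64), cell_id=cid)


def write_depth_file(depth: BinnedDepth, path) -> None:
    w = depth.windows
    with open(path, "w") as fh:
        for c, s, e, x in zip(w.chroms, w.starts, w.ends, depth.counts):
            fh.write(f"{c}\t{s}\t{e}\t{x}\n")


def read_cnp(path, cell_id: str | None = None) -> CopyNumberProfile:
    """Read a 4-column copy-number TSV (chrom, start, end, cn)."""
    windows, vals = _parse_rows(path, 1, float, "copy number")
    cn = vals[:, 0]
    integer = bool(np.allclose(cn, np.round(cn)))
    cid = cell_id if cell_id is not None else str(path)
    return CopyNumberProfile(windows, cn, integer_valued=integer, cell_id=cid)


def write_cnp(profile: CopyNumberProfile, path, round_to_int: bool = False) -> None:
    """Write a profile as 4-column TSV; ``round_to_int`` rounds half-up."""
    w = profile.windows
    cn = profile.cn
    if round_to_int:
        cn = np.floor(cn + 0.5)
    with open(path, "w") as fh:
        for c, s, e, v in zip(w.chroms, w.starts, w.ends, cn):
            if round_to_int or profile.integer_valued:
                fh.write(f"{c}\t{s}\t{e}\t{int(round(v))}\n")
            else:
                fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")


def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"{path}: Newick parse error: {exc}") from exc


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_matrix(path) -> DistanceMatrix:
    """Read a labeled square TSV distance matrix (header row + label column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(labels, df.to_numpy(dtype=float))


def write_matrix(dm: DistanceMatrix, path, phylip: bool = False) -> None:
    if phylip:
        with open(path, "w") as fh:
            fh.write(f"{len(dm.labels)}\n")
            for lab, row in zip(dm.labels, dm.d):
                fh.write(lab + "\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")
        return
    df = pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels)
    df.to_csv(path, sep="\t")


def check_same_grid(items) -> GenomicWindows:
    """Assert all depths/profiles share one window grid; return it."""
    items = list(items)
    if not items:
        raise ValueError("no items to check")
    ref = items[0].windows
    for it in items[1:]:
        if not ref.same_grid(it.windows):
            raise ValueError(
                f"window grid of {getattr(it, 'cell_id', '?')} differs from "
                f"{getattr(items[0], 'cell_id', '?')}"
            )
    return ref
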