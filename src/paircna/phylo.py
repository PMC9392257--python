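"""Distance matrices, neighbor-joining, and Robinson-Foulds comparison.

Under the two-cell model the sum t2 + t3 of the private branch lengths is a
pairwise evolutionary distance, and neighbor-joining on the t2+t3 matrix
reconstructs the tumor phylogeny.  The Euclidean distance between profiles
is kept as the standard baseline metric.  Robinson-Foulds distances use the
unweighted bipartition-count convention; rooted inputs are unrooted first.
"""

from __future__ import annotations

import io as _io
import warnings
from itertools import combinations

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .io import CopyNumberProfile, DistanceMatrix, check_same_grid

__all__ = ["t2t3_matrix", "euclidean_matrix", "neighbor_joining", "robinson_foulds"]


def t2t3_matrix(pair_fits: dict, labels: list[str] | None = None) -> DistanceMatrix:
    """Assemble d(A,B) = t2 + t3 from the pair fits.

    Every unordered pair must be present: a neighbor-restricted pair set
    cannot produce a complete distance matrix.
    """
    if labels is None:
        labels = sorted({c for ab in pair_fits for c in ab})
    missing = [
        (a, b) for a, b in combinations(sorted(labels), 2) if (a, b) not in pair_fits
    ]
    if missing:
        raise ValueError(f"missing pair fits: {missing}")
    n = len(labels)
    d = np.zeros((n, n))
    pos = {c: i for i, c in enumerate(labels)}
    for (a, b), fit in pair_fits.items():
        if a in pos and b in pos:
            val = fit.tree.t2 + fit.tree.t3
            d[pos[a], pos[b]] = d[pos[b], pos[a]] = val
    return DistanceMatrix(labels, d)


def euclidean_matrix(cnps: dict[str, CopyNumberProfile]) -> DistanceMatrix:
    """Pairwise Euclidean distances between copy-number profiles."""
    labels = sorted(cnps)
    check_same_grid([cnps[c] for c in labels])
    mat = np.stack([cnps[c].cn for c in labels])
    diff = mat[:, None, :] - mat[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    sk_tree = _skbio_nj(_SkbioDM(dm.d, ids=dm.labels), neg_as_zero=False)
    buf = _io.StringIO()
    sk_tree.write(buf, format="newick")
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
    n_neg = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_neg += 1
    if n_neg:
        warnings.warn(f"clamped {n_neg} negative branch length(s) to 0")
    return tree


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted RF distance: symmetric difference of non-trivial bipartitions."""
    leaves1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(
            f"leaf sets differ: {sorted(leaves1 ^ leaves2)} not shared"
        )
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    for t in (a, b):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
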