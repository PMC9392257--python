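"""Line-segments tumor-evolution simulator and accuracy metrics.

The simulated genome is a multiset of line segments over a fixed reference
``[0, genome_length)``; the ploidy at a reference point is the number of
segments covering it, and the ancestral diploid carries two full-length
segments.  CNAs arrive along each tree branch as a Poisson process; each
event picks a type (amplification or deletion), a uniform start, and a
truncated-exponential length, then duplicates or removes the overlapped
portion of one uniformly chosen covering segment.  Events are inherited:
a child's genome is its parent's genome plus the events of its own branch.
Because events create paired breakpoints and the genome length never
changes, this model is deliberately non-Markovian along the genome and
different in structure from the inference model.

Read depths are drawn per window from a negative binomial whose mean is
proportional to the window's average ploidy, scaled so the expected total
per cell equals ``total_reads``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import BinnedDepth, CopyNumberProfile, GenomicWindows

__all__ = [
    "SimTreeSpec",
    "SimParams",
    "SegmentGenome",
    "make_windows",
    "build_sim_tree",
    "simulate_cnas",
    "true_window_cnp",
    "simulate_reads",
    "simulate_diploid",
    "sse",
    "breakpoints",
    "breakpoint_stats",
]


@dataclass(frozen=True)
class SimTreeSpec:
    """Tree shape for the simulation: A pectinate ultrametric, B balanced
    ultrametric, C pectinate uniform-branch, D pectinate with logarithmically
    decaying terminal branches."""

    structure: str = "A"
    n_leaves: int = 128
    root_branch: float = 1.0
    height_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.structure not in "ABCD":
            raise ValueError("structure must be one of A, B, C, D")
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if self.structure == "B" and self.n_leaves & (self.n_leaves - 1):
            raise ValueError("balanced tree needs a power-of-2 leaf count")


@dataclass(frozen=True)
class SimParams:
    """Simulation constants; defaults reproduce the study conditions:
    12,397 windows, 4,000,000 expected reads per cell (322.7 per window),
    negative-binomial size 50, genome length 100 arbitrary units."""

    genome_length: float = 100.0
    amp_rate: float = 0.05  # events / unit time / unit genome
    del_rate: float = 0.05
    amp_mean_len: float = 0.01  # expected event length, fraction of genome
    del_mean_len: float = 0.01
    n_windows: int = 12_397
    n_chroms: int = 22
    window_bp: int = 250_000
    total_reads: float = 4_000_000.0
    nb_size: float = 50.0
    n_diploid: int = 100

    def __post_init__(self) -> None:
        if (
            min(
                self.genome_length,
                self.amp_mean_len,
                self.del_mean_len,
                self.total_reads,
                self.nb_size,
            ) <= 0
            or min(self.amp_rate, self.del_rate) < 0
            or self.n_windows < 1
        ):
            raise ValueError("simulation parameters must be positive")
        if max(self.amp_mean_len, self.del_mean_len) >= 1.0:
            raise ValueError("mean event length must be < genome length")


@dataclass
class SegmentGenome:
    """A mutated genome as a multiset of reference-coordinate segments."""

    segments: list[tuple[float, float]]
    genome_length: float
    events: list[tuple] = field(default_factory=list)  # (kind, start, end)

    @classmethod
    def diploid(cls, genome_length: float) -> "SegmentGenome":
        return cls([(0.0, genome_length), (0.0, genome_length)], genome_length)

    def copy(self) -> "SegmentGenome":
        return SegmentGenome(list(self.segments), self.genome_length, list(self.events))

    def _covering(self, lo: float, hi: float) -> list[int]:
        return [i for i, (s, e) in enumerate(self.segments) if s < hi and e > lo]

    def apply_event(self, kind: str, lo: float, hi: float, rng: np.random.Generator) -> None:
        """Duplicate (amp) or excise (del) the overlap of one covering segment."""
        idx = self._covering(lo, hi)
        if not idx:
            return  # the event hit a fully deleted region; ploidy 0 stays 0
        i = int(rng.choice(idx))
        s, e = self.segments[i]
        a, b = max(s, lo), min(e, hi)
        if kind == "amp":
            self.segments.append((a, b))
        else:
            del self.segments[i]
            if s < a:
                self.segments.append((s, a))
            if b < e:
                self.segments.append((b, e))
        self.events.append((kind, a, b))

    def ploidy_breaks(self) -> tuple[np.ndarray, np.ndarray]:
        """Step-function ploidy: boundaries x_0..x_m and values on each piece."""
        pts = {0.0, self.genome_length}
        for s, e in self.segments:
            pts.add(s)
            pts.add(e)
        xs = np.array(sorted(pts))
        vals = np.zeros(len(xs) - 1)
        for s, e in self.segments:
            lo = np.searchsorted(xs, s)
            hi = np.searchsorted(xs, e)
            vals[lo:hi] += 1
        return xs, vals


def make_windows(
    n_windows: int = 12_397, n_chroms: int = 22, window_bp: int = 250_000
) -> GenomicWindows:
    """A synthetic grid of equal windows split into chromosome blocks."""
    base, extra = divmod(n_windows, n_chroms)
    chroms, starts, ends = [], [], []
    for c in range(n_chroms):
        n = base + (1 if c < extra else 0)
        name = f"chr{c + 1}"
        for j in range(n):
            chroms.append(name)
            starts.append(j * window_bp)
            ends.append((j + 1) * window_bp)
    return GenomicWindows(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


def _pectinate(taxa: list[str], internal: float, terminals: list[float]) -> dendropy.Tree:
    """Caterpillar tree: leaf j diverges after j internal branches."""
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    node = tree.seed_node
    n = len(taxa)
    for j in range(n - 1):
        leaf = dendropy.Node(taxon=tns.get_taxon(taxa[j]))
        leaf.edge.length = terminals[j]
        node.add_child(leaf)
        if j < n - 2:
            nxt = dendropy.Node()
            nxt.edge.length = internal
            node.add_child(nxt)
            node = nxt
        else:
            last = dendropy.Node(taxon=tns.get_taxon(taxa[n - 1]))
            last.edge.length = terminals[n - 1]
            node.add_child(last)
    return tree


def _balanced(taxa: list[str], branch: float) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)

    def grow(node, labels):
        if len(labels) == 1:
            node.taxon = tns.get_taxon(labels[0])
            return
        mid = len(labels) // 2
        for part in (labels[:mid], labels[mid:]):
            child = dendropy.Node()
            child.edge.length = branch
            node.add_child(child)
            grow(child, part)

    grow(tree.seed_node, taxa)
    return tree


def build_sim_tree(spec: SimTreeSpec) -> dendropy.Tree:
    """Build tree A/B/C/D, rescale its height, and prepend the root branch.

    The root-branch length is stored on the seed node's edge, so shared
    ancestral events on it are inherited by every cell.
    """
    n = spec.n_leaves
    taxa = [f"cell{j}" for j in range(n)]
    u = 1.0 / n
    if spec.structure == "A":
        # pectinate, internal branches u, terminals stretched to equal depth
        terminals = [1.0 - (j + 1) * u for j in range(n - 1)] + [1.0 - (n - 1) * u]
        tree = _pectinate(taxa, u, terminals)
    elif spec.structure == "B":
        tree = _balanced(taxa, u)
    elif spec.structure == "C":
        tree = _pectinate(taxa, u, [u] * n)
    else:  # D: terminals decay as 1/ln(j+1), ladder order
        terminals = [1.0 / np.log(j + 2) for j in range(n)]
        tree = _pectinate(taxa, u, terminals)
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    scale = spec.height_scale / max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tree.seed_node.edge.length = spec.root_branch
    return tree


def simulate_cnas(
    tree: dendropy.Tree, params: SimParams, rng: np.random.Generator
) -> dict[str, SegmentGenome]:
    """Propagate CNA events down the tree; returns genomes keyed by node.

    Leaf keys are taxon labels; internal nodes get synthetic ``node<i>`` keys.
    The root branch (seed-node edge) mutates the shared ancestral genome.
    """
    G = params.genome_length
    genomes: dict[str, SegmentGenome] = {}
    node_genome: dict[int, SegmentGenome] = {}
    counter = [0]

    def branch_events(genome: SegmentGenome, t: float) -> None:
        if t is None or t <= 0:
            return
        n_amp = rng.poisson(params.amp_rate * t * G)
        n_del = rng.poisson(params.del_rate * t * G)
        kinds = ["amp"] * n_amp + ["del"] * n_del
        rng.shuffle(kinds)
        for kind in kinds:
            mean_len = (params.amp_mean_len if kind == "amp" else params.del_mean_len) * G
            start = rng.uniform(0.0, G)
            length = min(rng.exponential(mean_len), G - start)  # truncated
            genome.apply_event(kind, start, start + length, rng)

    def key_of(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        counter[0] += 1
        return f"node{counter[0]}"

    for node in tree.preorder_node_iter():
        parent = node.parent_node
        g = (
            SegmentGenome.diploid(G)
            if parent is None
            else node_genome[id(parent)].copy()
        )
        branch_events(g, node.edge.length)
        node_genome[id(node)] = g
        genomes[key_of(node)] = g
    return genomes


def true_window_cnp(
    genome: SegmentGenome, windows: GenomicWindows, genome_length: float | None = None
) -> CopyNumberProfile:
    """Average ploidy per window; windows tile the reference proportionally."""
    G = genome.genome_length if genome_length is None else genome_length
    n = len(windows)
    edges = np.linspace(0.0, G, n + 1)
    xs, vals = genome.ploidy_breaks()
    # cumulative integral of the ploidy step function at each boundary
    cum = np.concatenate([[0.0], np.cumsum(vals * np.diff(xs))])

    def integral(x):
        i = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, len(vals) - 1)
        return cum[i] + vals[i] * (x - xs[i])

    cn = (integral(edges[1:]) - integral(edges[:-1])) / np.diff(edges)
    cn = np.clip(cn, 0.0, None)
    return CopyNumberProfile(windows, cn, integer_valued=False)


def simulate_reads(
    true_cnp: CopyNumberProfile,
    params: SimParams,
    rng: np.random.Generator,
    cell_id: str = "",
) -> BinnedDepth:
    """NB read counts with per-window means proportional to average ploidy."""
    widths = (true_cnp.windows.ends - true_cnp.windows.starts).astype(float)
    mass = true_cnp.cn * widths
    total = mass.sum()
    if total <= 0:
        raise ValueError("all-zero genome: no reads to distribute")
    lam = params.total_reads * mass / total
    r = params.nb_size
    p = r / (r + lam)
    counts = rng.negative_binomial(r, p)
    return BinnedDepth(true_cnp.windows, counts, cell_id=cell_id)


def simulate_diploid(
    windows: GenomicWindows, params: SimParams, rng: np.random.Generator, cell_id: str = ""
) -> BinnedDepth:
    """A matched normal: true copy number exactly 2 everywhere."""
    cnp = CopyNumberProfile(windows, np.full(len(windows), 2.0))
    return simulate_reads(cnp, params, rng, cell_id=cell_id)


# ---------------------------------------------------------------------------
# accuracy metrics


def sse(inferred: CopyNumberProfile, truth: CopyNumberProfile) -> float:
    """Sum of squared per-window copy-number errors."""
    if not inferred.windows.same_grid(truth.windows):
        raise ValueError("profiles are on different window grids")
    return float(np.sum((inferred.cn - truth.cn) ** 2))


def breakpoints(profile: CopyNumberProfile, atol: float = 1e-9) -> list[tuple[str, int]]:
    """Boundaries (chrom, local index) where CN changes between neighbors."""
    out = []
    for lo, hi in profile.windows.chrom_slices():
        cn = profile.cn[lo:hi]
        for j in np.nonzero(np.abs(np.diff(cn)) > atol)[0]:
            out.append((str(profile.windows.chroms[lo]), int(j + 1)))
    return out


def breakpoint_stats(
    inferred: CopyNumberProfile, truth: CopyNumberProfile
) -> tuple[float, float | None]:
    """(total distance to nearest inferred breakpoint, omega).

    For each true breakpoint, the distance in window units to the nearest
    inferred breakpoint on the same chromosome; a chromosome with true
    breakpoints but no inferred ones contributes its length in windows per
    true breakpoint.  omega = #inferred / #true; None when no true
    breakpoints exist.
    """
    if not inferred.windows.same_grid(truth.windows):
        raise ValueError("profiles are on different window grids")
    bp_inf = breakpoints(inferred)
    bp_true = breakpoints(truth)
    chrom_len = {
        str(inferred.windows.chroms[lo]): hi - lo
        for lo, hi in inferred.windows.chrom_slices()
    }
    by_chrom: dict[str, list[int]] = {}
    for c, j in bp_inf:
        by_chrom.setdefault(c, []).append(j)
    total = 0.0
    for c, j in bp_true:
        cand = by_chrom.get(c)
        if not cand:
            total += chrom_len[c]
        else:
            total += min(abs(j - i) for i in cand)
    omega = len(bp_inf) / len(bp_true) if bp_true else None
    return total, omega
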