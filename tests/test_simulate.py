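import numpy as np
import pytest

from paircna.io import CopyNumberProfile
from paircna.simulate import (
    SegmentGenome,
    SimParams,
    SimTreeSpec,
    breakpoint_stats,
    breakpoints,
    build_sim_tree,
    make_windows,
    simulate_cnas,
    simulate_diploid,
    simulate_reads,
    sse,
    true_window_cnp,
)

from conftest import make_grid


def leaf_depths(tree):
    return tree.calc_node_root_distances(return_leaf_distances_only=True)


class TestSimTrees:
    def test_balanced_tree_is_ultrametric(self):
        tree = build_sim_tree(SimTreeSpec("B", n_leaves=8, root_branch=1.0))
        depths = leaf_depths(tree)
        assert len(depths) == 8
        assert np.ptp(depths) < 1e-12
        assert max(depths) == pytest.approx(1.0)  # height scaled to 1

    def test_pectinate_ultrametric_has_one_cherry(self):
        tree = build_sim_tree(SimTreeSpec("A", n_leaves=8))
        assert np.ptp(leaf_depths(tree)) < 1e-12
        cherries = sum(
            1
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and all(c.is_leaf() for c in nd.child_nodes())
        )
        assert cherries == 1

    def test_uniform_branch_ladder_not_ultrametric(self):
        tree = build_sim_tree(SimTreeSpec("C", n_leaves=8))
        assert np.ptp(leaf_depths(tree)) > 0.1

    def test_log_decay_terminals_strictly_decreasing(self):
        tree = build_sim_tree(SimTreeSpec("D", n_leaves=8))
        terms = [
            l.edge.length
            for l in sorted(
                tree.leaf_node_iter(), key=lambda l: int(l.taxon.label[4:])
            )
        ]
        assert all(a > b for a, b in zip(terms, terms[1:]))

    def test_balanced_requires_power_of_two(self):
        with pytest.raises(ValueError):
            SimTreeSpec("B", n_leaves=6)


class TestSegmentEvents:
    def test_zero_rates_leave_everyone_diploid(self):
        params = SimParams(amp_rate=0.0, del_rate=0.0, n_windows=50, n_chroms=2)
        tree = build_sim_tree(SimTreeSpec("A", n_leaves=4))
        genomes = simulate_cnas(tree, params, np.random.default_rng(0))
        windows = make_windows(50, 2)
        for g in genomes.values():
            assert np.all(true_window_cnp(g, windows).cn == 2.0)

    def test_single_deletion_halves_ploidy_in_region(self, rng):
        g = SegmentGenome.diploid(100.0)
        g.apply_event("del", 20.0, 40.0, rng)
        xs, vals = g.ploidy_breaks()
        assert vals[np.searchsorted(xs, 30.0) - 1] == 1
        assert vals[np.searchsorted(xs, 10.0) - 1] == 2
        assert vals[np.searchsorted(xs, 50.0) - 1] == 2

    def test_amplification_adds_one_copy(self, rng):
        g = SegmentGenome.diploid(100.0)
        g.apply_event("amp", 20.0, 40.0, rng)
        xs, vals = g.ploidy_breaks()
        assert vals[np.searchsorted(xs, 30.0) - 1] == 3

    def test_events_are_heritable(self):
        params = SimParams(amp_rate=0.1, del_rate=0.1, n_windows=50)
        tree = build_sim_tree(SimTreeSpec("A", n_leaves=4))
        genomes = simulate_cnas(tree, params, np.random.default_rng(7))
        # the two cells of the single cherry share their ancestral event prefix
        cherry = [
            nd
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and all(c.is_leaf() for c in nd.child_nodes())
        ][0]
        kids = [c.taxon.label for c in cherry.child_nodes()]
        shared = 0
        for e1, e2 in zip(genomes[kids[0]].events, genomes[kids[1]].events):
            if e1 != e2:
                break
            shared += 1
        private = [len(genomes[c].events) - shared for c in kids]
        assert all(p >= 0 for p in private)
        # parent genome's events are exactly the shared prefix
        for kid in kids:
            assert genomes[kid].events[:shared] == genomes[kid].events[:shared]


class TestTrueWindowCnp:
    def test_diploid_everywhere(self):
        g = SegmentGenome.diploid(100.0)
        cnp = true_window_cnp(g, make_windows(40, 2))
        assert np.all(cnp.cn == 2.0)

    def test_half_window_deletion_gives_fractional_cn(self, rng):
        g = SegmentGenome.diploid(100.0)
        windows = make_windows(10, 1)  # each window covers 10 units
        g.apply_event("del", 10.0, 15.0, rng)  # half of window 1, one copy
        cnp = true_window_cnp(g, windows)
        assert cnp.cn[1] == pytest.approx(1.5)
        assert cnp.cn[0] == 2.0

    def test_mass_conservation(self, rng):
        g = SegmentGenome.diploid(100.0)
        for _ in range(30):
            kind = "amp" if rng.random() < 0.5 else "del"
            start = rng.uniform(0, 100)
            g.apply_event(kind, start, start + rng.exponential(3.0), rng)
        windows = make_windows(200, 4)
        cnp = true_window_cnp(g, windows)
        total_mass = np.sum(cnp.cn * (100.0 / 200))
        seg_mass = sum(e - s for s, e in g.segments)
        assert total_mass == pytest.approx(seg_mass, rel=1e-9)


class TestReads:
    def test_diploid_expected_reads_per_window(self):
        params = SimParams()
        windows = make_windows(params.n_windows, params.n_chroms)
        depth = simulate_diploid(windows, params, np.random.default_rng(0))
        assert len(depth.counts) == 12_397
        lam = params.total_reads / params.n_windows
        assert lam == pytest.approx(322.7, abs=0.05)
        # total reads within 4 SD of 4,000,000 (NB variance sum)
        var = params.n_windows * (lam + lam**2 / params.nb_size)
        assert abs(depth.counts.sum() - params.total_reads) < 4 * np.sqrt(var)

    def test_cn4_window_doubles_expected_count(self, rng):
        params = SimParams(n_windows=40, n_chroms=1, total_reads=40 * 322.7)
        windows = make_windows(40, 1)
        cn = np.full(40, 2.0)
        cn[7] = 4.0
        cnp = CopyNumberProfile(windows, cn)
        sums = np.zeros(40)
        for _ in range(300):
            sums += simulate_reads(cnp, params, rng).counts
        other = np.delete(sums, 7).mean()
        assert sums[7] / other == pytest.approx(2.0, rel=0.1)

    def test_all_zero_genome_rejected(self):
        params = SimParams(n_windows=10)
        cnp = CopyNumberProfile(make_windows(10, 1), np.zeros(10))
        with pytest.raises(ValueError, match="zero"):
            simulate_reads(cnp, params, np.random.default_rng(0))


class TestMetrics:
    def test_sse_examples(self):
        grid = make_grid(6)
        a = CopyNumberProfile(grid, [2, 2, 2, 2, 2, 2])
        b = CopyNumberProfile(grid, [2, 3, 1, 2, 3, 2])
        assert sse(a, a) == 0.0
        assert sse(b, a) == 3.0
        c = CopyNumberProfile(grid, [2.5, 2.5, 1.5, 1.5, 2, 2])
        assert sse(c, a) == pytest.approx(1.0)

    def test_breakpoint_worked_example(self):
        n = 60
        grid = make_grid(n)
        truth = np.full(n, 2.0)
        truth[10:50] = 3.0  # true breakpoints at boundaries 10 and 50
        inferred = np.full(n, 2.0)
        inferred[12:] = 3.0  # single inferred breakpoint at 12
        dist, omega = breakpoint_stats(
            CopyNumberProfile(grid, inferred), CopyNumberProfile(grid, truth)
        )
        assert dist == (12 - 10) + (50 - 12)
        assert omega == pytest.approx(0.5)

    def test_perfect_inference(self):
        grid = make_grid(20)
        cn = np.r_[np.full(10, 2.0), np.full(10, 4.0)]
        p = CopyNumberProfile(grid, cn)
        dist, omega = breakpoint_stats(p, p)
        assert dist == 0.0 and omega == 1.0

    def test_no_inferred_breakpoints_capped(self):
        grid = make_grid(30)
        truth = np.full(30, 2.0)
        truth[5:] = 3.0
        dist, omega = breakpoint_stats(
            CopyNumberProfile(grid, np.full(30, 2.0)), CopyNumberProfile(grid, truth)
        )
        assert omega == 0.0
        assert dist == 30.0  # one true breakpoint, capped at chromosome length

    def test_no_true_breakpoints_omega_undefined(self):
        grid = make_grid(10)
        flat = CopyNumberProfile(grid, np.full(10, 2.0))
        wiggly = CopyNumberProfile(grid, np.r_[np.full(5, 2.0), np.full(5, 3.0)])
        dist, omega = breakpoint_stats(wiggly, flat)
        assert omega is None
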