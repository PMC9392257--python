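"""Self-contained validation experiments for the two-cell model.

These functions regenerate the study conditions end to end — self-simulation
from the two-cell HMM, line-segments simulation of tumor/diploid cohorts,
the four-stage inference pipeline, and phylogeny reconstruction — and return
the summary quantities used to judge the method: branch-length recovery,
copy-number SSE, breakpoint statistics, and Robinson-Foulds distances.

Problem sizes are parameters; the defaults here are reduced-scale versions
of the full study conditions (which use 12,397 windows and 128-cell trees)
chosen so each experiment completes in minutes on one core.  Per-window
coverage is always held at the study value of ~322.7 expected reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from . import hmm as hmm_mod
from .consensus import ConsensusConfig, consensus_profile
from .emissions import CellEmissionContext, DispersionModel, sample_counts
from .io import BinnedDepth, CopyNumberProfile
from .markov import PairTree, build_rate_matrix, genome_transition, pair_joint_adjacent, steady_state, transition_matrix
from .pairwise import SharedRates, combine_rates, fit_pair_tree, run_all_pairs
from .phylo import euclidean_matrix, neighbor_joining, robinson_foulds, t2t3_matrix
from .simulate import (
    SimParams,
    SimTreeSpec,
    breakpoint_stats,
    build_sim_tree,
    make_windows,
    simulate_cnas,
    simulate_diploid,
    simulate_reads,
    sse,
    true_window_cnp,
)
from .single_cell import average_diploid, fit_cell, fit_dispersion

__all__ = [
    "READS_PER_WINDOW",
    "sample_pair_dataset",
    "pair_recovery",
    "divergence_ladder",
    "pipeline_experiment",
    "phylo_experiment",
]

# study-condition coverage: 4,000,000 expected reads over 12,397 windows
READS_PER_WINDOW = 4_000_000.0 / 12_397

# rates used when self-simulating from the inference model itself: chosen so
# copy-number segments span tens of windows and cells stay mostly diploid,
# the regime of the line-segments simulations (gamma >> 1 because real CNAs
# usually cover both of two adjacent bins)
_SELF_SIM_RATES = SharedRates(alpha=0.005, beta=0.0005, gamma=10.0)

# dispersion matching NB size 50: var = lam + lam^2/50
_SELF_SIM_DISP = DispersionModel(a=0.02, b=1.0, c=0.0)


def _scaled_params(n_windows: int, n_chroms: int, **overrides) -> SimParams:
    """Reduced-scale simulation constants at study per-window coverage."""
    return SimParams(
        n_windows=n_windows,
        n_chroms=n_chroms,
        total_reads=READS_PER_WINDOW * n_windows,
        **overrides,
    )


def sample_pair_dataset(
    tree: PairTree,
    k: int,
    n_windows: int,
    rng: np.random.Generator,
    n_chroms: int = 10,
    shared: SharedRates = _SELF_SIM_RATES,
    disp: DispersionModel = _SELF_SIM_DISP,
):
    """Draw a two-cell dataset exactly from the pair HMM.

    Returns (depthA, depthB, ctxA, ctxB, true_cnA, true_cnB).
    """
    windows = make_windows(n_windows, n_chroms)
    chrom_slices = windows.chrom_slices()
    Q = build_rate_matrix(shared.as_rate_params(), k)
    F = pair_joint_adjacent(
        transition_matrix(Q, tree.t1),
        transition_matrix(Q, tree.t2),
        transition_matrix(Q, tree.t3),
        k,
    )
    M = genome_transition(F)
    pi = steady_state(M)
    states = hmm_mod.sample_states(M, pi, chrom_slices, rng)
    k1 = k + 1
    cn_a, cn_b = states // k1, states % k1
    mu = np.full(n_windows, READS_PER_WINDOW)
    ctx_a = CellEmissionContext(1.0, mu, disp)
    ctx_b = CellEmissionContext(1.0, mu, disp)
    depth_a = BinnedDepth(windows, sample_counts(cn_a, ctx_a, rng), "A")
    depth_b = BinnedDepth(windows, sample_counts(cn_b, ctx_b, rng), "B")
    return depth_a, depth_b, ctx_a, ctx_b, cn_a, cn_b


def pair_recovery(
    seed: int,
    tree: PairTree = PairTree(1.0, 0.5, 0.5),
    k: int = 4,
    n_windows: int = 12_000,
) -> dict:
    """Fit the pair tree on data self-simulated at known branch lengths."""
    rng = np.random.default_rng(seed)
    depth_a, depth_b, ctx_a, ctx_b, _, _ = sample_pair_dataset(tree, k, n_windows, rng)
    fit = fit_pair_tree(
        depth_a,
        depth_b,
        ctx_a,
        ctx_b,
        _SELF_SIM_RATES,
        t_a=tree.t1 + tree.t2,
        t_b=tree.t1 + tree.t3,
        k=k,
        seed=seed,
    )
    return {
        "true_t2t3": tree.t2 + tree.t3,
        "est_t2t3": fit.tree.t2 + fit.tree.t3,
        "est_tree": fit.tree,
        "loglik": fit.loglik,
    }


def divergence_ladder(
    seed: int,
    levels=(0.1, 0.3, 0.5, 0.7, 0.9),
    reps: int = 5,
    k: int = 4,
    n_windows: int = 2_000,
) -> dict:
    """Recovery of t2+t3 across a ladder of true divergence levels."""
    rng = np.random.default_rng(seed)
    true_vals, est_vals = [], []
    for lvl in levels:
        for _ in range(reps):
            tree = PairTree(1.0, lvl, lvl)
            depth_a, depth_b, ctx_a, ctx_b, _, _ = sample_pair_dataset(
                tree, k, n_windows, rng
            )
            fit = fit_pair_tree(
                depth_a,
                depth_b,
                ctx_a,
                ctx_b,
                _SELF_SIM_RATES,
                t_a=tree.t1 + tree.t2,
                t_b=tree.t1 + tree.t3,
                k=k,
                seed=seed,
            )
            true_vals.append(tree.t2 + tree.t3)
            est_vals.append(fit.tree.t2 + fit.tree.t3)
    rho = float(spearmanr(true_vals, est_vals).statistic)
    return {"true": true_vals, "est": est_vals, "spearman_rho": rho}


@dataclass
class PipelineResult:
    cells: list[str]
    sse_independent: dict[str, float]
    sse_pair_median: dict[str, float]
    sse_mean_consensus: dict[str, float]
    omega_independent: dict[str, float | None]
    omega_mean: dict[str, float | None]
    bpdist_independent: dict[str, float]
    bpdist_mean: dict[str, float]
    pair_fits: dict
    cnps: dict[str, CopyNumberProfile]
    consensus_cnps: dict[str, CopyNumberProfile]
    true_cnps: dict[str, CopyNumberProfile]
    true_tree: object


def pipeline_experiment(
    seed: int,
    n_tumor: int = 8,
    n_diploid: int = 20,
    n_windows: int = 1_200,
    n_chroms: int = 10,
    k: int = 10,
    structure: str = "A",
    consensus_summary: str = "mean",
) -> PipelineResult:
    """Full four-stage pipeline on a line-segments simulation.

    Simulates tumor cells down a scaled tree plus matched diploids, runs
    diploid averaging, dispersion fitting, independent per-cell fits, shared
    rate combination, all-pairs branch-length fits, and consensus calling,
    then scores every stage against the simulated truth.
    """
    rng = np.random.default_rng(seed)
    params = _scaled_params(n_windows, n_chroms)
    windows = make_windows(n_windows, n_chroms)
    tree = build_sim_tree(SimTreeSpec(structure, n_leaves=n_tumor))
    genomes = simulate_cnas(tree, params, rng)
    labels = [f"cell{j}" for j in range(n_tumor)]

    true_cnps, depths = {}, {}
    for c in labels:
        true_cnps[c] = true_window_cnp(genomes[c], windows)
        true_cnps[c].cell_id = c
        depths[c] = simulate_reads(true_cnps[c], params, rng, cell_id=c)
    diploids = [
        simulate_diploid(windows, params, rng, cell_id=f"diploid{j}")
        for j in range(n_diploid)
    ]

    diploid_profile = average_diploid(diploids)
    disp = fit_dispersion(diploid_profile)
    fits = {
        c: fit_cell(depths[c], diploid_profile, disp, k=k, seed=seed) for c in labels
    }
    shared = combine_rates(list(fits.values()))
    contexts = {
        c: CellEmissionContext(fits[c].s, diploid_profile.mean, disp) for c in labels
    }
    pair_fits = run_all_pairs(depths, fits, contexts, shared, k=k, seed=seed)

    paired_per_cell: dict[str, list[CopyNumberProfile]] = {c: [] for c in labels}
    for (a, b), pf in pair_fits.items():
        paired_per_cell[a].append(pf.cnp_a)
        paired_per_cell[b].append(pf.cnp_b)
    cfg = ConsensusConfig(summary=consensus_summary, kappa="all")
    consensus_cnps = {c: consensus_profile(paired_per_cell[c], cfg) for c in labels}

    res = PipelineResult(
        cells=labels,
        sse_independent={},
        sse_pair_median={},
        sse_mean_consensus={},
        omega_independent={},
        omega_mean={},
        bpdist_independent={},
        bpdist_mean={},
        pair_fits=pair_fits,
        cnps={c: fits[c].cnp for c in labels},
        consensus_cnps=consensus_cnps,
        true_cnps=true_cnps,
        true_tree=tree,
    )
    for c in labels:
        res.sse_independent[c] = sse(fits[c].cnp, true_cnps[c])
        res.sse_pair_median[c] = float(
            np.median([sse(p, true_cnps[c]) for p in paired_per_cell[c]])
        )
        res.sse_mean_consensus[c] = sse(consensus_cnps[c], true_cnps[c])
        d_s, om_s = breakpoint_stats(fits[c].cnp, true_cnps[c])
        d_m, om_m = breakpoint_stats(consensus_cnps[c], true_cnps[c])
        res.bpdist_independent[c], res.omega_independent[c] = d_s, om_s
        res.bpdist_mean[c], res.omega_mean[c] = d_m, om_m
    return res


def phylo_experiment(
    seed: int,
    reps: int = 10,
    n_cells: int = 8,
    n_diploid: int = 10,
    n_windows: int = 600,
    n_chroms: int = 5,
    k: int = 6,
    structure: str = "A",
) -> dict:
    """NJ tree accuracy of the t2+t3 metric vs Euclidean-over-single-cell.

    Each replicate simulates a small cohort, runs the pipeline through the
    all-pairs stage, reconstructs NJ trees from both distance matrices, and
    records Robinson-Foulds distances to the true simulated tree.
    """
    rf_t2t3, rf_euclid = [], []
    for rep in range(reps):
        rep_seed = seed + 1000 * rep
        rng = np.random.default_rng(rep_seed)
        params = _scaled_params(n_windows, n_chroms)
        windows = make_windows(n_windows, n_chroms)
        tree = build_sim_tree(SimTreeSpec(structure, n_leaves=n_cells))
        genomes = simulate_cnas(tree, params, rng)
        labels = [f"cell{j}" for j in range(n_cells)]
        depths = {}
        for c in labels:
            cnp = true_window_cnp(genomes[c], windows)
            depths[c] = simulate_reads(cnp, params, rng, cell_id=c)
        diploids = [
            simulate_diploid(windows, params, rng, cell_id=f"d{j}")
            for j in range(n_diploid)
        ]
        diploid_profile = average_diploid(diploids)
        disp = fit_dispersion(diploid_profile)
        fits = {
            c: fit_cell(depths[c], diploid_profile, disp, k=k, seed=rep_seed)
            for c in labels
        }
        shared = combine_rates(list(fits.values()))
        contexts = {
            c: CellEmissionContext(fits[c].s, diploid_profile.mean, disp)
            for c in labels
        }
        pair_fits = run_all_pairs(depths, fits, contexts, shared, k=k, seed=rep_seed)
        nj_t = neighbor_joining(t2t3_matrix(pair_fits, labels))
        nj_e = neighbor_joining(euclidean_matrix({c: fits[c].cnp for c in labels}))
        rf_t2t3.append(robinson_foulds(nj_t, tree))
        rf_euclid.append(robinson_foulds(nj_e, tree))
    return {
        "rf_t2t3": rf_t2t3,
        "rf_euclidean": rf_euclid,
        "median_rf_t2t3": float(np.median(rf_t2t3)),
        "median_rf_euclidean": float(np.median(rf_euclid)),
    }
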