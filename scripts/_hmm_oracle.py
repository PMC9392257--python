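"""Brute-force HMM oracle used by the acceptance script: exhaustive
enumeration over all state paths of a small random model."""

import itertools

import numpy as np

from paircna.hmm import HmmModel


def random_model(n_windows, n_states, seed, chrom_slices=None):
    rng = np.random.default_rng(seed)
    M = rng.random((n_states, n_states)) + 0.05
    M /= M.sum(axis=1, keepdims=True)
    pi = rng.random(n_states) + 0.05
    pi /= pi.sum()
    logE = np.log(rng.random((n_windows, n_states)) + 1e-3)
    return HmmModel(M, pi, logE, chrom_slices or [(0, n_windows)])


def enumerate_paths(model, lo, hi):
    n = hi - lo
    S = model.transition.shape[0]
    logM = np.log(model.transition)
    logpi = np.log(model.initial)
    logE = model.log_emissions[lo:hi]
    best_lp, best_path, total = -np.inf, None, -np.inf
    for path in itertools.product(range(S), repeat=n):
        lp = logpi[path[0]] + logE[0, path[0]]
        for t in range(1, n):
            lp += logM[path[t - 1], path[t]] + logE[t, path[t]]
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return total, best_lp, np.array(best_path)
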