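import numpy as np
import pytest

from paircna.io import BinnedDepth, GenomicWindows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid2():
    """Two windows on one chromosome."""
    return GenomicWindows(
        np.array(["chr1", "chr1"], dtype=object),
        np.array([0, 250_000]),
        np.array([250_000, 500_000]),
    )


@pytest.fixture
def grid_two_chroms():
    """Six windows over two chromosomes."""
    return GenomicWindows(
        np.array(["chr1"] * 3 + ["chr2"] * 3, dtype=object),
        np.array([0, 10, 20, 0, 10, 20]),
        np.array([10, 20, 30, 10, 20, 30]),
    )


def make_grid(n, n_chroms=1, width=10):
    base, extra = divmod(n, n_chroms)
    chroms, starts, ends = [], [], []
    for c in range(n_chroms):
        m = base + (1 if c < extra else 0)
        for j in range(m):
            chroms.append(f"chr{c + 1}")
            starts.append(j * width)
            ends.append((j + 1) * width)
    return GenomicWindows(
        np.array(chroms, dtype=object), np.array(starts), np.array(ends)
    )


@pytest.fixture
def depth_factory():
    def make(counts, n_chroms=1, cell_id="cell"):
        counts = np.asarray(counts)
        return BinnedDepth(make_grid(len(counts), n_chroms), counts, cell_id)

    return make
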