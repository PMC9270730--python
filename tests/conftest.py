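"""Shared fixtures: tiny hand-built matrices and the seeded planted-loop chromosome."""

import numpy as np
import pytest

from nbloop import LoopCallingConfig, SyntheticSpec, generate_dataset
from nbloop.matrix_io import BandedContactMatrix
from nbloop.peak_calling import call_loops


def make_banded(dense, bin_size=10_000, chrom="chrT", min_d=0, band_width=None,
                balanced=False, raw=None):
    """Build a BandedContactMatrix from a dense symmetric array (upper triangle)."""
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    band_width = band_width if band_width is not None else n - 1
    ii, jj = np.triu_indices(n)
    keep = (dense[ii, jj] != 0) & (jj - ii >= min_d) & (jj - ii <= band_width)
    ii, jj = ii[keep], jj[keep]
    vals = dense[ii, jj]
    raw_vals = np.asarray(raw, dtype=float)[ii, jj] if raw is not None else vals.copy()
    return BandedContactMatrix(
        chrom=chrom, bin_size=bin_size, n_bins=n,
        bin1=ii, bin2=jj, values=vals, raw=raw_vals,
        band_width=band_width, min_d=min_d, balanced=balanced,
    )


def planted_loop_positions(n_bins=2000, n_loops=20, seed=42, d_min=30, d_max=190):
    """Deterministic well-separated loop centers inside the 2 Mb search band."""
    rng = np.random.default_rng(seed)
    placed = []
    while len(placed) < n_loops:
        i = int(rng.integers(20, n_bins - 40))
        j = i + int(rng.integers(d_min, d_max))
        if j >= n_bins:
            continue
        if any(max(abs(i - a), abs(j - b)) < 15 for a, b in placed):
            continue
        placed.append((i, j))
    return placed


@pytest.fixture(scope="session")
def planted_dataset():
    """2,000-bin chromosome, NB dispersion 3, 20 loops at 8x enrichment."""
    loops = [(i, j, 8.0, 2) for (i, j) in planted_loop_positions()]
    matrix, truth = generate_dataset(SyntheticSpec(n_bins=2000, loops=loops, seed=7))
    return matrix, truth


@pytest.fixture(scope="session")
def planted_calls(planted_dataset):
    """Default-configuration loop calls on the planted chromosome."""
    matrix, _ = planted_dataset
    counts: dict = {}
    calls = call_loops(matrix, LoopCallingConfig(), stage_counts=counts)
    return calls, counts


@pytest.fixture()
def default_config():
    return LoopCallingConfig()
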