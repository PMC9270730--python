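"""Assessment utilities: anchor-peak matching, loop-set intersection,
aggregate loop pileups, and the two-proportion z-test.

A loop is "CTCF-supported" (or supported by any protein peak set) only when
*both* anchor bins contain at least one peak; one covered anchor is not
enough.  Loop sets from different callers are intersected by greedy
one-to-one matching within a Chebyshev bin tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expected_model import compute_expected, transform_obs_exp
from .matrix_io import BandedContactMatrix, GenomicInterval, LoopCall

__all__ = [
    "MatchReport",
    "anchors_match_intervals",
    "intersect_loop_sets",
    "proportion_z_test",
    "aggregate_loop_submatrices",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchReport:
    n_loops: int
    n_matched: int

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_loops if self.n_loops else 0.0


def anchors_match_intervals(loops, peaks, bin_size: int) -> MatchReport:
    """Count loops whose anchors *both* overlap a binned peak interval.

    Peaks are binned to ``bin_size``: a peak covers every bin it intersects.
    Loops on chromosomes absent from the peak set score zero matches (with a
    warning).
    """
    covered: dict[str, set[int]] = {}
    for pk in peaks:
        bins = covered.setdefault(pk.chrom, set())
        bins.update(range(pk.start // bin_size, (pk.end - 1) // bin_size + 1))

    missing = set()
    n_matched = 0
    loops = list(loops)
    for lp in loops:
        if lp.chrom not in covered:
            missing.add(lp.chrom)
            continue
        bins = covered[lp.chrom]
        if lp.bin_i in bins and lp.bin_j in bins:
            n_matched += 1
    for chrom in sorted(missing):
        log.warning("no peaks on chromosome %s; its loops count as unmatched", chrom)
    return MatchReport(n_loops=len(loops), n_matched=n_matched)


def _loop_bins(loops):
    return [
        (lp.chrom, lp.bin_i, lp.bin_j) if isinstance(lp, LoopCall)
        else (lp[0], int(lp[1]), int(lp[2]))
        for lp in loops
    ]


def intersect_loop_sets(a, b, tol_bins: int = 0):
    """Greedy one-to-one intersection of two loop sets.

    Loops match when on the same chromosome and within Chebyshev distance
    ``tol_bins`` in (bin_i, bin_j).  Matching proceeds in genomic order of
    ``a``; the matched count is symmetric in the two sets.  Returns
    ``(n_a, n_b, n_intersect)``.
    """
    la, lb = sorted(_loop_bins(a)), sorted(_loop_bins(b))
    by_chrom: dict[str, list] = {}
    for k, (chrom, i, j) in enumerate(lb):
        by_chrom.setdefault(chrom, []).append((i, j, k))
    claimed = set()
    n_match = 0
    for (chrom, i, j) in la:
        best = None
        for (bi, bj, k) in by_chrom.get(chrom, ()):
            if k in claimed:
                continue
            dist = max(abs(bi - i), abs(bj - j))
            if dist <= tol_bins and (best is None or dist < best[0]):
                best = (dist, k)
        if best is not None:
            claimed.add(best[1])
            n_match += 1
    return len(la), len(lb), n_match


def proportion_z_test(x1: int, n1: int, x2: int, n2: int):
    """Pooled two-proportion z statistic with a two-sided normal p-value.

    z = (p1 - p2) / sqrt(p*(1-p)*(1/n1 + 1/n2)) with p the pooled proportion.
    A degenerate pooled proportion of 0 or 1 (no variance under the null)
    returns (0, 1) by convention.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def aggregate_loop_submatrices(
    matrix: BandedContactMatrix,
    loops,
    half_width_bins: int = 5,
    expected_mode: str = "nonzero",
) -> np.ndarray:
    """Mean obs/exp submatrix over loop calls (aggregate peak analysis).

    Each loop contributes its ``(2h+1) x (2h+1)`` obs/exp window; loops whose
    window leaves the matrix or the distance band are skipped (logged).
    """
    profile = compute_expected(matrix, expected_mode)
    obsexp = transform_obs_exp(matrix, profile)
    csr = obsexp.to_csr("values")
    h = half_width_bins
    total = np.zeros((2 * h + 1, 2 * h + 1))
    used = 0
    skipped = 0
    for (chrom, i, j) in _loop_bins(loops):
        if chrom != matrix.chrom:
            skipped += 1
            continue
        if (
            i - h < 0 or j + h >= matrix.n_bins
            or (j - h) - (i + h) < matrix.min_d
            or (j + h) - (i - h) > matrix.band_width
        ):
            skipped += 1
            continue
        total += csr[i - h : i + h + 1, j - h : j + h + 1].toarray()
        used += 1
    if used == 0:
        raise ValueError("no loop window fits inside the matrix band")
    if skipped:
        log.info("aggregate: skipped %d loops whose window exits the band", skipped)
    return total / used
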