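"""Neighborhood testing of loop candidates (donut-style peak detection).

Candidates from adjacent distances cluster; each neighborhood keeps only the
candidate with the highest obs/exp value as its representative.  Around each
representative a square window (inradius ``window_size``) is split into a
central peak square (inradius ``peak_width``) and background regions:

    offsets (di, dj) from the center, row index grows downward

    peak        max(|di|, |dj|) <= pw
    vertical    |di| <= pw  and  pw < |dj| <= w     (left / right stripes)
    horizontal  |dj| <= pw  and  pw < |di| <= w     (above / below stripes)
    corner      pw < di <= w  and  -w <= dj < -pw   (bottom-left block)

The three remaining window corners belong to no named test region but do
count toward ``all_background`` (= window minus peak) for the mean filter.
A candidate is rejected outright when mean(all_background) >= mean(peak);
otherwise the peak is tested one-sided (peak stochastically greater, Wilcoxon
rank-sum) against each of the vertical, horizontal, and corner regions, and
accepted only when all three p-values fall below the significance level.

Window cells that lie outside the matrix or outside the distance band are
truncated (absent); in-band cells with no stored entry contribute zeros.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .candidate_selection import Candidate, select_candidates
from .config import LoopCallingConfig
from .cont_negbinom import fit_all_distances
from .expected_model import compute_expected, transform_obs_exp
from .matrix_io import BandedContactMatrix, LoopCall

__all__ = [
    "Neighborhood",
    "pool_candidates",
    "extract_neighborhood",
    "evaluate_neighborhood",
    "rank_sum_greater",
    "call_loops",
]

log = logging.getLogger(__name__)


@dataclass
class Neighborhood:
    """Peak/background partition of the window around one candidate."""

    center: tuple[int, int]
    peak: np.ndarray
    horizontal: np.ndarray
    vertical: np.ndarray
    corner: np.ndarray
    all_background: np.ndarray
    testable: bool = True
    reason: str = ""


def pool_candidates(candidates: list[Candidate], window_size: int) -> list[Candidate]:
    """Keep one representative per neighborhood: the highest obs/exp wins.

    After pooling, no two survivors lie within Chebyshev distance
    ``window_size`` of each other.  Ties break toward smaller distance, then
    smaller i, making the result deterministic and the operation idempotent.
    """
    ranked = sorted(candidates, key=lambda c: (-c.obs_exp, c.d, c.i))
    cell = window_size + 1  # Chebyshev <= window_size implies grid offset <= 1
    grid: dict[tuple[int, int], list[Candidate]] = {}
    survivors: list[Candidate] = []
    for c in ranked:
        gi, gj = c.i // cell, c.j // cell
        clash = False
        for a in (gi - 1, gi, gi + 1):
            for b in (gj - 1, gj, gj + 1):
                for s in grid.get((a, b), ()):
                    if max(abs(s.i - c.i), abs(s.j - c.j)) <= window_size:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
        if not clash:
            survivors.append(c)
            grid.setdefault((gi, gj), []).append(c)
    survivors.sort(key=lambda c: (c.d, c.i))
    return survivors


class _ObsExpLookup:
    """Dense window extraction from the sparse upper-triangle obs/exp store."""

    def __init__(self, obsexp: BandedContactMatrix):
        self.n_bins = obsexp.n_bins
        self.min_d = obsexp.min_d
        self.max_d = obsexp.band_width
        self._csr = obsexp.to_csr("values")

    def window_values(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Values at (row, col) pairs plus a validity mask.

        Invalid (truncated) cells are off the matrix or outside the distance
        band; valid unstored cells are zero.  Cells below the diagonal read
        their symmetric mirror.
        """
        lo = np.minimum(rows, cols)
        hi = np.maximum(rows, cols)
        d = hi - lo
        valid = (lo >= 0) & (hi < self.n_bins) & (d >= self.min_d) & (d <= self.max_d)
        vals = np.zeros(len(rows))
        if valid.any():
            vals[valid] = np.asarray(
                self._csr[lo[valid], hi[valid]]
            ).ravel()
        return vals, valid


def _region_masks(peak_width: int, window_size: int):
    w, pw = window_size, peak_width
    di, dj = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
    di, dj = di.ravel(), dj.ravel()
    peak = (np.abs(di) <= pw) & (np.abs(dj) <= pw)
    vertical = (np.abs(di) <= pw) & (np.abs(dj) > pw)
    horizontal = (np.abs(dj) <= pw) & (np.abs(di) > pw)
    corner = (di > pw) & (dj < -pw)
    return di, dj, peak, horizontal, vertical, corner


def extract_neighborhood(
    obsexp: BandedContactMatrix | "_ObsExpLookup",
    center: tuple[int, int],
    peak_width: int,
    window_size: int,
    min_background_elements: int = 25,
) -> Neighborhood:
    """Extract the peak/background partition of the window around ``center``."""
    lookup = obsexp if isinstance(obsexp, _ObsExpLookup) else _ObsExpLookup(obsexp)
    ci, cj = center
    di, dj, m_peak, m_hor, m_ver, m_cor = _region_masks(peak_width, window_size)
    vals, valid = lookup.window_values(ci + di, cj + dj)

    def region(mask):
        return vals[mask & valid]

    peak = region(m_peak)
    horizontal = region(m_hor)
    vertical = region(m_ver)
    corner = region(m_cor)
    background = region(~m_peak)

    nb = Neighborhood(
        center=center, peak=peak, horizontal=horizontal,
        vertical=vertical, corner=corner, all_background=background,
    )
    if len(peak) == 0:
        nb.testable, nb.reason = False, "empty peak region"
    elif len(background) < min_background_elements:
        nb.testable, nb.reason = False, "background truncated below minimum size"
    elif min(len(horizontal), len(vertical), len(corner)) == 0:
        nb.testable, nb.reason = False, "empty test region after truncation"
    return nb


def rank_sum_greater(peak: np.ndarray, background: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p-value for peak stochastically greater.

    Exact null distribution when both groups have <= 25 values and no ties;
    normal approximation with tie and continuity correction otherwise.  A
    fully tied comparison (every value equal) has no rank separation and
    returns 1.
    """
    if len(peak) == 0 or len(background) == 0:
        return 1.0
    pooled = np.concatenate([peak, background])
    if np.all(pooled == pooled[0]):
        return 1.0
    exact = (
        len(peak) <= 25
        and len(background) <= 25
        and len(np.unique(pooled)) == len(pooled)
    )
    res = stats.mannwhitneyu(
        peak, background, alternative="greater",
        method="exact" if exact else "asymptotic",
    )
    return float(res.pvalue)


def evaluate_neighborhood(nb: Neighborhood, p_value: float):
    """Mean filter plus the three one-sided rank-sum tests.

    Returns ``(accepted, p_horizontal, p_vertical, p_corner)``.  Rejected
    immediately (p-values reported as 1) when the mean of the full background
    reaches the peak mean — a lone outlier cannot carry a loop.
    """
    if not nb.testable:
        return False, 1.0, 1.0, 1.0
    if nb.all_background.mean() >= nb.peak.mean():
        return False, 1.0, 1.0, 1.0
    p_hor = rank_sum_greater(nb.peak, nb.horizontal)
    p_ver = rank_sum_greater(nb.peak, nb.vertical)
    p_cor = rank_sum_greater(nb.peak, nb.corner)
    accepted = p_hor < p_value and p_ver < p_value and p_cor < p_value
    return accepted, p_hor, p_ver, p_cor


def call_loops(
    matrix: BandedContactMatrix,
    config: LoopCallingConfig | None = None,
    stage_counts: dict | None = None,
) -> list[LoopCall]:
    """Run the full pipeline on one chromosome's banded matrix.

    expected profile -> obs/exp -> per-distance NB fits -> candidate gates ->
    neighborhood pooling -> mean filter + rank-sum tests.  Output is sorted
    by (bin_i, bin_j) and independent of thread counts (the per-chromosome
    computation is sequential and deterministic).
    """
    config = config or LoopCallingConfig()
    if stage_counts is None:
        stage_counts = {}
    if (2 * config.window_size + 1) ** 2 < 250:
        warnings.warn(
            "neighborhood window holds fewer than ~250 elements; rank-sum "
            "tests lose power on sparse data",
            stacklevel=2,
        )
    if len(matrix) == 0:
        return []

    profile = compute_expected(matrix, config.expected_mode)
    obsexp = transform_obs_exp(matrix, profile)
    models = fit_all_distances(
        obsexp,
        prefit_threshold=config.obs_exp_threshold,
        min_obs=config.min_fit_observations,
    )
    stage_counts["fitted_distances"] = len(models)
    if not models:
        log.warning("%s: no genomic distance produced a usable fit", matrix.chrom)
        return []

    candidates = select_candidates(obsexp, models, config, stage_counts)
    pooled = pool_candidates(candidates, config.window_size)
    stage_counts["pooled"] = len(pooled)

    lookup = _ObsExpLookup(obsexp)
    loops: list[LoopCall] = []
    n_mean_pass = 0
    for c in pooled:
        nb = extract_neighborhood(
            lookup, (c.i, c.j), config.peak_width, config.window_size,
            config.min_background_elements,
        )
        accepted, p_hor, p_ver, p_cor = evaluate_neighborhood(nb, config.p_value)
        if nb.testable and nb.all_background.mean() < nb.peak.mean():
            n_mean_pass += 1
        if accepted:
            loops.append(
                LoopCall.from_bins(
                    matrix.chrom, c.i, c.j, matrix.bin_size,
                    obs_exp=c.obs_exp, p_preselect=c.p_preselect,
                    p_horizontal=p_hor, p_vertical=p_ver, p_corner=p_cor,
                    raw_count=c.raw_count,
                )
            )
    stage_counts["mean_filter"] = n_mean_pass
    stage_counts["accepted"] = len(loops)
    log.info("%s: stage counts %s", matrix.chrom, stage_counts)
    loops.sort(key=lambda lp: (lp.bin_i, lp.bin_j))
    return loops
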