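"""Observed/expected normalisation of banded contact matrices.

Contact frequency decays strongly with genomic distance, so enrichment must
be judged against the average contact at the same distance.  Three expected
values are supported, selected by ``mode``:

``nonzero``
    mean over the nonzero entries at distance d (default; sparse-robust),
``all``
    mean over all ``n_bins - d`` positions at distance d,
``ligation``
    the nonzero mean scaled per element by the coverage product
    ``rowsum_i * rowsum_j / total_sum`` (HOMER-style ligation correction).

Row sums are marginals of the full symmetric matrix implied by the band
(each off-diagonal entry contributes to both its rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import BandedContactMatrix

__all__ = ["ExpectedProfile", "compute_expected", "transform_obs_exp", "EXPECTED_MODES"]

EXPECTED_MODES = ("nonzero", "all", "ligation")


@dataclass
class ExpectedProfile:
    """Per-distance expected contact values and element counts.

    ``exp_d[d]`` is NaN for distances whose every entry is zero (downstream
    stages skip those distances rather than divide by zero).
    """

    mode: str
    distances: np.ndarray          # distances present in the band
    exp_d: np.ndarray              # expected value per distance (NaN = absent)
    n_nonzero_d: np.ndarray
    n_all_d: np.ndarray
    n_bins: int
    bin_size: int
    row_sums: np.ndarray | None = None   # ligation mode only
    total_sum: float | None = None

    _lookup: dict = field(default=None, repr=False)

    def expected_at(self, d: int) -> float:
        """Expected value at distance d (NaN if absent)."""
        if self._lookup is None:
            self._lookup = {int(dd): float(e) for dd, e in zip(self.distances, self.exp_d)}
        return self._lookup.get(int(d), float("nan"))


def compute_expected(matrix: BandedContactMatrix, mode: str = "nonzero") -> ExpectedProfile:
    """Compute the per-distance expected profile of a banded matrix."""
    if mode not in EXPECTED_MODES:
        raise ValueError(f"unknown expected mode {mode!r}; choose from {EXPECTED_MODES}")
    if len(matrix) == 0:
        raise ValueError("cannot compute an expected profile of an empty band")

    d = matrix.distances
    v = matrix.values
    dmax = matrix.band_width
    sums = np.bincount(d, weights=v, minlength=dmax + 1)
    n_nonzero = np.bincount(d[v > 0], minlength=dmax + 1)
    dist = np.arange(matrix.min_d, dmax + 1)
    sums = sums[dist]
    n_nonzero = n_nonzero[dist]
    n_all = matrix.n_bins - dist

    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "all":
            exp_d = np.where(n_nonzero > 0, sums / n_all, np.nan)
        else:  # nonzero and ligation share the nonzero mean
            exp_d = np.where(n_nonzero > 0, sums / np.maximum(n_nonzero, 1), np.nan)

    row_sums = None
    total = None
    if mode == "ligation":
        row_sums = np.zeros(matrix.n_bins)
        np.add.at(row_sums, matrix.bin1, v)
        off_diag = matrix.bin1 != matrix.bin2
        np.add.at(row_sums, matrix.bin2[off_diag], v[off_diag])
        # grand sum of the symmetric matrix: off-diagonal entries count twice
        total = float(v.sum() + v[off_diag].sum())
        if total == 0:
            raise ValueError("ligation mode undefined: matrix total sum is zero")

    return ExpectedProfile(
        mode=mode, distances=dist, exp_d=exp_d,
        n_nonzero_d=n_nonzero, n_all_d=n_all,
        n_bins=matrix.n_bins, bin_size=matrix.bin_size,
        row_sums=row_sums, total_sum=total,
    )


def transform_obs_exp(
    matrix: BandedContactMatrix, profile: ExpectedProfile
) -> BandedContactMatrix:
    """Divide each stored entry by its expected value.

    In ligation mode the expected value is per element,
    ``exp_nonzero_d * rowsum_i * rowsum_j / total_sum``.  Entries at distances
    with an absent expected value are dropped.  Returns a matrix with the same
    banded geometry whose ``values`` are the obs/exp ratios (``raw`` counts
    are carried through unchanged).
    """
    if profile.n_bins != matrix.n_bins or profile.bin_size != matrix.bin_size:
        raise ValueError("expected profile geometry does not match the matrix")

    d = matrix.distances
    exp_at_d = np.full(matrix.band_width + 1, np.nan)
    exp_at_d[profile.distances] = profile.exp_d
    denom = exp_at_d[d]
    if profile.mode == "ligation":
        rs = profile.row_sums
        denom = denom * rs[matrix.bin1] * rs[matrix.bin2] / profile.total_sum

    keep = np.isfinite(denom) & (denom > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(keep, matrix.values / np.where(keep, denom, 1.0), 0.0)

    out = BandedContactMatrix(
        matrix.chrom, matrix.bin_size, matrix.n_bins,
        matrix.bin1[keep], matrix.bin2[keep],
        ratio[keep], matrix.raw[keep],
        matrix.band_width, matrix.min_d, matrix.balanced,
    )
    return out
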