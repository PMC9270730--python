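"""Seeded synthetic Hi-C matrices with planted loops, plus truth-set scoring.

The generator emulates the statistical features loop calling relies on:
power-law distance decay of the mean contact count, per-distance negative
binomial dispersion (variance = dispersion x mean), point-like loop
enrichments that multiply the local mean over a small square patch, and
optional random sparsity / faulty (zeroed) bin ranges.  It does not attempt
TADs, compartments, or read-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import BandedContactMatrix, LoopCall

__all__ = ["SyntheticSpec", "TruthSet", "generate_dataset", "score_recovery", "decay_power_law"]


def decay_power_law(d, c: float = 80.0, alpha: float = 1.0, floor_frac: float = 0.1):
    """Expected count at distance d (bins): c * d^(-alpha) + floor_frac * c.

    A simple power law with a floor, qualitatively matching the contact decay
    of a 10 kb balanced Hi-C matrix; d = 0 is treated as d = 1.
    """
    d = np.maximum(np.asarray(d, dtype=np.float64), 1.0)
    return c * d ** (-alpha) + floor_frac * c


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic chromosome.

    ``loops`` holds ``(i, j, enrichment_factor, spread_bins)`` tuples; the NB
    mean is multiplied by ``enrichment_factor`` over the
    ``(2*spread+1) x (2*spread+1)`` patch centered at (i, j), so the
    enrichment is scale-free in obs/exp terms.  ``dispersion`` is the
    variance/mean ratio and must exceed 1 (negative binomial requires
    overdispersion).
    """

    n_bins: int = 2000
    bin_size: int = 10_000
    band_width: int = 200          # bins; 2 Mb at 10 kb
    decay_c: float = 80.0
    decay_alpha: float = 1.0
    decay_floor_frac: float = 0.1
    dispersion: float = 3.0
    loops: list = field(default_factory=list)
    sparsity: float = 0.0
    faulty_regions: list = field(default_factory=list)   # (start_bin, end_bin) half-open
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 1.0:
            raise ValueError(
                f"dispersion (variance/mean) must exceed 1, got {self.dispersion}"
            )
        if not (0.0 <= self.sparsity < 1.0):
            raise ValueError("sparsity must lie in [0, 1)")
        for (i, j, enr, spread) in self.loops:
            if enr <= 1.0:
                raise ValueError(f"loop enrichment_factor must exceed 1, got {enr}")
            if not (0 <= i < j < self.n_bins) or (j - i) > self.band_width:
                raise ValueError(f"loop center ({i}, {j}) outside the band")

    def decay(self, d):
        return decay_power_law(d, self.decay_c, self.decay_alpha, self.decay_floor_frac)


@dataclass
class TruthSet:
    """Planted loop centers, for precision/recall scoring."""

    centers: list  # [(i, j), ...]

    def __len__(self) -> int:
        return len(self.centers)


def generate_dataset(spec: SyntheticSpec):
    """Draw one synthetic banded matrix; returns (matrix, truth).

    Counts at distance d are NB with mean ``spec.decay(d)`` (times the local
    loop enrichment) and variance ``dispersion * mean``.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, bw = spec.n_bins, spec.band_width

    rows = []
    cols = []
    for d in range(0, bw + 1):
        i = np.arange(0, n - d)
        rows.append(i)
        cols.append(i + d)
    bin1 = np.concatenate(rows)
    bin2 = np.concatenate(cols)
    d = bin2 - bin1
    mu = spec.decay(d)

    # multiply means inside each planted-loop patch (both triangle mirrors of
    # the patch fold onto the stored upper triangle, so clip to i <= j)
    if spec.loops:
        from scipy.sparse import csr_matrix

        # direct patch walk is cheap: patches are tiny
        enrich = np.ones(len(bin1))
        index = csr_matrix(
            (np.arange(1, len(bin1) + 1), (bin1, bin2)), shape=(n, n)
        )
        for (li, lj, factor, spread) in spec.loops:
            for a in range(li - spread, li + spread + 1):
                for b in range(lj - spread, lj + spread + 1):
                    # focal profile: full factor in the core, sqrt on the
                    # outermost ring, like the peaked shape of real pileups
                    ring = max(abs(a - li), abs(b - lj))
                    f = factor if ring < spread or spread == 0 else np.sqrt(factor)
                    lo, hi = min(a, b), max(a, b)
                    if 0 <= lo and hi < n and 0 <= hi - lo <= bw:
                        pos = index[lo, hi]
                        if pos > 0:
                            enrich[pos - 1] *= f
        mu = mu * enrich

    # NB(mean mu, variance phi*mu): size r = mu/(phi-1), numpy's p = 1/phi
    phi = spec.dispersion
    r = mu / (phi - 1.0)
    counts = rng.negative_binomial(r, 1.0 / phi).astype(np.float64)

    if spec.sparsity > 0:
        counts[rng.random(len(counts)) < spec.sparsity] = 0.0
    for (a, b) in spec.faulty_regions:
        dead = ((bin1 >= a) & (bin1 < b)) | ((bin2 >= a) & (bin2 < b))
        counts[dead] = 0.0

    keep = counts > 0
    matrix = BandedContactMatrix(
        chrom="chrS", bin_size=spec.bin_size, n_bins=n,
        bin1=bin1[keep], bin2=bin2[keep],
        values=counts[keep], raw=counts[keep],
        band_width=bw, min_d=0, balanced=False,
    )
    truth = TruthSet(centers=[(i, j) for (i, j, _, _) in spec.loops])
    return matrix, truth


def score_recovery(called, truth: TruthSet, tol_bins: int = 2):
    """Greedy one-to-one matching of calls to planted loops.

    A call matches an unclaimed truth center within Chebyshev distance
    ``tol_bins``.  Precision = matched/called (1 by convention when nothing
    was called), recall = matched/truth.  Returns
    ``(precision, recall, matched_pairs)``.
    """
    centers = [
        (lp.bin_i, lp.bin_j) if isinstance(lp, LoopCall) else tuple(lp)
        for lp in called
    ]
    centers.sort()
    unclaimed = set(range(len(truth.centers)))
    matched = []
    for (ci, cj) in centers:
        best = None
        for t in sorted(unclaimed):
            ti, tj = truth.centers[t]
            dist = max(abs(ti - ci), abs(tj - cj))
            if dist <= tol_bins and (best is None or dist < best[0]):
                best = (dist, t)
        if best is not None:
            unclaimed.discard(best[1])
            matched.append(((ci, cj), truth.centers[best[1]]))
    precision = len(matched) / len(centers) if centers else 1.0
    recall = len(matched) / len(truth.centers) if truth.centers else 1.0
    return precision, recall, matched
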