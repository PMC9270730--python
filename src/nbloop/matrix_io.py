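"""Reading and writing the file formats the loop-calling pipeline touches.

Hi-C contact matrices are consumed per chromosome as a *banded* sparse
matrix: only the upper triangle within a genomic-distance window
``[min_distance, max_distance]`` is stored, since loop anchors beyond a few
megabases are not searched for.  Matrices arrive either as single-resolution
cooler files (HDF5, read directly through :mod:`h5py`) or as a plain
triplet-text format with a JSON sidecar so that tests and fixtures need no
binary dependency.  Loops are exchanged as BEDPE, peak intervals as BED.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BandedContactMatrix",
    "GenomicInterval",
    "LoopCall",
    "MatrixFormatError",
    "ChromosomeNotFoundError",
    "NoWeightsError",
    "load_contact_matrix",
    "load_triplet_text",
    "write_triplet_text",
    "write_loops_bedpe",
    "read_loops_bedpe",
    "read_intervals_bed",
]


class MatrixFormatError(ValueError):
    """Input matrix violates format expectations (negative/NaN values, bad geometry)."""


class ChromosomeNotFoundError(KeyError):
    """Requested chromosome is absent from the input file."""


class NoWeightsError(ValueError):
    """Balanced values requested but the file stores no balancing weights."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )


@dataclass(frozen=True)
class LoopCall:
    """An accepted loop: two single-bin anchors plus the statistics that accepted it."""

    chrom: str
    bin_i: int
    bin_j: int
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    obs_exp: float
    p_preselect: float
    p_horizontal: float
    p_vertical: float
    p_corner: float
    raw_count: float

    def __post_init__(self) -> None:
        if self.bin_i >= self.bin_j:
            raise ValueError("loop anchors must satisfy bin_i < bin_j")
        for p in (self.p_preselect, self.p_horizontal, self.p_vertical, self.p_corner):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value {p} outside [0, 1]")

    @classmethod
    def from_bins(
        cls,
        chrom: str,
        bin_i: int,
        bin_j: int,
        bin_size: int,
        obs_exp: float,
        p_preselect: float,
        p_horizontal: float,
        p_vertical: float,
        p_corner: float,
        raw_count: float,
    ) -> "LoopCall":
        a1 = GenomicInterval(chrom, bin_i * bin_size, (bin_i + 1) * bin_size)
        a2 = GenomicInterval(chrom, bin_j * bin_size, (bin_j + 1) * bin_size)
        return cls(
            chrom, bin_i, bin_j, a1, a2, obs_exp,
            p_preselect, p_horizontal, p_vertical, p_corner, raw_count,
        )


@dataclass
class BandedContactMatrix:
    """Symmetric per-chromosome contact matrix restricted to a diagonal band.

    Only the upper triangle is stored: parallel arrays ``bin1 <= bin2`` with
    ``min_d <= bin2 - bin1 <= band_width`` (distances in bins).  ``values``
    holds the analysis substrate (balanced counts when ``balanced`` is true,
    raw otherwise); ``raw`` always holds the uncorrected counts so that the
    absolute-interaction filter can be applied regardless of balancing.
    """

    chrom: str
    bin_size: int
    n_bins: int
    bin1: np.ndarray
    bin2: np.ndarray
    values: np.ndarray
    raw: np.ndarray
    band_width: int
    min_d: int = 0
    balanced: bool = False
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if not (len(self.bin1) == len(self.bin2) == len(self.values) == len(self.raw)):
            raise MatrixFormatError("entry arrays have inconsistent lengths")
        if len(self.bin1):
            if self.bin1.min() < 0 or self.bin2.max() >= self.n_bins:
                raise MatrixFormatError("bin index outside [0, n_bins)")
            d = self.bin2 - self.bin1
            if d.min() < 0:
                raise MatrixFormatError("entries must satisfy bin1 <= bin2")
            if d.min() < self.min_d or d.max() > self.band_width:
                raise MatrixFormatError("entry outside the configured distance band")
            if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
                raise MatrixFormatError("values must be finite and >= 0")
            keys = self.bin1 * self.n_bins + self.bin2
            if len(np.unique(keys)) != len(keys):
                raise MatrixFormatError("duplicate (bin1, bin2) entries")
        # canonical (distance, bin1) order so downstream output is deterministic
        order = np.lexsort((self.bin1, self.bin2 - self.bin1))
        self.bin1 = self.bin1[order]
        self.bin2 = self.bin2[order]
        self.values = self.values[order]
        self.raw = self.raw[order]

    def __len__(self) -> int:
        return len(self.bin1)

    @property
    def distances(self) -> np.ndarray:
        return self.bin2 - self.bin1

    def with_values(self, values: np.ndarray) -> "BandedContactMatrix":
        """Same geometry with a new value array (used for obs/exp transforms)."""
        return BandedContactMatrix(
            self.chrom, self.bin_size, self.n_bins,
            self.bin1.copy(), self.bin2.copy(),
            np.asarray(values, dtype=np.float64), self.raw.copy(),
            self.band_width, self.min_d, self.balanced,
        )

    def to_csr(self, use: str = "values"):
        """Upper-triangle CSR view of the band (missing entries are zero)."""
        from scipy.sparse import csr_matrix

        data = self.values if use == "values" else self.raw
        return csr_matrix(
            (data, (self.bin1, self.bin2)), shape=(self.n_bins, self.n_bins)
        )


# ---------------------------------------------------------------------------
# contact matrix input

def load_contact_matrix(
    path: str | os.PathLike,
    chrom: str,
    max_distance: int,
    min_distance: int = 0,
    use_balanced: bool = True,
) -> BandedContactMatrix:
    """Load one chromosome of a contact matrix as a banded sparse matrix.

    ``path`` may be a single-resolution cooler file (HDF5) or triplet text
    with a ``<path>.json`` sidecar.  ``max_distance``/``min_distance`` are in
    base pairs; only entries with
    ``min_distance/bin_size <= (j - i) <= max_distance/bin_size`` are kept.
    With ``use_balanced`` the stored balancing weights are applied
    multiplicatively (``w_i * w_j * count``); raw counts remain available on
    the returned matrix either way.
    """
    if max_distance < min_distance or min_distance < 0:
        raise ValueError("require max_distance >= min_distance >= 0")
    path = os.fspath(path)
    if _is_hdf5(path):
        return _load_cooler(path, chrom, max_distance, min_distance, use_balanced)
    return load_triplet_text(path, chrom, max_distance, min_distance, use_balanced)


def list_chromosomes(path: str | os.PathLike) -> list[str]:
    """Chromosome names stored in a cooler file (or the triplet sidecar's one)."""
    path = os.fspath(path)
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "r") as f:
            return [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in f["chroms/name"][:]
            ]
    with open(path + ".json") as fh:
        return [json.load(fh)["chrom"]]


def _is_hdf5(path: str) -> bool:
    try:
        with open(path, "rb") as fh:
            return fh.read(8) == b"\x89HDF\r\n\x1a\n"
    except OSError:
        return False


def _load_cooler(path, chrom, max_distance, min_distance, use_balanced):
    import h5py

    with h5py.File(path, "r") as f:
        grp = f
        # multi-cooler files nest single-resolution groups; require one matrix
        if "bins" not in grp:
            raise MatrixFormatError(
                f"{path}: not a single-resolution cooler file (no 'bins' group)"
            )
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in grp["chroms/name"][:]
        ]
        if chrom not in chrom_names:
            raise ChromosomeNotFoundError(
                f"chromosome {chrom!r} not in {path} (has {chrom_names})"
            )
        cid = chrom_names.index(chrom)
        bin_chrom = grp["bins/chrom"][:]
        bin_start = grp["bins/start"][:]
        bin_end = grp["bins/end"][:]
        mask = bin_chrom == cid
        (bin_idx,) = np.nonzero(mask)
        lo, hi = int(bin_idx[0]), int(bin_idx[-1]) + 1
        n_bins = hi - lo
        bin_size = int(np.median(bin_end[mask] - bin_start[mask]))
        weights = None
        if use_balanced:
            if "weight" not in grp["bins"]:
                raise NoWeightsError(
                    f"{path} stores no 'weight' column; pass use_balanced=False"
                )
            weights = grp["bins/weight"][lo:hi]
        # pixels are sorted by bin1_id; indexes/bin1_offset bounds the slice
        if "indexes" in grp and "bin1_offset" in grp["indexes"]:
            off = grp["indexes/bin1_offset"][:]
            p_lo, p_hi = int(off[lo]), int(off[hi])
        else:
            p_lo, p_hi = 0, grp["pixels/bin1_id"].shape[0]
        b1 = grp["pixels/bin1_id"][p_lo:p_hi]
        b2 = grp["pixels/bin2_id"][p_lo:p_hi]
        counts = grp["pixels/count"][p_lo:p_hi].astype(np.float64)

    sel = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
    b1, b2, counts = b1[sel] - lo, b2[sel] - lo, counts[sel]
    return _assemble(
        chrom, bin_size, n_bins, b1, b2, counts, weights,
        max_distance, min_distance,
    )


def load_triplet_text(
    path: str | os.PathLike,
    chrom: str | None = None,
    max_distance: int | None = None,
    min_distance: int = 0,
    use_balanced: bool = False,
) -> BandedContactMatrix:
    """Read the triplet-text fallback: lines ``bin_i bin_j value`` plus a
    ``<path>.json`` sidecar holding chrom / bin_size / n_bins (and optional
    per-bin ``weights``)."""
    path = os.fspath(path)
    sidecar = path + ".json"
    if not os.path.exists(sidecar):
        raise MatrixFormatError(f"triplet file {path} has no sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    if chrom is not None and meta["chrom"] != chrom:
        raise ChromosomeNotFoundError(
            f"sidecar declares chromosome {meta['chrom']!r}, requested {chrom!r}"
        )
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["bin1", "bin2", "value"],
    )
    b1 = df["bin1"].to_numpy(dtype=np.int64)
    b2 = df["bin2"].to_numpy(dtype=np.int64)
    counts = df["value"].to_numpy(dtype=np.float64)
    weights = None
    if use_balanced:
        if "weights" not in meta:
            raise NoWeightsError(f"{sidecar} stores no 'weights'; pass use_balanced=False")
        weights = np.asarray(meta["weights"], dtype=np.float64)
    bin_size = int(meta["bin_size"])
    if max_distance is None:
        max_distance = (int(meta["n_bins"]) - 1) * bin_size
    return _assemble(
        meta["chrom"], bin_size, int(meta["n_bins"]),
        b1, b2, counts, weights, max_distance, min_distance,
    )


def _assemble(chrom, bin_size, n_bins, b1, b2, counts, weights, max_distance, min_distance):
    if np.any(~np.isfinite(counts)) or (len(counts) and counts.min() < 0):
        raise MatrixFormatError("matrix contains negative or non-finite counts")
    # fold into the upper triangle
    lo = np.minimum(b1, b2)
    hi = np.maximum(b1, b2)
    max_d = int(max_distance // bin_size)
    min_d = int(-(-min_distance // bin_size))  # ceil
    d = hi - lo
    sel = (d >= min_d) & (d <= max_d)
    lo, hi, counts = lo[sel], hi[sel], counts[sel]
    raw = counts.copy()
    balanced = weights is not None
    if balanced:
        w = np.asarray(weights, dtype=np.float64)
        vals = w[lo] * w[hi] * counts
        bad = ~np.isfinite(vals)
        # bins with NaN weight are masked by balancing (cooler convention)
        vals[bad] = 0.0
        raw[bad] = 0.0
    else:
        vals = counts
    return BandedContactMatrix(
        chrom=chrom, bin_size=bin_size, n_bins=n_bins,
        bin1=lo, bin2=hi, values=vals, raw=raw,
        band_width=max_d, min_d=min_d, balanced=balanced,
    )


def write_triplet_text(matrix: BandedContactMatrix, path: str | os.PathLike) -> None:
    """Write a banded matrix as triplet text + JSON sidecar (values column = raw counts)."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write(f"# triplet contact matrix {matrix.chrom}\n")
        for i, j, v in zip(matrix.bin1, matrix.bin2, matrix.raw):
            fh.write(f"{i}\t{j}\t{v:g}\n")
    with open(path + ".json", "w") as fh:
        json.dump(
            {"chrom": matrix.chrom, "bin_size": matrix.bin_size, "n_bins": matrix.n_bins},
            fh,
        )
        fh.write("\n")


# ---------------------------------------------------------------------------
# BEDPE / BED

_BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\tstrand1\tstrand2"
    "\tobs_exp\tp_preselect\tp_horizontal\tp_vertical\tp_corner\traw_count\n"
)


def write_loops_bedpe(loops, path: str | os.PathLike) -> None:
    """Write loop calls as BEDPE with p-value columns; deterministic byte output.

    Rows are sorted by (chrom, bin_i, bin_j); score is the obs/exp value.
    """
    rows = sorted(loops, key=lambda lp: (lp.chrom, lp.bin_i, lp.bin_j))
    with open(path, "w") as fh:
        fh.write(_BEDPE_HEADER)
        for k, lp in enumerate(rows):
            fh.write(
                f"{lp.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}"
                f"\t{lp.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}"
                f"\tloop_{k}\t{lp.obs_exp:.6g}\t.\t."
                f"\t{lp.obs_exp:.10g}\t{lp.p_preselect:.10g}"
                f"\t{lp.p_horizontal:.10g}\t{lp.p_vertical:.10g}"
                f"\t{lp.p_corner:.10g}\t{lp.raw_count:.10g}\n"
            )


def read_loops_bedpe(path: str | os.PathLike) -> list[LoopCall]:
    """Read loops written by :func:`write_loops_bedpe` (round-trip inverse)."""
    loops: list[LoopCall] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            t = line.rstrip("\n").split("\t")
            chrom, s1, e1, _, s2, e2 = t[0], int(t[1]), int(t[2]), t[3], int(t[4]), int(t[5])
            bin_size = e1 - s1
            extras = [float(x) for x in t[10:16]] if len(t) >= 16 else [1, 1, 1, 1, 1, 0]
            loops.append(
                LoopCall(
                    chrom, s1 // bin_size, s2 // bin_size,
                    GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2),
                    obs_exp=extras[0], p_preselect=extras[1],
                    p_horizontal=extras[2], p_vertical=extras[3],
                    p_corner=extras[4], raw_count=extras[5],
                )
            )
    return loops


def read_intervals_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a 3+ column BED file as 0-based half-open intervals.

    Track, browser, and ``#`` comment lines are skipped; a start >= end raises
    with the offending line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            t = s.split("\t") if "\t" in s else s.split()
            if len(t) < 3:
                raise MatrixFormatError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = t[0], int(t[1]), int(t[2])
            if start >= end:
                raise MatrixFormatError(
                    f"{path}:{ln}: invalid interval start={start} >= end={end}"
                )
            out.append(GenomicInterval(chrom, start, end))
    return out
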