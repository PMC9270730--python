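"""Strict per-distance candidate selection.

A pixel (i, j) becomes a loop candidate only if all of the following hold:

* its genomic distance carries a usable fitted model,
* its obs/exp value reaches ``obs_exp_threshold``,
* its right-tail p-value under the distance's continuous NB model is below
  ``p_value_preselection``,
* its *raw* (uncorrected) interaction count reaches
  ``peak_interaction_threshold``.

Tightening any threshold can only shrink the candidate set; pixels at
distances whose fit failed are silently non-candidates (their count is
reported in the stage-count summary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LoopCallingConfig
from .cont_negbinom import ModelSet, cnb_pvalue
from .matrix_io import BandedContactMatrix

__all__ = ["Candidate", "select_candidates"]


@dataclass(frozen=True)
class Candidate:
    """An enriched pixel that survived all preselection gates."""

    i: int
    j: int
    d: int
    obs_exp: float
    raw_count: float
    p_preselect: float


def select_candidates(
    obsexp: BandedContactMatrix,
    models: ModelSet,
    config: LoopCallingConfig,
    stage_counts: dict | None = None,
) -> list[Candidate]:
    """Apply the preselection gates; output sorted by (distance, i).

    ``stage_counts``, if given, is filled with the pixel count surviving each
    successive filter (modelled distance -> obs/exp gate -> p-value gate ->
    raw-count gate).
    """
    d = obsexp.distances
    n = len(obsexp)
    # the configured search band may be narrower than the stored band
    min_d = -(-config.min_distance // obsexp.bin_size)
    max_d = config.max_distance // obsexp.bin_size
    in_band = (d >= min_d) & (d <= max_d)
    has_model = in_band & np.isin(
        d, np.fromiter(models.keys(), dtype=np.int64, count=len(models))
    )

    enriched = has_model & (obsexp.values >= config.obs_exp_threshold)

    pvals = np.ones(n)
    for dd in np.unique(d[enriched]):
        sel = enriched & (d == dd)
        pvals[sel] = cnb_pvalue(obsexp.values[sel], models[int(dd)])
    significant = enriched & (pvals < config.p_value_preselection)

    tall = significant & (obsexp.raw >= config.peak_interaction_threshold)

    if stage_counts is not None:
        stage_counts["in_band"] = int(n)
        stage_counts["modelled_distance"] = int(has_model.sum())
        stage_counts["obs_exp_gate"] = int(enriched.sum())
        stage_counts["p_value_gate"] = int(significant.sum())
        stage_counts["raw_count_gate"] = int(tall.sum())

    idx = np.nonzero(tall)[0]
    # entries are already in (distance, i) order in the banded store
    return [
        Candidate(
            i=int(obsexp.bin1[k]), j=int(obsexp.bin2[k]), d=int(d[k]),
            obs_exp=float(obsexp.values[k]), raw_count=float(obsexp.raw[k]),
            p_preselect=float(pvals[k]),
        )
        for k in idx
    ]
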