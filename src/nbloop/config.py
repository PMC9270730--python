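"""Loop-calling configuration with the tool's standard defaults.

Defaults: peak_width 2, window_size 5, p_value_preselection 0.1,
p_value 0.025, peak_interaction_threshold 10, obs_exp_threshold 1.5,
nonzero expected mode, search band 40 kb - 2 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .expected_model import EXPECTED_MODES

__all__ = ["LoopCallingConfig"]


@dataclass
class LoopCallingConfig:
    """All tunables of the loop-calling pipeline.

    ``peak_width`` and ``window_size`` are inradii: a square with inradius w
    spans (2w+1) bins per side.  ``obs_exp_threshold`` is used twice, as the
    prefit thinning threshold for the per-distance NB fits and as the
    enrichment gate on candidates.  ``min_distance``/``max_distance`` are in
    base pairs.
    """

    peak_width: int = 2
    window_size: int = 5
    p_value_preselection: float = 0.1
    p_value: float = 0.025
    peak_interaction_threshold: float = 10.0
    obs_exp_threshold: float = 1.5
    expected_mode: str = "nonzero"
    min_distance: int = 40_000          # 4 bins at 10 kb: skip the noisy near-diagonal
    max_distance: int = 2_000_000
    threads: int = 1
    min_background_elements: int = 25
    min_fit_observations: int = 100
    use_balanced: bool = True

    def __post_init__(self) -> None:
        if self.peak_width >= self.window_size:
            raise ValueError(
                f"peak_width ({self.peak_width}) must be smaller than "
                f"window_size ({self.window_size})"
            )
        if self.peak_width < 1:
            raise ValueError("peak_width must be >= 1")
        if not (0 < self.p_value_preselection < 1) or not (0 < self.p_value < 1):
            raise ValueError("p-value thresholds must lie in (0, 1)")
        if self.peak_interaction_threshold < 0 or self.obs_exp_threshold < 0:
            raise ValueError("interaction/enrichment thresholds must be >= 0")
        if self.expected_mode not in EXPECTED_MODES:
            raise ValueError(f"expected_mode must be one of {EXPECTED_MODES}")
        if not (0 <= self.min_distance <= self.max_distance):
            raise ValueError("require 0 <= min_distance <= max_distance")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
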