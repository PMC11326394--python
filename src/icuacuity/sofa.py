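"""SOFA-score comparison baselines.

SOFA (Sequential Organ Failure Assessment) is an integer 0-24 organ
dysfunction score. Two baseline predictors are provided: the raw score
scaled to [0, 1] (used directly as a risk probability), and the binary
criterion of a rise of 2 or more points over the admission (baseline)
score, used to flag windows as unstable. SOFA is consumed as a precomputed
per-window series; computing it from organ components is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SofaSeries", "scale_sofa", "sofa_delta_flag"]

SOFA_MAX = 24


@dataclass
class SofaSeries:
    stay_id: str
    baseline_sofa: int
    scores: np.ndarray  # integer score per prediction window

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if not (0 <= self.baseline_sofa <= SOFA_MAX):
            raise ValueError("baseline SOFA out of [0, 24]")
        if self.scores.size and not (
            self.scores.min() >= 0 and self.scores.max() <= SOFA_MAX
        ):
            raise ValueError("SOFA scores out of [0, 24]")

    def scaled(self) -> np.ndarray:
        return np.array([scale_sofa(int(s)) for s in self.scores])

    def delta_flags(self) -> np.ndarray:
        return np.array(
            [sofa_delta_flag(int(s), self.baseline_sofa) for s in self.scores]
        )


def scale_sofa(raw: int) -> float:
    """Scale a raw SOFA score to [0, 1]."""
    if not 0 <= raw <= SOFA_MAX:
        raise ValueError(f"SOFA score must lie in [0, {SOFA_MAX}], got {raw}")
    return raw / SOFA_MAX


def sofa_delta_flag(current: int, baseline: int) -> int:
    """1 iff the current score rose >= 2 points above the admission score."""
    if not (0 <= current <= SOFA_MAX and 0 <= baseline <= SOFA_MAX):
        raise ValueError("SOFA scores must lie in [0, 24]")
    return int(current - baseline >= 2)
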