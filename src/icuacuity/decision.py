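"""Deterministic acuity decision logic over thresholded head outputs.

The seven relevant binary heads are combined into a single acuity state
with a fixed priority: deceased (most severe) first; then unstable if any
instability-indicating head fires (unstable, stable->unstable transition,
or any therapy onset MV/VP/CRRT); then discharge; stable is the default.
The unstable->stable head is an evaluated output but does not enter the
logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["BinaryHeads", "decide_acuity", "decide_acuity_frame", "truth_table"]

#: Head names feeding the decision, in canonical order.
DECISION_HEADS = ("deceased", "unstable", "stable_to_unstable", "mv", "vp", "crrt", "discharge")


@dataclass(frozen=True)
class BinaryHeads:
    deceased: int
    unstable: int
    stable_to_unstable: int
    mv: int
    vp: int
    crrt: int
    discharge: int

    def __post_init__(self) -> None:
        for name in DECISION_HEADS:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"head {name} must be 0 or 1")


def decide_acuity(h: BinaryHeads) -> str:
    """Map thresholded heads to one of discharge/stable/unstable/deceased."""
    if h.deceased:
        return "deceased"
    if h.unstable or h.stable_to_unstable or h.mv or h.vp or h.crrt:
        return "unstable"
    if h.discharge:
        return "discharge"
    return "stable"


def decide_acuity_frame(frame: pd.DataFrame) -> pd.Series:
    """Vectorized decision over a predictions table.

    Expects binary columns ``b_deceased``, ``b_unstable``,
    ``b_stable_to_unstable``, ``b_mv_onset``, ``b_vp_onset``,
    ``b_crrt_onset``, ``b_discharge``.
    """
    deceased = frame["b_deceased"] == 1
    unstable = (
        (frame["b_unstable"] == 1)
        | (frame["b_stable_to_unstable"] == 1)
        | (frame["b_mv_onset"] == 1)
        | (frame["b_vp_onset"] == 1)
        | (frame["b_crrt_onset"] == 1)
    )
    discharge = frame["b_discharge"] == 1
    out = pd.Series("stable", index=frame.index)
    out[discharge] = "discharge"
    out[unstable] = "unstable"
    out[deceased] = "deceased"
    return out


def truth_table() -> pd.DataFrame:
    """The exhaustive 128-row decision table over all head combinations."""
    rows = []
    for bits in range(2**7):
        values = [(bits >> i) & 1 for i in range(7)]
        heads = BinaryHeads(**dict(zip(DECISION_HEADS, values)))
        rows.append({**dict(zip(DECISION_HEADS, values)), "state": decide_acuity(heads)})
    return pd.DataFrame(rows)
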