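"""Computable acuity phenotyping of ICU stays.

Each stay is tiled into consecutive prediction windows (default 4 hours,
half-open ``[start, end)``); each prediction window is paired with the
immediately preceding observation window of the same length. A window is

* ``unstable`` if any life-sustaining therapy (MV, VP, CRRT) overlaps it or
  the rolling massive-blood-transfusion flag (>= 10 units in the trailing
  24 h) is raised anywhere inside it;
* ``deceased`` / ``discharge`` on the stay's final window, depending on the
  disposition (the terminal state overrides instability);
* ``stable`` otherwise.

Transition labels (stable->unstable, unstable->stable) compare consecutive
prediction-window states and are masked on the first prediction window,
which has no predecessor state. Therapy-onset labels mark windows in which
a therapy starts after being absent throughout the preceding window. BT has
no onset label: its definition looks back 24 hours, so the therapy is
already underway by prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import REQUIRED_VITALS, THERAPIES, StayRecord

__all__ = [
    "PhenotypeConfig",
    "LabeledWindow",
    "STATES",
    "LABEL_NAMES",
    "apply_cohort_filters",
    "build_window_grid",
    "rolling_bt_flag",
    "label_states",
    "label_transitions",
    "label_onsets",
    "label_stay",
    "label_cohort",
    "windows_to_frame",
    "transition_matrix",
]

STATES = ("discharge", "stable", "unstable", "deceased")

#: The nine outcome labels, in head order.
LABEL_NAMES = (
    "discharge",
    "stable",
    "unstable",
    "deceased",
    "unstable_to_stable",
    "stable_to_unstable",
    "mv_onset",
    "vp_onset",
    "crrt_onset",
)

_ONSET_OF = {"MV": "mv_onset", "VP": "vp_onset", "CRRT": "crrt_onset"}


@dataclass(frozen=True)
class PhenotypeConfig:
    window_hours: float = 4.0
    bt_window_hours: float = 24.0
    bt_unit_threshold: float = 10.0
    min_los_hours: float = 8.0
    max_los_days: float = 30.0
    required_vitals: tuple[str, ...] = REQUIRED_VITALS

    def __post_init__(self) -> None:
        if not self.window_hours > 0:
            raise ValueError("window_hours must be positive")
        if self.bt_unit_threshold < 1:
            raise ValueError("bt_unit_threshold must be >= 1")
        if not self.min_los_hours < self.max_los_days * 24.0:
            raise ValueError("min_los_hours must be below max_los_days")


@dataclass
class LabeledWindow:
    """One prediction window with its nine binary outcome labels.

    ``labels`` maps each name in :data:`LABEL_NAMES` to 0/1; ``mask`` is 0
    where a label is undefined (transition labels on the first window).
    Exactly one of the four primary labels is 1, and the terminal labels
    (discharge, deceased) appear only on the stay's final window.
    """

    stay_id: str
    window_index: int
    obs_start: float
    obs_end: float
    pred_start: float
    pred_end: float
    state: str
    labels: dict[str, int] = field(default_factory=dict)
    mask: dict[str, int] = field(default_factory=dict)


def apply_cohort_filters(
    stays: list[StayRecord], cfg: PhenotypeConfig
) -> tuple[list[StayRecord], list[tuple[StayRecord, str]]]:
    """Split a cohort into kept stays and excluded stays with reason codes.

    A stay is kept iff its length of stay lies within
    ``[min_los_hours, max_los_days * 24]``, every required vital sign has at
    least one event, and no static field is missing. Reason codes:
    ``los_below_min``, ``los_above_max``, ``missing_vital:<name>``,
    ``missing_static:<name>``.
    """
    kept: list[StayRecord] = []
    excluded: list[tuple[StayRecord, str]] = []
    for stay in stays:
        reason = _exclusion_reason(stay, cfg)
        if reason is None:
            kept.append(stay)
        else:
            excluded.append((stay, reason))
    return kept, excluded


def _exclusion_reason(stay: StayRecord, cfg: PhenotypeConfig) -> str | None:
    if stay.los_hours < cfg.min_los_hours:
        return "los_below_min"
    if stay.los_hours > cfg.max_los_days * 24.0:
        return "los_above_max"
    seen = {ev.variable for ev in stay.events}
    for vital in cfg.required_vitals:
        if vital not in seen:
            return f"missing_vital:{vital}"
    for name, value in stay.static.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return f"missing_static:{name}"
    return None


def build_window_grid(
    stay: StayRecord, cfg: PhenotypeConfig
) -> list[tuple[float, float, float, float]]:
    """Tile the stay into (obs_start, obs_end, pred_start, pred_end) pairs.

    Prediction windows tile ``[window_hours, los]``; the final window may be
    shorter than ``window_hours`` and carries the terminal state. A stay
    shorter than two windows yields an empty grid.
    """
    W = cfg.window_hours
    T = stay.los_hours
    if T < 2.0 * W:
        return []
    grid = []
    start = W
    while start < T:
        end = min(start + W, T)
        grid.append((start - W, start, start, end))
        start += W
    return grid


def rolling_bt_flag(
    bt_events: list[tuple[float, float]], t: float, cfg: PhenotypeConfig
) -> int:
    """1 iff transfused units in the trailing window ``(t - bt_window, t]``
    reach ``bt_unit_threshold``."""
    total = 0.0
    lo = t - cfg.bt_window_hours
    for time, units in bt_events:
        if units < 0:
            raise ValueError("transfusion units must be non-negative")
        if lo < time <= t:
            total += units
    return int(total >= cfg.bt_unit_threshold)


def _bt_unstable_in(
    bt_events: list[tuple[float, float]], lo: float, hi: float, cfg: PhenotypeConfig
) -> bool:
    """Whether the rolling BT flag is 1 anywhere in the window [lo, hi).

    The trailing-24h unit sum is piecewise constant, jumping up only at
    event times and decaying at event time + bt_window; its maximum over
    [lo, hi) is attained at lo or at an event time inside the window, so
    only those points need checking.
    """
    checkpoints = [lo] + [t for t, _ in bt_events if lo < t < hi]
    return any(rolling_bt_flag(bt_events, t, cfg) for t in checkpoints)


def label_states(
    stay: StayRecord,
    grid: list[tuple[float, float, float, float]],
    cfg: PhenotypeConfig,
) -> list[str]:
    """One acuity state per prediction window."""
    if not grid:
        raise ValueError("empty window grid")
    for iv in stay.therapies:
        if iv.start_hours > stay.los_hours:
            raise ValueError(
                f"stay {stay.stay_id}: therapy interval outside the stay"
            )
    states = []
    for _, _, lo, hi in grid:
        therapy = any(iv.overlaps(lo, hi) for iv in stay.therapies)
        bt = _bt_unstable_in(stay.bt_events, lo, hi, cfg)
        states.append("unstable" if (therapy or bt) else "stable")
    # terminal state overrides whatever therapy overlap says
    states[-1] = "deceased" if stay.disposition == "deceased" else "discharge"
    return states


def label_transitions(states: list[str]) -> list[dict[str, int | None]]:
    """Per-window stable->unstable / unstable->stable labels.

    ``None`` marks a masked label: the first prediction window has no
    predecessor state, so its transition labels are undefined rather than
    negative.
    """
    out: list[dict[str, int | None]] = []
    for i, state in enumerate(states):
        if i == 0:
            out.append({"stable_to_unstable": None, "unstable_to_stable": None})
        else:
            prev = states[i - 1]
            out.append(
                {
                    "stable_to_unstable": int(prev == "stable" and state == "unstable"),
                    "unstable_to_stable": int(prev == "unstable" and state == "stable"),
                }
            )
    return out


def label_onsets(
    stay: StayRecord,
    grid: list[tuple[float, float, float, float]],
    cfg: PhenotypeConfig,
) -> list[dict[str, int]]:
    """Per-window MV/VP/CRRT onset labels.

    A therapy onset is flagged for a prediction window iff some interval of
    that therapy starts inside the window and the therapy was not active at
    any point during the preceding ``window_hours``. The preceding interval
    always exists (the first prediction window is preceded by the first
    observation window), so onset labels are never masked.
    """
    out = []
    for _, _, lo, hi in grid:
        labels = {}
        for therapy in THERAPIES:
            ivs = [iv for iv in stay.therapies if iv.therapy == therapy]
            starts_here = any(lo <= iv.start_hours < hi for iv in ivs)
            active_before = any(iv.overlaps(lo - cfg.window_hours, lo) for iv in ivs)
            labels[_ONSET_OF[therapy]] = int(starts_here and not active_before)
        out.append(labels)
    return out


def label_stay(stay: StayRecord, cfg: PhenotypeConfig) -> list[LabeledWindow]:
    """Full labeling of one stay: states, transitions, onsets, one-hot primaries."""
    grid = build_window_grid(stay, cfg)
    if not grid:
        return []
    states = label_states(stay, grid, cfg)
    transitions = label_transitions(states)
    onsets = label_onsets(stay, grid, cfg)
    windows = []
    for i, ((olo, ohi, plo, phi), state) in enumerate(zip(grid, states)):
        labels = {name: 0 for name in LABEL_NAMES}
        mask = {name: 1 for name in LABEL_NAMES}
        labels[state] = 1
        for name, value in transitions[i].items():
            if value is None:
                mask[name] = 0
            else:
                labels[name] = value
        labels.update(onsets[i])
        windows.append(
            LabeledWindow(stay.stay_id, i, olo, ohi, plo, phi, state, labels, mask)
        )
    return windows


def label_cohort(
    stays: list[StayRecord], cfg: PhenotypeConfig
) -> list[LabeledWindow]:
    windows: list[LabeledWindow] = []
    for stay in stays:
        windows.extend(label_stay(stay, cfg))
    return windows


def windows_to_frame(windows: list[LabeledWindow]) -> pd.DataFrame:
    """Labeled windows as a flat table (one row per prediction window)."""
    rows = []
    for w in windows:
        row = {
            "stay_id": w.stay_id,
            "window_index": w.window_index,
            "obs_start": w.obs_start,
            "obs_end": w.obs_end,
            "pred_start": w.pred_start,
            "pred_end": w.pred_end,
            "state": w.state,
        }
        for name in LABEL_NAMES:
            row[name] = w.labels[name]
            row[f"{name}_mask"] = w.mask[name]
        rows.append(row)
    return pd.DataFrame(rows)


def transition_matrix(cohort_states: list[list[str]]) -> pd.DataFrame:
    """Empirical 2x4 row-stochastic acuity transition matrix.

    Rows: the current state (stable, unstable); columns: the next window's
    state. Terminal states never appear as the current state because they
    only occur on final windows.
    """
    counts = np.zeros((2, 4), dtype=float)
    row_of = {"stable": 0, "unstable": 1}
    col_of = {s: i for i, s in enumerate(("stable", "unstable", "discharge", "deceased"))}
    n_pairs = 0
    for states in cohort_states:
        for cur, nxt in zip(states[:-1], states[1:]):
            counts[row_of[cur], col_of[nxt]] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no consecutive state pairs in cohort")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(
        probs,
        index=["stable", "unstable"],
        columns=["stable", "unstable", "discharge", "deceased"],
    )
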