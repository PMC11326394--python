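"""Imputation-free triplet encoding of observation windows.

Each clinical event is a triplet (time since admission, value, variable
code). Windows are encoded as fixed-length padded sequences: events sorted
by (time, code), truncated to the most recent ``L`` if necessary, padded at
the tail with zeros and a binary mask. No value is ever imputed — padded
positions are identifiable from the mask (and code 0) alone.

The vocabulary is fitted on the development cohort: variables present in
fewer than ``min_stay_fraction`` of stays are dropped (boundary inclusive:
exactly 5% is retained), integer codes are assigned by first appearance
(code 0 is reserved for padding), per-variable 1st/99th percentile bounds
and optional hard physiologic bounds drive outlier removal, and min-max
ranges drive scaling. Event times are scaled by a fixed horizon of 720 h
(the 30-day maximum stay), keeping the encoding invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .records import ClinicalEvent, StayRecord

__all__ = [
    "TIME_SCALE_HOURS",
    "Vocabulary",
    "TripletTensor",
    "build_vocabulary",
    "filter_outliers",
    "scale_events",
    "scale_static",
    "encode_observation",
    "decode_observation",
]

TIME_SCALE_HOURS = 720.0


@dataclass
class VariableInfo:
    code: int
    stay_fraction: float
    scale_min: float
    scale_max: float
    p1: float
    p99: float
    hard_low: float | None = None
    hard_high: float | None = None


@dataclass
class Vocabulary:
    """Fitted per-variable codes, frequency, outlier bounds and ranges."""

    variables: dict[str, VariableInfo]
    static_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.variables)

    def code_of(self, name: str) -> int:
        return self.variables[name].code

    def to_json(self) -> str:
        payload = {
            "variables": {
                name: {
                    "code": v.code,
                    "stay_fraction": v.stay_fraction,
                    "scale_min": v.scale_min,
                    "scale_max": v.scale_max,
                    "p1": v.p1,
                    "p99": v.p99,
                    "hard_low": v.hard_low,
                    "hard_high": v.hard_high,
                }
                for name, v in self.variables.items()
            },
            "static_ranges": {k: list(v) for k, v in self.static_ranges.items()},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        payload = json.loads(text)
        variables = {
            name: VariableInfo(**info) for name, info in payload["variables"].items()
        }
        static_ranges = {k: tuple(v) for k, v in payload["static_ranges"].items()}
        return cls(variables, static_ranges)


@dataclass
class TripletTensor:
    """Fixed-length encoding of one observation window.

    ``mask`` is monotone (real events precede padding) and codes are 0
    exactly where the mask is 0.
    """

    times: np.ndarray
    values: np.ndarray
    codes: np.ndarray
    mask: np.ndarray

    @property
    def L(self) -> int:
        return self.times.shape[-1]

    def n_events(self) -> int:
        return int(self.mask.sum())


def build_vocabulary(
    stays: list[StayRecord],
    min_stay_fraction: float = 0.05,
    hard_bounds: dict[str, tuple[float, float]] | None = None,
) -> Vocabulary:
    """Fit the variable vocabulary on a development cohort.

    Retains variables appearing in at least ``min_stay_fraction`` of stays;
    assigns dense 1-based codes by order of first appearance (scanning
    stays in order and each stay's events in time order); records per-
    variable min/max scaling ranges and 1st/99th percentile bounds, with
    percentiles taken before outlier removal and min/max after it.
    """
    if not stays:
        raise ValueError("cannot build a vocabulary from an empty cohort")
    hard_bounds = hard_bounds or {}
    n_stays = len(stays)
    stay_counts: dict[str, int] = {}
    first_seen: list[str] = []
    values: dict[str, list[float]] = {}
    for stay in stays:
        seen: set[str] = set()
        for ev in sorted(stay.events, key=lambda e: e.time_hours):
            if ev.variable not in values:
                values[ev.variable] = []
                first_seen.append(ev.variable)
            values[ev.variable].append(ev.value)
            seen.add(ev.variable)
        for name in seen:
            stay_counts[name] = stay_counts.get(name, 0) + 1
    variables: dict[str, VariableInfo] = {}
    code = 1
    for name in first_seen:
        fraction = stay_counts[name] / n_stays
        if fraction < min_stay_fraction:
            continue
        arr = np.asarray(values[name], dtype=float)
        p1, p99 = np.percentile(arr, [1.0, 99.0])
        lo, hi = hard_bounds.get(name, (None, None))
        inlier = arr[(arr >= p1) & (arr <= p99)]
        if lo is not None:
            inlier = inlier[inlier >= lo]
        if hi is not None:
            inlier = inlier[inlier <= hi]
        if inlier.size == 0:
            inlier = arr
        variables[name] = VariableInfo(
            code=code,
            stay_fraction=fraction,
            scale_min=float(inlier.min()),
            scale_max=float(inlier.max()),
            p1=float(p1),
            p99=float(p99),
            hard_low=lo,
            hard_high=hi,
        )
        code += 1
    vocab = Vocabulary(variables)
    vocab.static_ranges = _fit_static_ranges(stays)
    return vocab


def _fit_static_ranges(stays: list[StayRecord]) -> dict[str, tuple[float, float]]:
    columns: dict[str, list[float]] = {}
    for stay in stays:
        for name, value in stay.static.items():
            columns.setdefault(name, []).append(float(value))
    return {
        name: (float(min(vals)), float(max(vals))) for name, vals in columns.items()
    }


def filter_outliers(
    events: list[ClinicalEvent], vocab: Vocabulary
) -> tuple[list[ClinicalEvent], dict[str, int]]:
    """Drop out-of-vocabulary events and outlier values.

    An event is removed if its variable is not in the vocabulary, its value
    falls outside the variable's (inclusive) 1st-99th percentile band, or
    outside the hard physiologic bounds when configured. Returns the kept
    events and per-variable removal counts.
    """
    kept: list[ClinicalEvent] = []
    removed: dict[str, int] = {}
    for ev in events:
        info = vocab.variables.get(ev.variable)
        drop = info is None
        if info is not None:
            if not (info.p1 <= ev.value <= info.p99):
                drop = True
            if info.hard_low is not None and ev.value < info.hard_low:
                drop = True
            if info.hard_high is not None and ev.value > info.hard_high:
                drop = True
        if drop:
            removed[ev.variable] = removed.get(ev.variable, 0) + 1
        else:
            kept.append(ev)
    return kept, removed


def _scale_value(value: float, lo: float, hi: float) -> float:
    if hi == lo:  # constant variable: park at mid-range
        return 0.5
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def scale_events(events: list[ClinicalEvent], vocab: Vocabulary) -> list[ClinicalEvent]:
    """Min-max scale event values with development-cohort ranges.

    Values outside the fitted range (validation data) clip to [0, 1].
    """
    out = []
    for ev in events:
        info = vocab.variables[ev.variable]
        out.append(
            ClinicalEvent(
                ev.time_hours, ev.variable, _scale_value(ev.value, info.scale_min, info.scale_max)
            )
        )
    return out


def scale_static(static: dict[str, float], vocab: Vocabulary) -> np.ndarray:
    """Scaled static feature vector, ordered by the fitted range keys."""
    return np.array(
        [
            _scale_value(float(static[name]), lo, hi)
            for name, (lo, hi) in vocab.static_ranges.items()
        ],
        dtype=float,
    )


def encode_observation(
    window_events: list[ClinicalEvent], vocab: Vocabulary, L: int
) -> TripletTensor:
    """Encode one observation window as a padded triplet sequence.

    Events are sorted by (time, code) — simultaneous events are ordered
    deterministically by ascending code. If more than ``L`` events remain,
    the ``L`` most recent are kept. Times are scaled by the fixed 720-hour
    horizon; values are assumed already scaled.
    """
    triples = sorted(
        ((ev.time_hours, vocab.code_of(ev.variable), ev.value) for ev in window_events),
        key=lambda x: (x[0], x[1]),
    )
    if len(triples) > L:
        triples = triples[-L:]
    n = len(triples)
    times = np.zeros(L)
    values = np.zeros(L)
    codes = np.zeros(L, dtype=np.int64)
    mask = np.zeros(L, dtype=np.int64)
    for i, (t, c, v) in enumerate(triples):
        times[i] = t / TIME_SCALE_HOURS
        values[i] = v
        codes[i] = c
        mask[i] = 1
    return TripletTensor(times, values, codes, mask)


def decode_observation(
    tensor: TripletTensor, vocab: Vocabulary
) -> list[ClinicalEvent]:
    """Invert :func:`encode_observation` (and value scaling) for the
    retained events; exact up to float round-off."""
    by_code = {info.code: name for name, info in vocab.variables.items()}
    events = []
    for i in range(tensor.L):
        if tensor.mask[i] == 0:
            continue
        name = by_code[int(tensor.codes[i])]
        info = vocab.variables[name]
        value = tensor.values[i]
        if info.scale_max != info.scale_min:
            value = value * (info.scale_max - info.scale_min) + info.scale_min
        events.append(
            ClinicalEvent(float(tensor.times[i] * TIME_SCALE_HOURS), name, float(value))
        )
    return events
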