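"""Domain records for ICU stays.

An ICU stay is represented in long format: a list of irregularly sampled
clinical events (time since admission in hours, variable name, value), a
static covariate vector captured at admission, intervals of life-sustaining
therapies (invasive mechanical ventilation MV, intravenous vasopressors VP,
continuous renal replacement therapy CRRT), unit blood-transfusion events
(BT), and a disposition (discharged alive or deceased) with its time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

THERAPIES = ("MV", "VP", "CRRT")

#: The six routine vital signs every kept stay must have recorded.
REQUIRED_VITALS = ("HR", "RR", "SBP", "DBP", "Temp", "SPO2")

DISPOSITIONS = ("discharged_alive", "deceased")


@dataclass(frozen=True)
class ClinicalEvent:
    """One measurement: hours since ICU admission, variable name, value."""

    time_hours: float
    variable: str
    value: float

    def __post_init__(self) -> None:
        if not (self.time_hours >= 0.0 and self.time_hours == self.time_hours):
            raise ValueError(
                f"event time must be finite and non-negative, got {self.time_hours}"
            )


@dataclass(frozen=True)
class TherapyInterval:
    """A contiguous interval during which one life-sustaining therapy ran.

    A one-time vasopressor push is recorded as a zero-length interval at
    administration time and expanded to its enclosing window downstream.
    """

    therapy: str
    start_hours: float
    end_hours: float

    def __post_init__(self) -> None:
        if self.therapy not in THERAPIES:
            raise ValueError(f"unknown therapy {self.therapy!r}; expected one of {THERAPIES}")
        if not self.end_hours >= self.start_hours:
            raise ValueError("therapy interval must have end >= start")
        if self.start_hours < 0:
            raise ValueError("therapy interval must start at or after admission")

    def overlaps(self, lo: float, hi: float) -> bool:
        """True if the interval intersects the half-open window [lo, hi).

        Zero-length intervals (one-time pushes) count as overlapping the
        window that contains their timestamp.
        """
        if self.end_hours == self.start_hours:
            return lo <= self.start_hours < hi
        return self.start_hours < hi and self.end_hours > lo


@dataclass
class StayRecord:
    """One ICU stay: events, static features, therapies, disposition."""

    stay_id: str
    events: list[ClinicalEvent]
    static: dict[str, float]
    therapies: list[TherapyInterval] = field(default_factory=list)
    bt_events: list[tuple[float, float]] = field(default_factory=list)  # (hours, units)
    disposition: str = "discharged_alive"
    disposition_time_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.disposition not in DISPOSITIONS:
            raise ValueError(f"disposition must be one of {DISPOSITIONS}")
        if not self.disposition_time_hours > 0:
            raise ValueError("disposition_time_hours must be positive")

    @property
    def los_hours(self) -> float:
        return self.disposition_time_hours

    def validate(self) -> None:
        """Raise if any event or therapy interval falls outside the stay."""
        T = self.disposition_time_hours
        for ev in self.events:
            if ev.time_hours > T:
                raise ValueError(
                    f"stay {self.stay_id}: event at {ev.time_hours} h after disposition {T} h"
                )
        for th in self.therapies:
            if th.start_hours > T:
                raise ValueError(
                    f"stay {self.stay_id}: therapy {th.therapy} starts outside the stay"
                )
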