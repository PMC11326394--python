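"""Seeded synthetic ICU cohort generator.

The generator produces cohorts with the statistical structure the acuity
prediction method assumes, without any real patient data:

* a latent deterioration process per stay — a bounded random walk on [0, 1]
  with a per-stay drift, stored on an hourly knot grid and interpolated
  piecewise-linearly;
* irregularly sampled clinical events — per-variable homogeneous Poisson
  processes thinned by missingness, with a planted signal: risk-coupled
  vitals are shifted by ``signal_strength`` (in units of the variable's
  standard deviation, scaled by the latent risk);
* life-sustaining therapy initiation (MV, VP, CRRT) via per-window
  Bernoulli draws with a logistic link on the latent risk, and death via a
  discrete-time hazard that also increases with risk;
* blood-transfusion events in bursts of single units, so the rolling
  24-hour massive-transfusion rule occasionally fires;
* a synthetic per-4-hour SOFA score series correlated with the latent risk
  (for the SOFA comparison baseline).

Ground truth (the latent trajectory) is returned in a sidecar structure
alongside the cohort and is never consumed by the modelling pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .records import REQUIRED_VITALS, ClinicalEvent, StayRecord, TherapyInterval

__all__ = [
    "SyntheticParams",
    "StayGroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "latent_risk_trajectory",
    "sample_events",
    "variable_table",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic cohort generator.

    ``signal_strength`` is the shift of the deteriorating (risk-coupled)
    vitals in latent-risk units: an event of a coupled variable at time t
    has mean ``mu + sd * coupling * signal_strength * risk(t)``.
    """

    n_stays: int = 200
    seed: int = 0
    mean_los_hours: float = 48.0
    event_rate_per_hour: float = 0.5
    n_temporal_vars: int = 12
    n_static_vars: int = 6
    signal_strength: float = 1.0
    therapy_hazard_scale: float = 1.0
    mortality_hazard_scale: float = 1.0
    missingness: float | dict[str, float] = 0.1
    truncate_los: bool = True
    hazard_window_hours: float = 4.0

    def validate(self) -> None:
        if self.n_stays < 1:
            raise ValueError("n_stays: must be >= 1")
        if not self.mean_los_hours > 0:
            raise ValueError("mean_los_hours: must be > 0")
        if not self.event_rate_per_hour > 0:
            raise ValueError("event_rate_per_hour: must be > 0")
        if self.n_temporal_vars < len(REQUIRED_VITALS):
            raise ValueError(
                f"n_temporal_vars: must be >= {len(REQUIRED_VITALS)} (the required vitals)"
            )
        if self.n_static_vars < 1:
            raise ValueError("n_static_vars: must be >= 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength: must be >= 0")
        if self.therapy_hazard_scale < 0:
            raise ValueError("therapy_hazard_scale: must be >= 0")
        if self.mortality_hazard_scale < 0:
            raise ValueError("mortality_hazard_scale: must be >= 0")
        miss = self.missingness
        values = miss.values() if isinstance(miss, dict) else [miss]
        for m in values:
            if not 0.0 <= m <= 1.0:
                raise ValueError("missingness: probabilities must lie in [0, 1]")
        if not self.hazard_window_hours > 0:
            raise ValueError("hazard_window_hours: must be > 0")

    def missingness_for(self, variable: str) -> float:
        if isinstance(self.missingness, dict):
            return self.missingness.get(variable, 0.0)
        return self.missingness


@dataclass
class StayGroundTruth:
    """Sidecar latent-risk trajectory of one synthetic stay.

    Risk is stored on an hourly knot grid and interpolated linearly, so the
    trajectory is piecewise-continuous on [0, los_hours].
    """

    stay_id: str
    los_hours: float
    knot_hours: np.ndarray
    risk: np.ndarray
    drift: float
    deteriorating: bool


@dataclass
class SyntheticCohort:
    """A generated cohort plus its never-consumed ground-truth sidecar."""

    stays: list[StayRecord]
    ground_truth: dict[str, StayGroundTruth]
    sofa: dict[str, np.ndarray]
    baseline_sofa: dict[str, int]
    params: SyntheticParams = field(repr=False, default=None)


# (name, mean, sd, risk coupling); the first six are the required vitals.
_BASE_VARIABLES = [
    ("HR", 80.0, 15.0, 1.0),
    ("RR", 18.0, 5.0, 0.7),
    ("SBP", 120.0, 20.0, -0.8),
    ("DBP", 70.0, 12.0, -0.4),
    ("Temp", 37.0, 0.6, 0.0),
    ("SPO2", 97.0, 2.5, -0.6),
]


def variable_table(n_temporal_vars: int) -> list[tuple[str, float, float, float]]:
    """The generator's temporal-variable catalogue.

    The six required vitals come first; extra variables (``lab7``,
    ``lab8``, ...) are uncoupled noise so attribution experiments have
    non-predictive competitors.
    """
    table = list(_BASE_VARIABLES[:n_temporal_vars])
    for i in range(len(table), n_temporal_vars):
        table.append((f"lab{i + 1}", 50.0, 10.0, 0.0))
    return table


def latent_risk_trajectory(gt: StayGroundTruth, t) -> np.ndarray | float:
    """Latent risk at time(s) t (hours since admission), in [0, 1]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > gt.los_hours):
        raise ValueError(
            f"time outside stay {gt.stay_id}: valid range is [0, {gt.los_hours}] h"
        )
    out = np.interp(t_arr, gt.knot_hours, gt.risk)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _draw_los(params: SyntheticParams, rng: np.random.Generator) -> float:
    sigma = 0.8
    mu = math.log(params.mean_los_hours) - 0.5 * sigma**2
    for _ in range(1000):
        los = float(rng.lognormal(mu, sigma))
        if not params.truncate_los or 8.0 <= los <= 720.0:
            return los
    return float(np.clip(los, 8.0, 720.0))


def _draw_risk_walk(
    los: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    n_knots = int(math.ceil(los)) + 1
    knots = np.arange(n_knots, dtype=float)
    knots[-1] = los  # hourly grid whose last knot is the disposition time
    r0 = float(np.clip(rng.normal(0.25, 0.15), 0.02, 0.9))
    deteriorating = rng.random() < 0.35
    if deteriorating:
        drift = 0.02 + abs(rng.normal(0.0, 0.025))
    else:
        drift = float(rng.normal(0.0, 0.004))
    steps = drift + 0.03 * rng.standard_normal(n_knots - 1)
    risk = np.empty(n_knots)
    risk[0] = r0
    for k in range(1, n_knots):
        risk[k] = min(1.0, max(0.0, risk[k - 1] + steps[k - 1]))
    return knots, risk, drift, deteriorating


def sample_events(
    gt: StayGroundTruth, params: SyntheticParams, rng: np.random.Generator | None = None
) -> list[ClinicalEvent]:
    """Sample irregular clinical events for one stay.

    Per variable, event times follow a homogeneous Poisson process at
    ``event_rate_per_hour`` over the stay, thinned independently by the
    variable's missingness probability. Values carry the planted signal
    through the latent risk. Duplicate timestamps across variables are
    permitted (ties are resolved deterministically at encoding time).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    events: list[ClinicalEvent] = []
    for name, mu, sd, coupling in variable_table(params.n_temporal_vars):
        n = rng.poisson(params.event_rate_per_hour * gt.los_hours)
        times = np.sort(rng.uniform(0.0, gt.los_hours, size=n))
        keep = rng.random(n) >= params.missingness_for(name)
        times = times[keep]
        if times.size == 0:
            continue
        risk = np.interp(times, gt.knot_hours, gt.risk)
        values = mu + sd * (
            coupling * params.signal_strength * risk + rng.standard_normal(times.size)
        )
        events.extend(
            ClinicalEvent(float(t), name, float(v)) for t, v in zip(times, values)
        )
    events.sort(key=lambda e: e.time_hours)
    return events


# Per-therapy (base per-window start probability, risk threshold of the
# logistic link, minimum duration in hours). The link is steep so starts
# concentrate in genuinely high-risk windows, and a running therapy stops
# shortly after the latent risk recedes below its threshold — both keep
# the planted vital signal recoverable from the instability labels.
_THERAPY_PARAMS = {
    "MV": (0.30, 0.70, 8.0),
    "VP": (0.25, 0.65, 4.0),
    "CRRT": (0.08, 0.85, 12.0),
}
_THERAPY_SLOPE = 14.0
_THERAPY_RELEASE = 0.15  # risk must fall this far below threshold to wean


def _therapy_end(
    gt: StayGroundTruth,
    start: float,
    thr: float,
    min_dur: float,
    rng: np.random.Generator,
) -> float:
    """Therapy runs until the latent risk recedes below thr - release
    (plus a short weaning delay), or to the end of the stay."""
    release = thr - _THERAPY_RELEASE
    earliest = start + min_dur * float(rng.lognormal(0.0, 0.3))
    end = gt.los_hours
    for kh, r in zip(gt.knot_hours, gt.risk):
        if kh >= earliest and r < release:
            end = kh + float(rng.uniform(0.0, 4.0))
            break
    return min(end, gt.los_hours)


def _draw_therapies(
    gt: StayGroundTruth, params: SyntheticParams, rng: np.random.Generator
) -> list[TherapyInterval]:
    W = params.hazard_window_hours
    intervals: list[TherapyInterval] = []
    for therapy, (base, thr, min_dur) in _THERAPY_PARAMS.items():
        active_until = -1.0
        t = 0.0
        while t < gt.los_hours:
            mid = min(t + 0.5 * W, gt.los_hours)
            if mid > active_until:
                r = float(np.interp(mid, gt.knot_hours, gt.risk))
                p = params.therapy_hazard_scale * base * expit(_THERAPY_SLOPE * (r - thr))
                if rng.random() < min(p, 1.0):
                    start = float(rng.uniform(t, min(t + W, gt.los_hours)))
                    if therapy == "VP" and rng.random() < 0.2:
                        end = start  # one-time push
                    else:
                        end = _therapy_end(gt, start, thr, min_dur, rng)
                    intervals.append(TherapyInterval(therapy, start, end))
                    active_until = end
            t += W
    intervals.sort(key=lambda iv: (iv.start_hours, iv.therapy))
    return intervals


def _draw_bt_events(
    gt: StayGroundTruth, params: SyntheticParams, rng: np.random.Generator
) -> list[tuple[float, float]]:
    p_burst = min(0.08 * params.therapy_hazard_scale, 1.0)
    if rng.random() >= p_burst or gt.los_hours < 2.0:
        return []
    # bursts happen around the stay's risk peak (a bleeding crisis), so the
    # massive-transfusion rule fires during genuinely high-risk periods
    peak = float(gt.knot_hours[int(np.argmax(gt.risk))])
    t0 = float(np.clip(peak + rng.uniform(-4.0, 0.0), 0.0, max(gt.los_hours - 2.0, 0.01)))
    n_units = 4 + int(rng.poisson(8))
    span = float(rng.uniform(2.0, 20.0))
    times = np.sort(rng.uniform(t0, min(t0 + span, gt.los_hours), size=n_units))
    return [(float(t), 1.0) for t in times]


def _draw_death(
    gt: StayGroundTruth, params: SyntheticParams, rng: np.random.Generator
) -> float | None:
    """Discrete-time death hazard over the hazard-window grid.

    Returns the death time in hours, or None if the stay survives.
    """
    W = params.hazard_window_hours
    t = 0.0
    while t < gt.los_hours:
        end = min(t + W, gt.los_hours)
        r = float(np.interp(min(t + 0.5 * W, gt.los_hours), gt.knot_hours, gt.risk))
        p = params.mortality_hazard_scale * 0.02 * expit(10.0 * (r - 0.7))
        if rng.random() < min(p, 1.0):
            return end
        t += W
    return None


def _draw_static(
    params: SyntheticParams, rng: np.random.Generator
) -> dict[str, float]:
    """Static covariates: realistic marginals, independent of the latent
    risk, so the planted predictive signal lives in the vitals alone and
    attribution experiments have a well-posed target."""
    static = {
        "age": float(np.clip(rng.normal(62.0, 15.0), 18.0, 95.0)),
        "sex": float(rng.random() < 0.45),
        "bmi": float(np.clip(rng.normal(28.0, 6.0), 14.0, 60.0)),
    }
    names = list(static)[: params.n_static_vars]
    static = {k: static[k] for k in names}
    for i in range(len(static), params.n_static_vars):
        static[f"comorb{i + 1}"] = float(rng.random() < 0.3)
    return static


def _sofa_series(
    gt: StayGroundTruth, params: SyntheticParams, rng: np.random.Generator
) -> np.ndarray:
    W = params.hazard_window_hours
    n = max(1, int(math.ceil(gt.los_hours / W)))
    mids = np.minimum((np.arange(n) + 0.5) * W, gt.los_hours)
    r = np.interp(mids, gt.knot_hours, gt.risk)
    noisy = np.clip(0.8 * r + 0.08 * rng.standard_normal(n), 0.0, 1.0)
    return np.clip(np.rint(24.0 * noisy), 0, 24).astype(int)


def generate_cohort(params: SyntheticParams) -> SyntheticCohort:
    """Generate a seeded synthetic ICU cohort of exactly ``n_stays`` stays.

    Identical parameters (including the seed) give identical cohorts across
    process invocations. Therapy initiation probability and the death
    hazard are increasing functions of the latent risk.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    stays: list[StayRecord] = []
    ground_truth: dict[str, StayGroundTruth] = {}
    sofa: dict[str, np.ndarray] = {}
    baseline: dict[str, int] = {}
    for i in range(params.n_stays):
        stay_id = f"stay{i:05d}"
        los = _draw_los(params, rng)
        knots, risk, drift, det = _draw_risk_walk(los, rng)
        gt = StayGroundTruth(stay_id, los, knots, risk, drift, det)
        death_time = _draw_death(gt, params, rng)
        if death_time is not None:
            # truncate the trajectory at death
            los = death_time
            keep = knots <= los
            knots = np.append(knots[keep], los) if knots[keep][-1] < los else knots[keep]
            risk_t = np.interp(knots, gt.knot_hours, gt.risk)
            gt = StayGroundTruth(stay_id, los, knots, risk_t, drift, det)
        events = sample_events(gt, params, rng)
        therapies = _draw_therapies(gt, params, rng)
        bt_events = _draw_bt_events(gt, params, rng)
        static = _draw_static(params, rng)
        stay = StayRecord(
            stay_id=stay_id,
            events=events,
            static=static,
            therapies=therapies,
            bt_events=bt_events,
            disposition="deceased" if death_time is not None else "discharged_alive",
            disposition_time_hours=los,
        )
        stays.append(stay)
        ground_truth[stay_id] = gt
        s = _sofa_series(gt, params, rng)
        sofa[stay_id] = s
        baseline[stay_id] = int(s[0])
    return SyntheticCohort(stays, ground_truth, sofa, baseline, params)
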