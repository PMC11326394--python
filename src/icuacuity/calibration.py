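"""Isotonic recalibration of head probabilities.

Raw head probabilities are recalibrated with isotonic regression (the
pool-adjacent-violators solution, monotone non-decreasing) fitted on a
seeded random 10% stay-level sample of the evaluation set. Calibration
quality is measured with the Brier score (mean squared error between
probability and binary outcome) and an equal-width reliability curve.
Out-of-domain raw probabilities clamp to the nearest fitted knot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "CalibrationModel",
    "fit_isotonic",
    "sample_calibration_stays",
    "apply_calibration",
    "brier",
    "reliability_curve",
]


@dataclass
class CalibrationModel:
    """A monotone step function from raw to calibrated probability."""

    knots_x: np.ndarray
    knots_y: np.ndarray
    n_fit: int = 0

    def __call__(self, probs: np.ndarray) -> np.ndarray:
        p = np.asarray(probs, float)
        return np.interp(p, self.knots_x, self.knots_y)  # clamps outside the range

    def to_json(self) -> str:
        return json.dumps(
            {
                "knots_x": self.knots_x.tolist(),
                "knots_y": self.knots_y.tolist(),
                "n_fit": self.n_fit,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(np.asarray(d["knots_x"]), np.asarray(d["knots_y"]), d["n_fit"])


def sample_calibration_stays(
    stay_ids: np.ndarray, sample_fraction: float = 0.10, seed: int = 0
) -> np.ndarray:
    """Seeded stay-level sample used to fit the calibration map."""
    unique = np.unique(np.asarray(stay_ids))
    rng = np.random.default_rng(seed)
    n = max(1, int(round(sample_fraction * len(unique))))
    return rng.choice(unique, size=n, replace=False)


def fit_isotonic(
    raw_probs: np.ndarray,
    labels: np.ndarray,
    stay_ids: np.ndarray | None = None,
    sample_fraction: float = 0.10,
    seed: int = 0,
) -> CalibrationModel:
    """Fit the pool-adjacent-violators calibration map.

    When ``stay_ids`` is given, fitting uses a seeded ``sample_fraction``
    sample of stays; otherwise all points are used.
    """
    p = np.asarray(raw_probs, float)
    y = np.asarray(labels, float)
    if stay_ids is not None:
        chosen = set(sample_calibration_stays(stay_ids, sample_fraction, seed))
        keep = np.array([sid in chosen for sid in stay_ids])
        p, y = p[keep], y[keep]
    if p.size == 0:
        raise ValueError("calibration sample is empty")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(p, y)
    return CalibrationModel(
        knots_x=np.asarray(iso.X_thresholds_, float),
        knots_y=np.asarray(iso.y_thresholds_, float),
        n_fit=int(p.size),
    )


def apply_calibration(model: CalibrationModel, probs: np.ndarray) -> np.ndarray:
    return model(probs)


def brier(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared error between predicted probability and outcome."""
    p = np.asarray(probs, float)
    y = np.asarray(labels, float)
    return float(np.mean((p - y) ** 2))


def reliability_curve(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-width reliability curve: mean predicted vs observed rate.

    Empty bins are omitted (flagged via the ``n`` column of retained bins).
    """
    p = np.asarray(probs, float)
    y = np.asarray(labels, float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        rows.append(
            {
                "bin": b,
                "lo": edges[b],
                "hi": edges[b + 1],
                "mean_predicted": float(p[m].mean()),
                "observed_rate": float(y[m].mean()),
                "n": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)
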