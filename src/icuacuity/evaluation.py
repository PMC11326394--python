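"""Step- and episode-level evaluation with bootstrap confidence intervals.

Step level scores every prediction window independently. Episode level
scores each ICU admission once, by the maximum predicted probability over
eligible windows: all windows strictly before outcome onset when the
outcome occurs, or every window when it does not; admissions whose outcome
occurs in the first eligible window have no pre-onset window and are
excluded with a logged reason. Alert thresholds can be chosen to hit a
target episode-level precision (PPV), after which lead time (hours from
first super-threshold alert to onset) and alert counts are measured.

Uncertainty: stay-level bootstrap (100 iterations by default) reporting
the 2.5/50/97.5 percentiles of each metric; model comparisons use the
two-sided Wilcoxon rank-sum test on bootstrap metric distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "EpisodeRecord",
    "step_metrics",
    "threshold_metrics",
    "episode_scores",
    "episode_table",
    "precision_targeted_threshold",
    "lead_time_and_alerts",
    "bootstrap_ci",
    "compare_models",
]


@dataclass
class EpisodeRecord:
    stay_id: str
    outcome_present: int
    episode_score: float | None
    onset_window_index: int | None
    excluded: bool = False
    exclusion_reason: str | None = None


def step_metrics(probs: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """AUROC (midrank ties) and AUPRC (step integration) for one head."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("step metrics need at least one positive and one negative")
    return {
        "auroc": float(roc_auc_score(labels, probs)),
        "auprc": float(average_precision_score(labels, probs)),
    }


def threshold_metrics(
    probs: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV at a decision threshold
    (positive iff p >= threshold)."""
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(probs) >= threshold
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
    }


def episode_scores(
    stay_id: str, probs: np.ndarray, labels: np.ndarray
) -> EpisodeRecord:
    """Episode record for one stay and one outcome head.

    ``probs``/``labels`` are per-window, in window order. If the outcome
    occurs, the score is the maximum probability strictly before onset; if
    it never occurs, the maximum over all windows.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    if pos.size == 0:
        return EpisodeRecord(stay_id, 0, float(probs.max()), None)
    onset = int(pos[0])
    if onset == 0:
        return EpisodeRecord(
            stay_id, 1, None, onset, excluded=True,
            exclusion_reason="onset_in_first_window",
        )
    return EpisodeRecord(stay_id, 1, float(probs[:onset].max()), onset)


def episode_table(
    stay_ids: np.ndarray, probs: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Episode records for a cohort (one head), window order preserved."""
    frame = pd.DataFrame({"stay_id": stay_ids, "p": probs, "y": labels})
    records = []
    for sid, grp in frame.groupby("stay_id", sort=False):
        rec = episode_scores(sid, grp["p"].to_numpy(), grp["y"].to_numpy())
        records.append(vars(rec))
    return pd.DataFrame(records)


def precision_targeted_threshold(
    episodes: pd.DataFrame, target_ppv: float = 0.33
) -> float | None:
    """Smallest threshold whose episode-level PPV reaches ``target_ppv``.

    Candidate thresholds are the observed episode scores. Returns None
    (with a diagnostic warning giving the best achievable PPV) when the
    target cannot be met.
    """
    usable = episodes[~episodes["excluded"].astype(bool)]
    scores = usable["episode_score"].to_numpy(float)
    y = usable["outcome_present"].to_numpy(int)
    if y.sum() == 0:
        return None
    best_ppv = 0.0
    for thr in np.unique(scores):  # ascending => first hit is the smallest
        pred = scores >= thr
        if pred.sum() == 0:
            continue
        ppv = y[pred].sum() / pred.sum()
        best_ppv = max(best_ppv, ppv)
        if ppv >= target_ppv:
            return float(thr)
    warnings.warn(
        f"target episode PPV {target_ppv} unattainable; best achievable {best_ppv:.3f}"
    )
    return None


def lead_time_and_alerts(
    probs: np.ndarray,
    threshold: float,
    onset_window: int,
    window_hours: float = 4.0,
) -> tuple[float | None, int]:
    """Earliest lead time (hours before onset of the first alert) and the
    number of alerts for one stay with the outcome present.

    Alerts are counted over the windows up to and including the onset
    window (an alert in the onset window is a correct zero-lead
    prediction); the lead is the gap between the first alert's window and
    the onset window.
    """
    probs = np.asarray(probs, float)
    eligible = probs[: onset_window + 1]
    alerts = np.flatnonzero(eligible >= threshold)
    if alerts.size == 0:
        return None, 0
    lead = (onset_window - int(alerts[0])) * window_hours
    return float(lead), int(alerts.size)


def bootstrap_ci(
    metric_fn,
    stay_ids: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[float, float, float]:
    """Stay-level bootstrap: (median, 2.5%, 97.5%) of ``metric_fn(stays)``.

    ``metric_fn`` receives a resampled array of stay ids (with repeats) and
    returns a scalar; resamples on which it raises are redrawn (at most
    ``max_retries`` times each, logged via warning).
    """
    rng = np.random.default_rng(seed)
    unique = np.unique(np.asarray(stay_ids))
    stats = []
    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            sample = rng.choice(unique, size=len(unique), replace=True)
            try:
                stats.append(float(metric_fn(sample)))
                break
            except ValueError:
                if attempt == max_retries:
                    raise
                warnings.warn("metric undefined on a bootstrap resample; redrawing")
    lo, med, hi = np.percentile(stats, [2.5, 50.0, 97.5])
    return float(med), float(lo), float(hi)


def compare_models(samples_a, samples_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two metric samples.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and max(a.size, b.size) <= 25) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
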