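"""Plot helpers: ROC / reliability curves and per-stay risk timelines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_roc", "plot_reliability", "plot_stay_timeline"]


def plot_roc(probs, labels, path: str | Path, title: str = "ROC") -> None:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, probs)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_reliability(curve: pd.DataFrame, path: str | Path) -> None:
    """Reliability diagram from a :func:`reliability_curve` table."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.plot(curve["mean_predicted"], curve["observed_rate"], marker="o")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed rate")
    ax.set_title("Calibration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stay_timeline(
    window_starts,
    probs: dict[str, np.ndarray],
    path: str | Path,
    states: list[str] | None = None,
    event_attr: tuple[np.ndarray, np.ndarray] | None = None,
) -> None:
    """One stay's predicted risks over time.

    ``probs`` maps head names to per-window probabilities. Optionally shade
    the background by the labeled acuity state and overlay per-event
    attribution as an orange intensity strip (``event_attr`` is a pair of
    event times and attribution values).
    """
    fig, ax = plt.subplots(figsize=(7, 3))
    t = np.asarray(window_starts, float)
    state_colors = {
        "stable": "#e8f4e8", "unstable": "#fbe9e7",
        "discharge": "#e3f2fd", "deceased": "#eceff1",
    }
    if states is not None:
        for start, state in zip(t, states):
            ax.axvspan(start, start + (t[1] - t[0] if len(t) > 1 else 4.0),
                       color=state_colors.get(state, "white"), lw=0)
    for name, p in probs.items():
        ax.plot(t, p, marker=".", label=name)
    if event_attr is not None:
        times, attr = event_attr
        scale = np.max(np.abs(attr)) or 1.0
        ax.scatter(times, np.zeros_like(times), c=np.abs(attr) / scale,
                   cmap="Oranges", s=12, marker="|")
    ax.set_xlabel("hours since admission")
    ax.set_ylabel("predicted probability")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
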