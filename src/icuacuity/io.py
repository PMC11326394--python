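"""Readers/writers for cohort tables, encoded datasets, and run manifests.

Cohorts are exchanged as four long-format CSV tables plus optional
sidecars:

* ``events.csv`` — stay_id, time_hours, variable, value
* ``static.csv`` — stay_id plus one column per static feature
* ``therapies.csv`` — stay_id, therapy (MV/VP/CRRT/BT), start_hours,
  end_hours, units (units used by BT rows only)
* ``dispositions.csv`` — stay_id, disposition, disposition_time_hours
* ``sofa.csv`` (sidecar) — stay_id, window_index, sofa, baseline_sofa
* ``ground_truth.csv`` (sidecar, synthetic cohorts only) — one row per
  latent-risk knot; never consumed by the pipeline.

Every CLI stage writes a ``manifest.json`` (stage, seed, package version,
configuration hash) so a run can be reproduced from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import WindowDataset
from .records import ClinicalEvent, StayRecord, TherapyInterval
from .synthetic import SyntheticCohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "save_dataset",
    "load_dataset",
    "write_manifest",
    "config_hash",
]


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = [
        {"stay_id": s.stay_id, "time_hours": e.time_hours, "variable": e.variable, "value": e.value}
        for s in cohort.stays
        for e in s.events
    ]
    pd.DataFrame(events).to_csv(out / "events.csv", index=False)
    static = [{"stay_id": s.stay_id, **s.static} for s in cohort.stays]
    pd.DataFrame(static).to_csv(out / "static.csv", index=False)
    therapies = [
        {
            "stay_id": s.stay_id,
            "therapy": iv.therapy,
            "start_hours": iv.start_hours,
            "end_hours": iv.end_hours,
            "units": np.nan,
        }
        for s in cohort.stays
        for iv in s.therapies
    ] + [
        {
            "stay_id": s.stay_id,
            "therapy": "BT",
            "start_hours": t,
            "end_hours": t,
            "units": u,
        }
        for s in cohort.stays
        for (t, u) in s.bt_events
    ]
    pd.DataFrame(
        therapies, columns=["stay_id", "therapy", "start_hours", "end_hours", "units"]
    ).to_csv(out / "therapies.csv", index=False)
    dispositions = [
        {
            "stay_id": s.stay_id,
            "disposition": s.disposition,
            "disposition_time_hours": s.disposition_time_hours,
        }
        for s in cohort.stays
    ]
    pd.DataFrame(dispositions).to_csv(out / "dispositions.csv", index=False)
    sofa_rows = [
        {
            "stay_id": sid,
            "window_index": i,
            "sofa": int(v),
            "baseline_sofa": cohort.baseline_sofa[sid],
        }
        for sid, series in cohort.sofa.items()
        for i, v in enumerate(series)
    ]
    pd.DataFrame(sofa_rows).to_csv(out / "sofa.csv", index=False)
    gt_rows = [
        {
            "stay_id": gt.stay_id,
            "knot_hours": kh,
            "risk": r,
            "drift": gt.drift,
            "deteriorating": gt.deteriorating,
            "los_hours": gt.los_hours,
        }
        for gt in cohort.ground_truth.values()
        for kh, r in zip(gt.knot_hours, gt.risk)
    ]
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[StayRecord], dict[str, np.ndarray], dict[str, int]]:
    """Read the four cohort tables; returns (stays, sofa series, baseline sofa)."""
    src = Path(in_dir)
    for name in ("events.csv", "static.csv", "therapies.csv", "dispositions.csv"):
        if not (src / name).exists():
            raise FileNotFoundError(f"missing cohort table {src / name}")
    events = pd.read_csv(src / "events.csv")
    static = pd.read_csv(src / "static.csv")
    therapies = pd.read_csv(src / "therapies.csv")
    dispositions = pd.read_csv(src / "dispositions.csv")
    _require_columns(events, ["stay_id", "time_hours", "variable", "value"], "events.csv")
    _require_columns(dispositions, ["stay_id", "disposition", "disposition_time_hours"],
                     "dispositions.csv")
    events_by = dict(tuple(events.groupby("stay_id", sort=False)))
    therapies_by = dict(tuple(therapies.groupby("stay_id", sort=False))) if len(therapies) else {}
    static_by = static.set_index("stay_id")
    stays = []
    for row in dispositions.itertuples():
        sid = row.stay_id
        ev_frame = events_by.get(sid)
        evs = (
            [
                ClinicalEvent(float(e.time_hours), str(e.variable), float(e.value))
                for e in ev_frame.itertuples()
            ]
            if ev_frame is not None
            else []
        )
        th_frame = therapies_by.get(sid)
        ivs, bts = [], []
        if th_frame is not None:
            for t in th_frame.itertuples():
                if t.therapy == "BT":
                    bts.append((float(t.start_hours), float(t.units)))
                else:
                    ivs.append(
                        TherapyInterval(str(t.therapy), float(t.start_hours), float(t.end_hours))
                    )
        stays.append(
            StayRecord(
                stay_id=str(sid),
                events=evs,
                static={k: float(v) for k, v in static_by.loc[sid].items()},
                therapies=ivs,
                bt_events=sorted(bts),
                disposition=str(row.disposition),
                disposition_time_hours=float(row.disposition_time_hours),
            )
        )
    sofa: dict[str, np.ndarray] = {}
    baseline: dict[str, int] = {}
    sofa_path = src / "sofa.csv"
    if sofa_path.exists():
        sofa_frame = pd.read_csv(sofa_path)
        for sid, grp in sofa_frame.groupby("stay_id", sort=False):
            grp = grp.sort_values("window_index")
            sofa[str(sid)] = grp["sofa"].to_numpy(int)
            baseline[str(sid)] = int(grp["baseline_sofa"].iloc[0])
    return stays, sofa, baseline


def _require_columns(frame: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{name}: missing required columns {missing}")


def save_dataset(dataset: WindowDataset, path: str | Path) -> None:
    np.savez_compressed(
        path,
        times=dataset.times,
        values=dataset.values,
        codes=dataset.codes,
        mask=dataset.mask,
        static=dataset.static,
        labels=dataset.labels,
        label_mask=dataset.label_mask,
        stay_ids=dataset.stay_ids.astype(str),
        window_index=dataset.window_index,
        pred_start=dataset.pred_start,
        states=dataset.states.astype(str),
    )


def load_dataset(path: str | Path) -> WindowDataset:
    with np.load(path, allow_pickle=False) as z:
        return WindowDataset(
            z["times"], z["values"], z["codes"], z["mask"], z["static"],
            z["labels"], z["label_mask"], z["stay_ids"].astype(str),
            z["window_index"], z["pred_start"], z["states"].astype(str),
        )


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, stage: str, config: dict, seed: int) -> dict:
    from . import __version__

    manifest = {
        "stage": stage,
        "seed": seed,
        "package_version": __version__,
        "config": config,
        "config_hash": config_hash(config),
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
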