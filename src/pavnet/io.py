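"""File writers and readers for session artifacts.

Event trains go to CSV (neuron_id, region, stage, time_s), timelines to
JSON, continuous signals (LFP, calcium, motion) to HDF5 datasets carrying
an ``fs`` attribute.  A flat ``key = value`` config file parameterizes the
pipeline; see :func:`default_config` for the schema and defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import (
    CalciumTrace,
    EventTrain,
    LFPRecord,
    MotionTrace,
    SessionTimeline,
)


def write_events_csv(trains: list[EventTrain], path: str | Path) -> None:
    rows = [
        {"neuron_id": tr.neuron_id, "region": tr.region, "stage": tr.stage,
         "treatment": tr.treatment, "time_s": t}
        for tr in trains
        for t in tr.event_times
    ]
    pd.DataFrame(rows, columns=["neuron_id", "region", "stage", "treatment", "time_s"]).to_csv(
        path, index=False
    )


def read_events_csv(path: str | Path) -> list[EventTrain]:
    df = pd.read_csv(path)
    trains = []
    for (nid, region, stage, treatment), grp in df.groupby(
        ["neuron_id", "region", "stage", "treatment"], sort=True
    ):
        trains.append(
            EventTrain(
                neuron_id=str(nid), region=str(region), stage=str(stage),
                treatment=str(treatment),
                event_times=grp["time_s"].to_numpy(),
            )
        )
    return trains


def write_timeline_json(timeline: SessionTimeline, path: str | Path) -> None:
    obj = {
        "session_length": timeline.session_length,
        "cs_duration": timeline.cs_duration,
        "cs_trials": [[t, typ] for t, typ in timeline.cs_trials],
        "us_events": [[t, typ] for t, typ in timeline.us_events],
        "behavior_episodes": [[t, k] for t, k in timeline.behavior_episodes],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_timeline_json(path: str | Path) -> SessionTimeline:
    obj = json.loads(Path(path).read_text())
    return SessionTimeline(
        cs_trials=[(float(t), str(ty)) for t, ty in obj["cs_trials"]],
        us_events=[(float(t), str(ty)) for t, ty in obj["us_events"]],
        behavior_episodes=[(float(t), str(k)) for t, k in obj["behavior_episodes"]],
        session_length=float(obj["session_length"]),
        cs_duration=float(obj.get("cs_duration", 10.0)),
    )


def write_signals_h5(
    path: str | Path,
    lfps: dict[str, LFPRecord] | None = None,
    calcium: list[CalciumTrace] | None = None,
    motion: MotionTrace | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        if lfps:
            g = f.create_group("lfp")
            for region, rec in lfps.items():
                d = g.create_dataset(region, data=rec.samples, track_times=False)
                d.attrs["fs"] = rec.fs
        if calcium:
            g = f.create_group("calcium")
            for tr in calcium:
                d = g.create_dataset(tr.trace_id or f"trace_{id(tr)}", data=tr.dff, track_times=False)
                d.attrs["fs"] = tr.fs
        if motion is not None:
            d = f.create_dataset("motion", data=motion.motion, track_times=False)
            d.attrs["fs"] = motion.fs


def read_signals_h5(path: str | Path):
    lfps: dict[str, LFPRecord] = {}
    calcium: list[CalciumTrace] = []
    motion = None
    with h5py.File(path, "r") as f:
        for region, d in f.get("lfp", {}).items():
            lfps[region] = LFPRecord(region=region, samples=d[...], fs=float(d.attrs["fs"]))
        for tid, d in f.get("calcium", {}).items():
            calcium.append(CalciumTrace(dff=d[...], fs=float(d.attrs["fs"]), trace_id=tid))
        if "motion" in f:
            motion = MotionTrace(motion=f["motion"][...], fs=float(f["motion"].attrs["fs"]))
    return lfps, calcium, motion


def parse_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config; '#' starts a comment, blanks ignored."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def default_config() -> dict[str, str]:
    """Schema and defaults of the pipeline config (all values strings)."""
    return {
        "seed": "0",
        "out_dir": "pipeline_out",
        "session_length": "600",
        "n_trials_per_cs": "6",
        "n_aIC": "20", "n_pIC": "20", "n_CE_SST": "10", "n_CE_PKCd": "10", "n_CEm": "8",
        "baseline_rate": "0.2",
        "cs_amp": "3.0",          # CS rate multiplier at the recall stage
        "behavior_correct_prob": "0.8",
        "coupling_excess": "0.35",  # aIC -> CE_SST lag-1 coupling
        "lfp_freq": "33", "lfp_amp": "1.0", "lfp_kappa": "4.0",
        "motion_threshold": "0.5",
        "decode_n_neurons": "15", "decode_repeats": "5",
        "te_n_draw": "40", "te_n_surr": "100", "te_alpha": "0.05",
        "sfc_window": "0.2",
    }


def format_config(cfg: dict[str, str]) -> str:
    return "\n".join(f"{k} = {v}" for k, v in cfg.items()) + "\n"
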