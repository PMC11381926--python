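"""Readers and writers for the pipeline's on-disk formats.

Traces travel as CSV (rows = time, columns = neuron ids, index = seconds),
trial structures as JSON, session configs as YAML/JSON, movies as
multi-page grayscale TIFF with 16-bit label-mask TIFFs, and event /
modulation tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .events import EventTrain
from .extraction import ROISet, TraceMatrix
from .session import SessionConfig, TrialStructure

__all__ = [
    "write_traces_csv", "read_traces_csv",
    "write_trials_json", "read_trials_json",
    "read_session_config",
    "write_movie_tiff", "read_movie_tiff",
    "write_mask_tiff", "read_mask_tiff",
    "events_table", "write_events_csv",
    "save_session",
]


def write_traces_csv(path, traces: TraceMatrix) -> None:
    df = pd.DataFrame(
        traces.values.T,
        index=pd.Index(traces.timestamps, name="time_s"),
        columns=[str(i) for i in traces.neuron_ids],
    )
    df.to_csv(path)


def read_traces_csv(path, fs: float = 20.0, stage: str = "dff") -> TraceMatrix:
    df = pd.read_csv(path, index_col=0)
    return TraceMatrix(
        values=df.to_numpy().T,
        fs=fs,
        timestamps=df.index.to_numpy(dtype=float),
        stage=stage,
        neuron_ids=np.asarray([int(c) for c in df.columns]),
    )


def write_trials_json(path, trials: TrialStructure) -> None:
    payload = {
        "us_onsets": trials.us_onsets.tolist(),
        "prf_per_trial": trials.prf_per_trial.tolist(),
        "us_s": trials.us_s,
        "pre_s": trials.pre_s,
        "post_s": trials.post_s,
        "pause_s": trials.pause_s,
        "session_duration_s": trials.session_duration_s,
        "fs": trials.fs,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_trials_json(path) -> TrialStructure:
    payload = json.loads(Path(path).read_text())
    return TrialStructure(
        us_onsets=np.asarray(payload["us_onsets"], float),
        prf_per_trial=np.asarray(payload["prf_per_trial"], float),
        us_s=payload["us_s"],
        pre_s=payload["pre_s"],
        post_s=payload["post_s"],
        pause_s=payload.get("pause_s", 0.5),
        session_duration_s=payload["session_duration_s"],
        fs=payload["fs"],
    )


def read_session_config(path) -> SessionConfig:
    """Session config from YAML or JSON mapping of SessionConfig fields."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    for key in ("prf_set", "evoked_latency_s"):
        if key in data:
            data[key] = tuple(data[key])
    return SessionConfig(**data)


def write_movie_tiff(path, movie: np.ndarray) -> None:
    tifffile.imwrite(
        path, np.asarray(movie, dtype=np.float32), photometric="minisblack"
    )


def read_movie_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_mask_tiff(path, rois: ROISet) -> None:
    tifffile.imwrite(path, np.asarray(rois.label_mask, dtype=np.uint16))


def read_mask_tiff(path, **kwargs) -> ROISet:
    return ROISet(label_mask=tifffile.imread(path).astype(np.int64), **kwargs)


def events_table(trains: dict) -> pd.DataFrame:
    """Tidy event table (neuron, rise_start_s, peak_s, rise_time_s,
    amplitude) from a mapping neuron id -> EventTrain."""
    rows = []
    for nid, train in trains.items():
        for e in train.events:
            rows.append({
                "neuron": nid,
                "rise_start_s": e.rise_start_s,
                "peak_s": e.peak_s,
                "rise_time_s": e.rise_time_s,
                "amplitude": e.amplitude,
            })
    return pd.DataFrame(rows)


def write_events_csv(path, trains: dict) -> None:
    events_table(trains).to_csv(path, index=False)


def save_session(out_dir, traces, trials, truth=None) -> None:
    """Write a simulated session: traces.csv, trials.json and, when ground
    truth is given, a ground_truth.json manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_traces_csv(out / "traces.csv", traces)
    write_trials_json(out / "trials.json", trials)
    if truth is not None:
        manifest = {
            "preferred_prf": [
                None if not np.isfinite(v) else float(v) for v in truth.preferred_prf
            ],
            "event_times": [t.tolist() for t in truth.event_times],
            "rise_durations": [r.tolist() for r in truth.rise_durations],
            "evoked": [e.astype(int).tolist() for e in truth.evoked],
            "pv_label": truth.pv_label.astype(int).tolist()
            if truth.pv_label is not None else None,
        }
        (out / "ground_truth.json").write_text(json.dumps(manifest))
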