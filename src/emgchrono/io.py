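"""Readers/writers for the pipeline's artifact formats.

Analysis tables travel as CSV, events as TSV, configuration as YAML, epochs
as one binary array file (.npy, float32) plus a JSON sidecar holding the
time base, sampling rate and per-epoch metadata.  Continuous recordings are
read from a CSV sample matrix (one column per channel) or an .npy array,
paired with an events TSV (onset_ms, type, trial_index).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import (
    DetectionConfig,
    GenerativeParams,
    generative_params_from_dict,
)
from .preprocessing import EmgEpoch, Recording

EVENT_TYPES = ("stimulus", "press_left", "press_right")


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        v = float(value)
        return None if np.isnan(v) else v
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, float) and np.isnan(value):
        return None
    return value


def write_epochs(epochs: list[EmgEpoch], directory, stem: str = "epochs") -> Path:
    """Write epochs as <stem>.npy (n, 2, T float32) + <stem>.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not epochs:
        raise ValueError("no epochs to write")
    data = np.stack([e.samples for e in epochs]).astype(np.float32)
    np.save(directory / f"{stem}.npy", data)
    sidecar = {
        "sampling_rate": epochs[0].sampling_rate,
        "t0_ms": epochs[0].t0_ms,
        "channels": ["response", "non_response"],
        "epochs": [
            {
                "press_time_ms": _jsonable(e.press_time_ms),
                "meta": {k: _jsonable(v) for k, v in e.meta.items()},
            }
            for e in epochs
        ],
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return directory / f"{stem}.npy"


def read_epochs(directory, stem: str = "epochs") -> list[EmgEpoch]:
    directory = Path(directory)
    data = np.load(directory / f"{stem}.npy")
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    if data.shape[0] != len(sidecar["epochs"]):
        raise ValueError("epoch array and sidecar disagree on epoch count")
    return [
        EmgEpoch(
            data[i].astype(float),
            sidecar["sampling_rate"],
            t0_ms=sidecar["t0_ms"],
            press_time_ms=entry["press_time_ms"],
            meta=dict(entry["meta"]),
        )
        for i, entry in enumerate(sidecar["epochs"])
    ]


def read_events(path) -> pd.DataFrame:
    """Events TSV with onset_ms, type, trial_index; validated row by row."""
    ev = pd.read_csv(path, sep="\t")
    required = ["onset_ms", "type", "trial_index"]
    missing = [c for c in required if c not in ev.columns]
    if missing:
        raise ValueError(f"events file {path} missing columns {missing}")
    bad = ~ev["type"].isin(EVENT_TYPES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"events file {path}: unknown event type {ev['type'].iloc[row]!r} "
            f"in row {row}"
        )
    # a press must follow its trial's stimulus
    stim = ev[ev["type"] == "stimulus"].set_index("trial_index")["onset_ms"]
    presses = ev[ev["type"] != "stimulus"]
    for row, press in presses.iterrows():
        t0 = stim.get(press["trial_index"])
        if t0 is not None and press["onset_ms"] <= t0:
            raise ValueError(
                f"events file {path}: press before stimulus in row {row} "
                f"(trial {press['trial_index']})"
            )
    return ev


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_recording(path, events_path, sampling_rate: float = 1000.0,
                   channel_names: tuple[str, ...] = ("left", "right")) -> Recording:
    """Load a continuous recording from a CSV sample matrix (columns =
    channels) or an .npy array of shape (n_channels, T), plus its events TSV.
    """
    path = Path(path)
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        frame = pd.read_csv(path)
        channel_names = tuple(frame.columns)
        data = frame.to_numpy(dtype=float).T
    events = read_events(events_path)
    return Recording(data, sampling_rate, channel_names, events)


def write_recording(recording: Recording, path, events_path) -> None:
    pd.DataFrame(recording.data.T, columns=list(recording.channel_names)).to_csv(
        path, index=False
    )
    write_events(recording.events, events_path)


@dataclass
class RunConfig:
    """Resolved pipeline configuration."""

    out_dir: str = "emgchrono_out"
    seed: int = 0
    n_participants: int = 4
    stages: tuple[str, ...] = ("simulate", "detect", "fractionate", "caf", "fit")
    fit_measures: tuple[str, ...] = ("pmt", "mt", "rt")
    log_level: str = "INFO"
    review_dir: str | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    generative: GenerativeParams = field(default_factory=GenerativeParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["fit_measures"] = list(self.fit_measures)
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    kwargs: dict = {}
    if "detection" in raw:
        kwargs["detection"] = DetectionConfig(**raw.pop("detection"))
    if "generative" in raw:
        kwargs["generative"] = generative_params_from_dict(raw.pop("generative"))
    allowed = {"out_dir", "seed", "n_participants", "stages", "fit_measures",
               "log_level", "review_dir"}
    for key in list(raw):
        if key not in allowed:
            raise ValueError(f"unknown config key {key!r}")
        value = raw.pop(key)
        if key in ("stages", "fit_measures"):
            value = tuple(value)
        kwargs[key] = value
    return RunConfig(**kwargs)


def write_resolved_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
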