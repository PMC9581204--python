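"""Reading and writing the package's delimited text artifacts.

Recordings travel as long-format tables (valve_id, grade, co_lpm, channel,
time_s, value), peak datasets as one-row-per-cell tables, fitted parameters
and configs as small YAML key-value files.  Everything is plain text so
runs are diffable and portable.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .models import ModelParams, ValveDataset
from .signals import DAQ_CHANNELS, SignalRecording
from .synthetic import GroundTruth, SyntheticConfig

__all__ = [
    "recordings_to_frame", "frame_to_recordings",
    "write_peak_table", "read_peak_table",
    "write_params", "read_params",
    "write_config", "read_config",
]


def recordings_to_frame(recordings: Sequence[SignalRecording]) -> pd.DataFrame:
    """Long-format table of every channel of every recording."""
    parts = []
    for rec in recordings:
        for name in DAQ_CHANNELS:
            x = np.asarray(rec.channels[name])
            parts.append(pd.DataFrame({
                "valve_id": rec.valve_id, "grade": rec.grade,
                "co_lpm": rec.co_lpm, "channel": name,
                "time_s": np.arange(len(x)) / rec.daq_rate, "value": x,
                "lvot_area_mm2": rec.lvot_area_mm2,
                "piston_area_cm2": rec.piston_area_cm2,
                "hr_bpm": rec.hr_bpm,
            }))
        a = np.asarray(rec.ava_series)
        parts.append(pd.DataFrame({
            "valve_id": rec.valve_id, "grade": rec.grade,
            "co_lpm": rec.co_lpm, "channel": "ava",
            "time_s": np.arange(len(a)) / rec.camera_rate, "value": a,
            "lvot_area_mm2": rec.lvot_area_mm2,
            "piston_area_cm2": rec.piston_area_cm2,
            "hr_bpm": rec.hr_bpm,
        }))
    return pd.concat(parts, ignore_index=True)


def frame_to_recordings(frame: pd.DataFrame) -> list[SignalRecording]:
    """Rebuild recordings from the long-format table (rates inferred from
    the time column)."""
    recs = []
    for (valve, grade, co), cell in frame.groupby(
            ["valve_id", "grade", "co_lpm"], sort=True):
        channels = {}
        rates = {}
        for name, sub in cell.groupby("channel"):
            sub = sub.sort_values("time_s")
            channels[name] = sub["value"].to_numpy()
            dt = np.diff(sub["time_s"].to_numpy()[:2])
            rates[name] = 1.0 / dt[0]
        ava = channels.pop("ava")
        meta = cell.iloc[0]
        recs.append(SignalRecording(
            valve_id=str(valve), grade=str(grade), co_lpm=float(co),
            daq_rate=round(rates["pump_position"]),
            camera_rate=round(rates["ava"]),
            channels=channels, ava_series=ava,
            lvot_area_mm2=float(meta["lvot_area_mm2"]),
            piston_area_cm2=float(meta["piston_area_cm2"]),
            hr_bpm=float(meta.get("hr_bpm", 60.0)),
        ))
    return recs


def write_peak_table(dataset: ValveDataset, path: str | Path) -> None:
    dataset.points.to_csv(path, index=False)


def read_peak_table(path: str | Path) -> ValveDataset:
    return ValveDataset(points=pd.read_csv(path))


def write_params(params: ModelParams, path: str | Path,
                 diagnostics: dict | None = None) -> None:
    payload = params.to_dict()
    if diagnostics:
        payload["diagnostics"] = diagnostics
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_params(path: str | Path) -> ModelParams:
    d = yaml.safe_load(Path(path).read_text())
    return ModelParams(kind=d["kind"], theta=tuple(d["theta"]),
                       linear_form=d.get("linear_form", "ratio"))


def _plain(obj):
    """Recursively convert numpy scalars/containers to built-in types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_config(config: SyntheticConfig, truth: GroundTruth,
                 path: str | Path) -> None:
    payload = {"config": asdict(config), "truth": asdict(truth)}
    payload["config"]["delays_ms"] = dict(config.delays_ms)
    payload["truth"]["s_star_per_grade"] = dict(truth.s_star_per_grade)
    Path(path).write_text(yaml.safe_dump(_plain(payload), sort_keys=False))


def read_config(path: str | Path) -> tuple[SyntheticConfig, GroundTruth]:
    d = yaml.safe_load(Path(path).read_text())
    cfg = d.get("config", {})
    for key in ("grades", "cardiac_outputs"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    truth = d.get("truth", {})
    if "theta_star" in truth:
        truth["theta_star"] = tuple(truth["theta_star"])
    return SyntheticConfig(**cfg), GroundTruth(**truth)
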