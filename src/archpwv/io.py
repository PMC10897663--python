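"""Plain-text I/O: waveform CSV + JSON sidecar, point-set CSV, lengths CSV,
and mock-loop config files (JSON or YAML)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mockloop import MockLoopConfig, PlanarPointSet, WaveformRecord

__all__ = [
    "write_waveform", "read_waveform",
    "write_point_set", "read_point_set",
    "write_lengths", "read_lengths",
    "save_config", "load_config",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_waveform(record: WaveformRecord, csv_path, seed: int | None = None) -> Path:
    """Two-column ``time_s,value`` CSV plus a JSON sidecar of metadata."""
    csv_path = Path(csv_path)
    t = np.arange(record.values.size) / record.sampling_rate_hz
    pd.DataFrame({"time_s": t, "value": record.values}).to_csv(
        csv_path, index=False)
    meta = {
        "site": record.site,
        "channel": record.channel,
        "units": record.units,
        "sampling_rate_hz": record.sampling_rate_hz,
        "heart_rate_bpm": record.heart_rate_bpm,
    }
    if seed is not None:
        meta["seed"] = int(seed)
    with open(_sidecar_path(csv_path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return csv_path


def read_waveform(csv_path) -> WaveformRecord:
    csv_path = Path(csv_path)
    with open(_sidecar_path(csv_path)) as fh:
        meta = json.load(fh)
    df = pd.read_csv(csv_path)
    return WaveformRecord(site=meta["site"], channel=meta["channel"],
                          sampling_rate_hz=float(meta["sampling_rate_hz"]),
                          heart_rate_bpm=float(meta["heart_rate_bpm"]),
                          values=df["value"].to_numpy())


def write_point_set(point_set: PlanarPointSet, csv_path) -> Path:
    """Ordered ``x_px,y_px`` rows; header comments carry scale and pressure."""
    csv_path = Path(csv_path)
    seg = [repr(float(v)) for v in point_set.scale_segment_px.ravel()]
    lines = [
        f"# scale_segment_px={','.join(seg)}",
        f"# scale_length_cm={float(point_set.scale_length_cm)!r}",
        f"# pressure_mmhg={float(point_set.pressure_mmhg)!r}",
        "x_px,y_px",
    ]
    lines += [f"{float(x)!r},{float(y)!r}" for x, y in point_set.points_px]
    csv_path.write_text("\n".join(lines) + "\n")
    return csv_path


def read_point_set(csv_path) -> PlanarPointSet:
    csv_path = Path(csv_path)
    meta = {}
    for line in csv_path.read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
    df = pd.read_csv(csv_path, comment="#")
    seg_vals = [float(v) for v in meta["scale_segment_px"].split(",")]
    return PlanarPointSet(
        points_px=df[["x_px", "y_px"]].to_numpy(),
        scale_segment_px=np.array(seg_vals).reshape(2, 2),
        pressure_mmhg=float(meta["pressure_mmhg"]),
        scale_length_cm=float(meta.get("scale_length_cm", 2.5)))


def write_lengths(pairs, csv_path) -> Path:
    """Lengths CSV ``pressure_mmhg,length_cm``."""
    csv_path = Path(csv_path)
    pd.DataFrame(pairs, columns=["pressure_mmhg", "length_cm"]).to_csv(
        csv_path, index=False)
    return csv_path


def read_lengths(csv_path) -> list:
    df = pd.read_csv(csv_path)
    return list(df[["pressure_mmhg", "length_cm"]].itertuples(index=False,
                                                              name=None))


def save_config(config: MockLoopConfig, path) -> Path:
    """Serialize a config as JSON or YAML (by extension), schema-versioned."""
    path = Path(path)
    payload = {"schema_version": 1, **dataclasses.asdict(config)}
    payload["pressure_windows_mmhg"] = {
        k: list(v) for k, v in payload["pressure_windows_mmhg"].items()}
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))
    return path


def load_config(path) -> MockLoopConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    payload.pop("schema_version", None)
    payload["pressure_windows_mmhg"] = {
        k: tuple(v) for k, v in payload["pressure_windows_mmhg"].items()}
    return MockLoopConfig(**payload)
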