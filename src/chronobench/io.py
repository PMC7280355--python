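"""Readers and writers for the package's plain-text interchange formats.

Sensor traces and tabular outputs are headered UTF-8 CSV ('.' decimal,
times in ms); device profiles and mixture fits are JSON.  All writers are
byte-stable for a given seed: no timestamps, fixed float formatting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emulator import DeviceProfile, FrameDist, SensorTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_table_csv",
    "read_table_csv",
    "profile_to_dict",
    "profile_from_dict",
    "write_profile_json",
    "read_profile_json",
    "write_json",
]

_FLOAT_FORMAT = "%.6f"


def write_trace_csv(trace: SensorTrace, path) -> None:
    df = pd.DataFrame({"time_ms": trace.time_ms, "luminance": trace.luminance})
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_trace_csv(path) -> SensorTrace:
    df = pd.read_csv(path)
    if not {"time_ms", "luminance"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_ms,luminance")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: trace too short")
    sample_hz = 1000.0 / float(np.median(np.diff(t)))
    return SensorTrace(time_ms=t, luminance=df["luminance"].to_numpy(dtype=float),
                       sample_hz=sample_hz)


def write_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_table_csv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _dist_key_to_str(key) -> str:
    if key == "default":
        return "default"
    return "|".join(str(part) for part in key)


def _dist_key_from_str(s: str):
    if s == "default":
        return "default"
    parts = s.split("|")
    if len(parts) == 3:
        return (parts[0], parts[1], int(parts[2]))
    return tuple(parts)


def profile_to_dict(profile: DeviceProfile) -> dict:
    d = dataclasses.asdict(profile)
    d["frame_diff_dist"] = {
        _dist_key_to_str(k): {str(s): p for s, p in v.as_dict().items()}
        for k, v in profile.frame_diff_dist.items()
    }
    d["internal_error_dists"] = {
        k: {str(s): p for s, p in v.as_dict().items()}
        for k, v in profile.internal_error_dists.items()
    }
    return d


def profile_from_dict(d: dict) -> DeviceProfile:
    d = dict(d)
    d["frame_diff_dist"] = {
        _dist_key_from_str(k): FrameDist.from_dict({int(s): p for s, p in v.items()})
        for k, v in d.get("frame_diff_dist", {}).items()
    }
    d["internal_error_dists"] = {
        k: FrameDist.from_dict({int(s): p for s, p in v.items()})
        for k, v in d.get("internal_error_dists", {}).items()
    }
    d["rt_offset_mix"] = tuple(d.get("rt_offset_mix", (0.0, 0.0, 0.0)))
    profile = DeviceProfile(**d)
    profile.validate()
    return profile


def write_profile_json(profile: DeviceProfile, path) -> None:
    write_json(profile_to_dict(profile), path)


def read_profile_json(path) -> DeviceProfile:
    with open(path, "r", encoding="utf-8") as fh:
        return profile_from_dict(json.load(fh))


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
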