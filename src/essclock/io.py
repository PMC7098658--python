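"""Timeseries CSV serialisation and run manifests.

Timeseries files are plain CSV with a ``time_h`` column, one column per
component, and an optional ``light`` annotation column; round trips preserve
full float precision.  Every artefact-producing CLI command writes a run
manifest (command, configs, seed, version, timestamp, outputs) alongside its
outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Timeseries


def write_timeseries(ts: Timeseries, path) -> None:
    ts.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path) -> Timeseries:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: missing 'time_h' column")
    if df.isna().any().any():
        raise ValueError(f"{path}: NaN cells in timeseries")
    time = df["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError(f"{path}: non-monotone time column")
    light = df["light"].to_numpy(dtype=float) if "light" in df.columns else None
    labels = [c for c in df.columns if c not in ("time_h", "light")]
    if not labels:
        raise ValueError(f"{path}: no component columns")
    return Timeseries(time, df[labels].to_numpy(dtype=float), labels, None, light)


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None
    outputs: list[str]
    tool: str = "essclock"
    version: str = field(default="")
    timestamp: str = field(default="")

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2, default=str) + "\n")
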