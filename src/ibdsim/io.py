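"""Result serialization: trajectory CSV (long format) with a JSON metadata
sidecar, and CSV/JSON writers for the metric reports.

All writers are deterministic (no timestamps, fixed float formatting,
sorted JSON keys), so reruns with an unchanged configuration reproduce
outputs byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .simulate import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_frame",
    "write_json",
]

_FLOAT_FMT = "%.10g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> Path:
    """Write a trajectory as long CSV (time, compartment, value) plus a
    ``<name>.csv.meta.json`` sidecar with the run metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_frame(long=True).to_csv(path, index=False, float_format=_FLOAT_FMT)
    write_json(traj.metadata, _sidecar(path))
    return path


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return Trajectory.from_frame(df, metadata=meta)


def write_frame(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_json(obj, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path
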