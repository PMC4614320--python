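"""Trace and grid writers with metadata sidecars.

Every artifact is a delimited (CSV) table plus a ``<name>.meta.json``
sidecar carrying the seed, a parameter echo and the package version —
enough to regenerate the artifact bit-identically.  Writes are byte-stable
for identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .results import DisabilityTrace, MAoDGrid

__all__ = ["write_trace", "read_trace", "write_grid", "read_grid"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__dataclass__": type(obj).__name__, **_jsonable(dataclasses.asdict(obj))}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_sidecar(path: Path, payload: dict) -> None:
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    payload = {"version": __version__, **payload}
    sidecar.write_text(json.dumps(_jsonable(payload), sort_keys=True, indent=1) + "\n")


def write_trace(trace: DisabilityTrace, path) -> Path:
    """Write a disability trace as CSV plus a metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(path, index=False)
    _write_sidecar(path, {"kind": "trace", "meta": trace.meta, "events": trace.events})
    return path


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_grid(grid: MAoDGrid, path) -> Path:
    """Write a MAoD grid: long-format per-replicate CSV, a per-cell summary
    CSV alongside it, and a metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid.to_frame().to_csv(path, index=False)
    summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    grid.summary_frame().to_csv(summary_path, index=False)
    _write_sidecar(
        path,
        {
            "kind": "grid",
            "meta": grid.meta,
            "axis1_name": grid.axis1_name,
            "axis2_name": grid.axis2_name,
            "n_seeds": grid.n_seeds,
        },
    )
    return path


def read_grid(path) -> pd.DataFrame:
    return pd.read_csv(path)
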