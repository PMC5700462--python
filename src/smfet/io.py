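"""Readers and writers for the package's delimited-text and HDF5 formats.

Formats:

* traces — 2-column TSV with header ``time_ms\tcurrent_nA``; optionally an
  HDF5 container (``/trace/values``, ``/trace/dt_ms``, metadata as attributes)
* idealized paths — 3-column TSV ``state\tstart_ms\tduration_ms``
* dwell tables — TSV ``state\tduration_ms\tnext_state``
* melting curves — 2-column TSV ``temp_C\tabs_norm``
* kinetic matrices / occupancy tables — JSON reports
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .kinetics import DwellRecord, KineticMatrix, OccupancyTable
from .models import MeltingCurve, ParameterError, StatePath, Trace


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            g = f.create_group("trace")
            g.create_dataset("values", data=trace.values)
            g.create_dataset("dt_ms", data=trace.dt)
            for k, v in trace.metadata.items():
                g.attrs[k] = v
        return
    # full (shortest-roundtrip) precision so a written-then-reread trace
    # reproduces the in-memory analysis bit for bit
    pd.DataFrame({"time_ms": trace.times, "current_nA": trace.values}).to_csv(
        path, sep="\t", index=False
    )


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            g = f["trace"]
            return Trace(
                dt=float(g["dt_ms"][()]),
                values=np.asarray(g["values"]),
                metadata=dict(g.attrs),
            )
    df = pd.read_csv(path, sep="\t")
    if not {"time_ms", "current_nA"} <= set(df.columns):
        raise ParameterError(f"{path}: expected columns time_ms and current_nA")
    t = df["time_ms"].to_numpy()
    if t.size < 2:
        raise ParameterError(f"{path}: trace too short")
    return Trace(dt=float(np.median(np.diff(t))), values=df["current_nA"].to_numpy())


def write_state_path(path_obj: StatePath, path: str | Path) -> None:
    starts = np.concatenate([[0.0], np.cumsum(path_obj.durations[:-1])])
    pd.DataFrame(
        {"state": path_obj.states, "start_ms": starts, "duration_ms": path_obj.durations}
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_state_path(path: str | Path) -> StatePath:
    df = pd.read_csv(path, sep="\t")
    return StatePath(states=df["state"].tolist(), durations=df["duration_ms"].to_numpy())


def write_dwells(dwells: Sequence[DwellRecord], path: str | Path) -> None:
    pd.DataFrame(dwells, columns=["state", "duration_ms", "next_state"]).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_dwells(path: str | Path) -> list[DwellRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DwellRecord(r.state, float(r.duration_ms), r.next_state)
        for r in df.itertuples(index=False)
    ]


def write_melting_curve(curve: MeltingCurve, path: str | Path) -> None:
    pd.DataFrame({"temp_C": curve.temperatures, "abs_norm": curve.absorbance}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_melting_curve(path: str | Path) -> MeltingCurve:
    df = pd.read_csv(path, sep="\t")
    return MeltingCurve(
        temperatures=df["temp_C"].to_numpy(), absorbance=df["abs_norm"].to_numpy()
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def occupancy_report(table: OccupancyTable) -> dict:
    return {"percent": table.rounded(1), "total_time_ms": round(table.total_time, 3)}


def kinetic_report(matrix: KineticMatrix) -> dict:
    return matrix.to_dict()
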