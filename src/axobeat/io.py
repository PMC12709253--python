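"""Plain-text I/O: centerline CSV, tangent-field CSV + JSON sidecar, summary tables.

Centerline CSV dialect: columns ``frame, point_index, x_um, y_um, t_s``,
one header line, points ordered base → tip within each frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputDataError
from .geometry import CenterlineSeries, TangentField

__all__ = [
    "write_centerlines_csv",
    "read_centerlines_csv",
    "write_tangent_field",
    "read_tangent_field",
]

CENTERLINE_COLUMNS = ["frame", "point_index", "x_um", "y_um", "t_s"]


def write_centerlines_csv(series: CenterlineSeries, path: str | Path) -> None:
    chunks = []
    for i, xy in enumerate(series.frames):
        chunks.append(
            pd.DataFrame(
                {
                    "frame": i,
                    "point_index": np.arange(xy.shape[0]),
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                    "t_s": series.times_s[i],
                }
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)


def read_centerlines_csv(path: str | Path) -> CenterlineSeries:
    df = pd.read_csv(path)
    missing = set(CENTERLINE_COLUMNS) - set(df.columns)
    if missing:
        raise InputDataError(f"centerline CSV missing columns: {sorted(missing)}")
    frames, times = [], []
    for frame_id, g in df.groupby("frame", sort=True):
        g = g.sort_values("point_index")
        frames.append(g[["x_um", "y_um"]].to_numpy(dtype=float))
        t = g["t_s"].unique()
        if t.size != 1:
            raise InputDataError(f"frame {frame_id}: inconsistent timestamps")
        times.append(float(t[0]))
    return CenterlineSeries(frames=frames, times_s=np.asarray(times))


def write_tangent_field(field: TangentField, csv_path: str | Path) -> None:
    """CSV matrix (rows = s, columns = t) plus a JSON sidecar with grid metadata."""
    csv_path = Path(csv_path)
    pd.DataFrame(field.psi).to_csv(csv_path, index=False, header=False)
    sidecar = {
        "s0_um": float(field.s_um[0]),
        "ds_um": field.ds_um,
        "n_s": int(field.s_um.size),
        "t0_s": float(field.t_s[0]),
        "dt_s": field.dt_s,
        "n_t": int(field.t_s.size),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_tangent_field(csv_path: str | Path) -> TangentField:
    csv_path = Path(csv_path)
    psi = pd.read_csv(csv_path, header=None).to_numpy(dtype=float)
    m = json.loads(csv_path.with_suffix(".json").read_text())
    s = m["s0_um"] + np.arange(m["n_s"]) * m["ds_um"]
    t = m["t0_s"] + np.arange(m["n_t"]) * m["dt_s"]
    return TangentField(psi=psi, s_um=s, t_s=t)
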