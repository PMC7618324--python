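"""CSV/JSON interchange for creep records, contours and droplet series.

Shared schemas:

* creep CSV: ``time_s, force_nN, indentation_um, phase`` (one file per
  experiment; the bead radius travels in the JSON sidecar or argument).
* contour CSV: ``frame, boundary, point_index, x_um, y_um`` with boundary in
  {inner, outer, droplet}.
* fits/stats: plain JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .afm_rheology import CreepRecord
from .droplet_analysis import DropletSeries
from .tissue_shape import CrossSectionContours

__all__ = [
    "write_creep_csv", "read_creep_csv",
    "write_contours_csv", "read_contours_csv",
    "write_droplet_csv", "read_droplet_csv",
    "write_json", "read_json",
]


def write_creep_csv(rec: CreepRecord, path) -> None:
    rec.to_frame().to_csv(path, index=False)


def read_creep_csv(path, bead_radius_um: float, meta: dict | None = None) -> CreepRecord:
    return CreepRecord.from_frame(pd.read_csv(path), bead_radius_um, meta)


def write_contours_csv(section: CrossSectionContours, path, frame: int = 0) -> None:
    rows = []
    for boundary, pts in (("inner", section.inner), ("outer", section.outer)):
        for i, (x, y) in enumerate(pts):
            rows.append((frame, boundary, i, x, y))
    pd.DataFrame(rows, columns=["frame", "boundary", "point_index",
                                "x_um", "y_um"]).to_csv(path, index=False)


def read_contours_csv(path, meta: dict | None = None) -> CrossSectionContours:
    df = pd.read_csv(path)
    parts = {}
    for boundary in ("inner", "outer"):
        sub = df[df["boundary"] == boundary].sort_values("point_index")
        if sub.empty:
            raise ValueError(f"contour CSV is missing the {boundary!r} boundary")
        parts[boundary] = sub[["x_um", "y_um"]].to_numpy(float)
    return CrossSectionContours(inner=parts["inner"], outer=parts["outer"],
                                meta=dict(meta or {}))


def write_droplet_csv(series: DropletSeries, path) -> None:
    rows = []
    for f, (t, contour) in enumerate(zip(series.times_h, series.contours)):
        for i, (x, y) in enumerate(contour):
            rows.append((f, t, "droplet", i, x, y))
    pd.DataFrame(rows, columns=["frame", "time_h", "boundary", "point_index",
                                "x_um", "y_um"]).to_csv(path, index=False)


def read_droplet_csv(path) -> DropletSeries:
    df = pd.read_csv(path)
    times, contours = [], []
    for f, sub in df.groupby("frame"):
        sub = sub.sort_values("point_index")
        times.append(float(sub["time_h"].iloc[0]))
        contours.append(sub[["x_um", "y_um"]].to_numpy(float))
    order = np.argsort(times)
    return DropletSeries.from_contours([times[i] for i in order],
                                       [contours[i] for i in order])


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return super().default(obj)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder,
                                     allow_nan=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
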