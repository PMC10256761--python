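"""Delimited-text readers and writers.

Formats:

* single series CSV — columns ``time,w,x,y,z``;
* long-format dataset CSV — ``series_id,time,w,x,y,z`` plus a separate
  labels CSV with ``series_id,label``;
* tangent-series CSV — ``time,v1,v2,v3`` preceded by one ``#`` metadata
  line recording the kind, the step and the anchor quaternion;
* DTW distance-matrix CSV cache.

Readers normalize quaternions on load and sign-align by default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .classification import LabeledDataset
from .quaternions import QuaternionSeries, sign_align
from .transforms import TangentSeries

__all__ = [
    "read_dataset",
    "read_series_csv",
    "read_tangent_csv",
    "write_dataset",
    "write_series_csv",
    "write_tangent_csv",
]

PathLike = Union[str, Path]


def write_series_csv(path: PathLike, s: QuaternionSeries) -> None:
    df = pd.DataFrame(s.q, columns=["w", "x", "y", "z"])
    df.insert(0, "time", s.times)
    df.to_csv(path, index=False)


def read_series_csv(path: PathLike, *, align: bool = True) -> QuaternionSeries:
    df = pd.read_csv(path)
    q = df[["w", "x", "y", "z"]].to_numpy(float)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    if align:
        q = sign_align(q)
    t = df["time"].to_numpy(float)
    h = float(np.mean(np.diff(t))) if len(t) > 1 else 1.0
    return QuaternionSeries(q, h)


def write_dataset(series_path: PathLike, labels_path: PathLike, data: LabeledDataset) -> None:
    frames = []
    for s, sid in zip(data.series, data.ids):
        df = pd.DataFrame(s.q, columns=["w", "x", "y", "z"])
        df.insert(0, "time", s.times)
        df.insert(0, "series_id", sid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(series_path, index=False)
    pd.DataFrame({"series_id": data.ids, "label": data.labels}).to_csv(labels_path, index=False)


def read_dataset(
    series_path: PathLike, labels_path: PathLike, *, align: bool = True
) -> LabeledDataset:
    long = pd.read_csv(series_path)
    labels = pd.read_csv(labels_path).set_index("series_id")["label"]
    series, ids, labs = [], [], []
    for sid, grp in long.groupby("series_id", sort=False):
        grp = grp.sort_values("time")
        q = grp[["w", "x", "y", "z"]].to_numpy(float)
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        if align:
            q = sign_align(q)
        t = grp["time"].to_numpy(float)
        h = float(np.mean(np.diff(t))) if len(t) > 1 else 1.0
        series.append(QuaternionSeries(q, h))
        ids.append(sid)
        labs.append(labels.loc[sid])
    return LabeledDataset(series, np.asarray(labs), ids)


def write_tangent_csv(path: PathLike, t: TangentSeries) -> None:
    anchor = t.anchor if t.anchor is not None else np.full(4, np.nan)
    anchor_txt = ",".join(f"{float(a):.17g}" for a in anchor)
    meta = f"# kind={t.kind} h={float(t.h):.17g} anchor={anchor_txt}\n"
    df = pd.DataFrame(t.values, columns=["v1", "v2", "v3"])
    df.insert(0, "time", np.arange(len(t.values)) * t.h)
    with open(path, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, index=False)


def read_tangent_csv(path: PathLike) -> TangentSeries:
    with open(path) as fh:
        meta = fh.readline().strip()
        df = pd.read_csv(fh)
    if not meta.startswith("#"):
        raise ValueError("tangent CSV is missing its metadata header line")
    fields = dict(item.split("=", 1) for item in meta[1:].split())
    anchor = np.array([float(v) for v in fields["anchor"].split(",")])
    if np.any(np.isnan(anchor)):
        anchor = None
    return TangentSeries(
        df[["v1", "v2", "v3"]].to_numpy(float),
        fields["kind"],
        float(fields["h"]),
        anchor=anchor,
    )
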