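"""Readers and writers for the plain-text formats the pipeline consumes.

Edge lists, neuron annotations and morphology-score tables are CSV (or
Parquet for edge lists); synapse locations travel in a companion
long-format file with one row per synapse; eyemaps are CSV with unit view
directions and per-layer marker coordinates; skeletons are SWC.  Synapse
and marker coordinates are nanometres as exported — no voxel conversion
is applied here.

The synthetic generators write these same formats, so synthetic and real
exports are interchangeable downstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import ConnectivityMatrix, NeuronRecord, SynapseEdge
from .receptive_fields import EyeMap

_SWC_COLUMNS = ["node_id", "type", "x", "y", "z", "radius", "parent_id"]


def read_edges(path: str | Path) -> list[SynapseEdge]:
    """Edge list with columns pre_id, post_id, count (CSV or Parquet)."""
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    required = {"pre_id", "post_id", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    return [
        SynapseEdge(pre_id=str(r.pre_id), post_id=str(r.post_id), count=int(r.count))
        for r in df.itertuples()
    ]


def write_edges(edges: Iterable[SynapseEdge], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.pre_id, e.post_id, e.count) for e in edges],
        columns=["pre_id", "post_id", "count"],
    )
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_synapse_locations(path: str | Path) -> dict[tuple[str, str], np.ndarray]:
    """Long-format synapse table: pre_id, post_id, x, y, z (nm), one row
    per synapse; returns per-connection point arrays."""
    df = pd.read_csv(path)
    required = {"pre_id", "post_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"synapse location table needs columns {sorted(required)}")
    out: dict[tuple[str, str], np.ndarray] = {}
    for (pre, post), sub in df.groupby(["pre_id", "post_id"], sort=True):
        out[(str(pre), str(post))] = sub[["x", "y", "z"]].to_numpy(dtype=float)
    return out


def write_synapse_locations(
    locations: Mapping[tuple[str, str], np.ndarray], path: str | Path
) -> None:
    rows = []
    for (pre, post), pts in locations.items():
        for x, y, z in np.atleast_2d(pts):
            rows.append((pre, post, x, y, z))
    pd.DataFrame(rows, columns=["pre_id", "post_id", "x", "y", "z"]).to_csv(
        path, index=False
    )


def read_annotations(path: str | Path) -> list[NeuronRecord]:
    df = pd.read_csv(path).fillna({"nt_prediction": ""})
    records = []
    for r in df.itertuples():
        nt = getattr(r, "nt_prediction", "") or None
        records.append(
            NeuronRecord(
                neuron_id=str(r.neuron_id),
                side=str(r.side),
                super_class=str(r.super_class),
                subtype=str(getattr(r, "subtype", "")),
                neuropil_origin=str(getattr(r, "neuropil_origin", "none")),
                nt_prediction=nt,
            )
        )
    ids = [rec.neuron_id for rec in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate neuron_id in annotation table")
    return records


def write_annotations(records: Iterable[NeuronRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.neuron_id, r.side, r.super_class, r.subtype, r.neuropil_origin,
             r.nt_prediction or "")
            for r in records
        ],
        columns=["neuron_id", "side", "super_class", "subtype", "neuropil_origin",
                 "nt_prediction"],
    ).to_csv(path, index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Morphology-similarity scores: query_id, target_id, score in [0, 1]."""
    df = pd.read_csv(path, dtype={"query_id": str, "target_id": str})
    required = {"query_id", "target_id", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    if not np.isfinite(df["score"]).all():
        raise ValueError("scores must be finite")
    return df


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index_label="input_id")


def read_matrix(
    path: str | Path, threshold: int = 0, binarized: bool = False
) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col="input_id")
    df.index = df.index.astype(str)
    return ConnectivityMatrix.from_frame(df, threshold=threshold, binarized=binarized)


def read_swc(path: str | Path) -> pd.DataFrame:
    """SWC skeleton as a node table (coordinates in nm, '#' comments)."""
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, names=_SWC_COLUMNS
    )
    return df.astype(
        {"node_id": int, "type": int, "radius": float, "parent_id": int}
    )


def swc_points(path: str | Path) -> np.ndarray:
    return read_swc(path)[["x", "y", "z"]].to_numpy(dtype=float)


def write_swc(points: np.ndarray, path: str | Path, radius: float = 50.0) -> None:
    """Write a point-cloud skeleton as an unrooted SWC node chain."""
    pts = np.atleast_2d(points)
    with open(path, "w") as fh:
        fh.write("# node_id type x y z radius parent_id\n")
        for i, (x, y, z) in enumerate(pts, start=1):
            parent = -1 if i == 1 else i - 1
            fh.write(f"{i} 0 {x:.3f} {y:.3f} {z:.3f} {radius:.1f} {parent}\n")


def write_eyemap(eye: EyeMap, path: str | Path) -> None:
    frames = []
    for layer, markers in eye.marker_positions.items():
        df = pd.DataFrame(
            {
                "column_id": eye.column_ids,
                "layer": layer,
                "dir_x": eye.directions[:, 0],
                "dir_y": eye.directions[:, 1],
                "dir_z": eye.directions[:, 2],
                "marker_x": markers[:, 0],
                "marker_y": markers[:, 1],
                "marker_z": markers[:, 2],
            }
        )
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def read_eyemap(path: str | Path) -> EyeMap:
    df = pd.read_csv(path, dtype={"column_id": str})
    layers = sorted(df["layer"].unique())
    first = df[df["layer"] == layers[0]].sort_values("column_id")
    column_ids = list(first["column_id"])
    directions = first[["dir_x", "dir_y", "dir_z"]].to_numpy(dtype=float)
    markers = {}
    for layer in layers:
        sub = df[df["layer"] == layer].sort_values("column_id")
        if list(sub["column_id"]) != column_ids:
            raise ValueError(f"layer {layer!r} has a different column set")
        markers[layer] = sub[["marker_x", "marker_y", "marker_z"]].to_numpy(dtype=float)
    return EyeMap(column_ids=column_ids, directions=directions, marker_positions=markers)
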