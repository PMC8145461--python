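"""Serialization of trajectories, point clouds, measures and reports.

All tabular artifacts are UTF-8 comma-separated files with a header row and
no index column; metadata travels in JSON sidecars.  Point clouds and
surface meshes can additionally be written as ASCII PLY for 3-D viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import PointCloud
from .measure import EmpiricalMeasure
from .switching import Trajectory

__all__ = [
    "write_trajectory",
    "write_cloud_csv",
    "write_cloud_ply",
    "write_mesh_ply",
    "write_measure_csv",
    "write_json",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_trajectory(traj: Trajectory, csv_path: str | Path) -> list[Path]:
    """Write a trajectory as CSV plus a metadata sidecar and jump-time CSV.

    The main table has columns ``step,t,xi1,xi2,xi3,i``; jump times go to
    ``<stem>.jumps.csv`` (single column, physical time) and run metadata to
    ``<stem>.meta.json``.  Returns the paths written.
    """
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        {
            "step": traj.steps,
            "t": traj.times,
            "xi1": traj.states[:, 0],
            "xi2": traj.states[:, 1],
            "xi3": traj.states[:, 2],
            "i": traj.gene,
        }
    )
    frame.to_csv(csv_path, index=False)
    jumps_path = csv_path.with_name(csv_path.stem + ".jumps.csv")
    pd.DataFrame({"jump_time": traj.jump_times}).to_csv(jumps_path, index=False)
    meta_path = csv_path.with_name(csv_path.stem + ".meta.json")
    meta_path.write_text(json.dumps(_jsonable(traj.meta), indent=2, sort_keys=True))
    return [csv_path, jumps_path, meta_path]


def write_cloud_csv(cloud: PointCloud, path: str | Path) -> Path:
    path = Path(path)
    data = {"x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2]}
    if cloud.weights is not None:
        data["weight"] = cloud.weights
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def _ply_header(n_vertices: int, n_faces: int = 0) -> list[str]:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {n_vertices}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if n_faces:
        lines += [f"element face {n_faces}", "property list uchar int vertex_indices"]
    lines.append("end_header")
    return lines


def write_cloud_ply(cloud: PointCloud, path: str | Path) -> Path:
    """ASCII PLY point cloud (vertices only)."""
    path = Path(path)
    lines = _ply_header(len(cloud))
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in cloud.points]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_mesh_ply(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> Path:
    """ASCII PLY triangle mesh."""
    path = Path(path)
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = _ply_header(len(vertices), len(faces))
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in vertices]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in faces]
    path.write_text("\n".join(lines) + "\n")
    return path


def grid_mesh_faces(n_rows: int, n_cols: int) -> np.ndarray:
    """Triangulation of a structured (n_rows x n_cols) vertex grid."""
    faces = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            k = r * n_cols + c
            faces.append([k, k + 1, k + n_cols])
            faces.append([k + 1, k + n_cols + 1, k + n_cols])
    return np.array(faces, dtype=int)


def write_measure_csv(measure: EmpiricalMeasure, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "x": measure.atoms[:, 0],
            "y": measure.atoms[:, 1],
            "z": measure.atoms[:, 2],
            "weight": measure.weights,
        }
    ).to_csv(path, index=False)
    return path


def write_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return path
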