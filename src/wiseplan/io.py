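"""File I/O: legacy-ASCII VTK polydata, OFF meshes, CSV/JSON tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh


def write_vtk_polydata(
    path,
    points: np.ndarray,
    faces: np.ndarray,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write a triangle mesh as legacy ASCII VTK polydata.

    ``point_data`` / ``cell_data`` map names to scalar arrays.
    """
    points = np.asarray(points, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "wiseplan mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} float",
    ]
    for p in points:
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    for f in faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")

    def _scalars(name, arr):
        arr = np.asarray(arr)
        out = [f"SCALARS {name} float 1", "LOOKUP_TABLE default"]
        out += [f"{float(v):.6f}" for v in arr]
        return out

    if point_data:
        lines.append(f"POINT_DATA {len(points)}")
        for name, arr in point_data.items():
            lines += _scalars(name, arr)
    if cell_data:
        lines.append(f"CELL_DATA {len(faces)}")
        for name, arr in cell_data.items():
            lines += _scalars(name, arr)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path):
    """Read a legacy ASCII VTK polydata file written by this package.

    Returns (points, faces, point_data, cell_data).
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    points = faces = None
    point_data: dict = {}
    cell_data: dict = {}
    current = None
    i = 0
    lines = [t for t in tokens]
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = " ".join(lines[i + 1 : i + 1 + n]).split()
            points = np.array(vals, dtype=float).reshape(n, 3)
            i += n
        elif line.startswith("POLYGONS"):
            n = int(line.split()[1])
            rows = [lines[i + 1 + k].split() for k in range(n)]
            faces = np.array([r[1:4] for r in rows], dtype=np.int64)
            i += n
        elif line.startswith("POINT_DATA"):
            current = point_data
        elif line.startswith("CELL_DATA"):
            current = cell_data
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            count = len(points) if current is point_data else len(faces)
            vals = lines[i + 2 : i + 2 + count]
            current[name] = np.array(vals, dtype=float)
            i += count + 1
        i += 1
    return points, faces, point_data, cell_data


def write_off(path, points: np.ndarray, faces: np.ndarray) -> None:
    mesh = trimesh.Trimesh(vertices=points, faces=faces, process=False)
    Path(path).write_bytes(trimesh.exchange.off.export_off(mesh).encode())


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_tac_csv(path, tac) -> None:
    """TAC table: columns time_s, aif_hu, seg01_hu..seg16_hu."""
    cols = {"time_s": tac.times, "aif_hu": tac.aif}
    for s in range(1, 17):
        cols[f"seg{s:02d}_hu"] = tac.regional_curves[s - 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_tac_csv(path, baseline_hu: float | None = None):
    from .types import TACSet

    df = pd.read_csv(path)
    curves = np.vstack([df[f"seg{s:02d}_hu"].to_numpy() for s in range(1, 17)])
    if baseline_hu is None:
        baseline_hu = float(curves[:, 0].mean())
    return TACSet(
        times=df["time_s"].to_numpy(),
        aif=df["aif_hu"].to_numpy(),
        regional_curves=curves,
        baseline_hu=baseline_hu,
    )
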