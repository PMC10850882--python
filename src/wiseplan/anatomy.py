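"""AHA parcellation of LV meshes and wall-thickness measurement.

Parcellation: longitudinal thirds of the normalised apex-to-base
coordinate crossed with circumferential sectors (6/6/4) anchored to the
septal direction.  When no anatomical RV insertion is supplied, the
anchor is synthesised from the RV pacing site direction.

Thickness: for each endocardial vertex, the distance to the epicardial
surface along the outward endocardial normal (nearest ray hit).  The
per-segment summary is the median (robust to basal-rim ray artifacts);
segments whose summary falls strictly below 5 mm are labeled thin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import aha
from .types import LVGeometry, ThicknessMap


@dataclass
class ThicknessPolicy:
    thin_threshold_mm: float = 5.0
    summary: str = "median"  # or "min" for conservative screening
    min_valid_vertices: int = 10
    max_ray_mm: float = 60.0


def parcellate_aha(geom: LVGeometry, septal_dir=None) -> np.ndarray:
    """Label every endo face with its AHA id (1..16).

    ``septal_dir`` overrides the anchor; by default it is taken from the
    RV pacing site direction relative to the long axis.
    """
    apex = geom.apex_point
    base = geom.base_centroid
    span = float((base - apex) @ geom.long_axis)
    if span <= 0:
        raise ValueError("apex/base landmarks missing or degenerate")
    if septal_dir is None:
        rel = geom.rv_pacing_site - apex
        septal_dir = rel - (rel @ geom.long_axis) * geom.long_axis
    u, v, w = aha.heart_frame(geom.long_axis, septal_dir)
    cent = geom.face_centroids() - apex
    h = np.clip((cent @ w) / span, 0.0, 1.0)
    ang = np.degrees(np.arctan2(cent @ v, cent @ u)) % 360.0
    # snap away float jitter so sector-boundary faces label identically
    # under rigid motion of the full input
    ang = np.round(ang, 6) % 360.0
    return np.array([aha.segment_of(a, hh) for a, hh in zip(ang, h)], dtype=np.int64)


def _vertex_normals(verts, faces):
    tri = verts[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    n = np.linalg.norm(vn, axis=1)
    n[n == 0] = 1.0
    return vn / n[:, None]


def ray_mesh_distances(origins, directions, verts, faces, max_dist=np.inf):
    """Nearest-hit distances of rays against a triangle mesh
    (vectorised Moller-Trumbore; NaN where a ray misses)."""
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    v0 = verts[faces[:, 0]]
    e1 = verts[faces[:, 1]] - v0
    e2 = verts[faces[:, 2]] - v0
    out = np.full(len(origins), np.nan)
    eps = 1e-9
    # chunk over rays to bound memory: (rays, faces) pair arrays
    chunk = max(1, int(4e6 // max(1, len(faces))))
    for lo in range(0, len(origins), chunk):
        O = origins[lo : lo + chunk][:, None, :]
        D = directions[lo : lo + chunk][:, None, :]
        P = np.cross(D, e2[None, :, :])
        det = np.einsum("rfk,fk->rf", P, e1)
        T = O - v0[None, :, :]
        inv = np.where(np.abs(det) > eps, 1.0 / np.where(det == 0, 1.0, det), np.nan)
        uu = np.einsum("rfk,rfk->rf", P, T) * inv
        Q = np.cross(T, e1[None, :, :])
        vv = np.einsum("rfk,rk->rf", Q, directions[lo : lo + chunk]) * inv
        tt = np.einsum("rfk,fk->rf", Q, e2) * inv
        ok = (
            (uu >= -1e-7)
            & (vv >= -1e-7)
            & (uu + vv <= 1.0 + 1e-7)
            & (tt > 1e-6)
            & (tt <= max_dist)
        )
        tt = np.where(ok, tt, np.inf)
        best = tt.min(axis=1)
        out[lo : lo + chunk] = np.where(np.isfinite(best), best, np.nan)
    return out


def compute_wall_thickness(
    geom: LVGeometry, policy: ThicknessPolicy | None = None, subsample: int | None = None
) -> ThicknessMap:
    """Per-vertex endo-to-epi thickness along the outward endo normal and
    per-segment summary with thin labeling (< threshold, strict).

    ``subsample`` caps the number of vertices ray-cast per segment.
    """
    policy = policy or ThicknessPolicy()
    normals = _vertex_normals(geom.endo_vertices, geom.endo_faces)
    n = geom.n_endo_vertices

    vert_segments: dict[int, list[int]] = {s: [] for s in range(1, 17)}
    seen = np.zeros(n, dtype=bool)
    for f, lab in zip(geom.endo_faces, geom.segment_labels):
        for vtx in f:
            if not seen[vtx]:
                vert_segments[int(lab)].append(int(vtx))
                seen[vtx] = True

    select = []
    for s in range(1, 17):
        vs = vert_segments[s]
        if subsample is not None and len(vs) > subsample:
            vs = list(np.array(vs)[np.linspace(0, len(vs) - 1, subsample).astype(int)])
            vert_segments[s] = vs
        select.extend(vs)
    select = np.array(sorted(set(select)), dtype=int)

    dist = ray_mesh_distances(
        geom.endo_vertices[select],
        normals[select],
        geom.epi_vertices,
        geom.epi_faces,
        max_dist=policy.max_ray_mm,
    )
    thickness = np.full(n, np.nan)
    thickness[select] = dist
    n_miss = int(np.sum(np.isnan(dist)))
    if n_miss:
        warnings.warn(f"{n_miss} thickness rays missed the epicardium", stacklevel=2)

    seg_thickness = np.full(16, np.nan)
    thin = np.zeros(16, dtype=bool)
    for s in range(1, 17):
        vals = thickness[np.array(vert_segments[s], dtype=int)] if vert_segments[s] else np.array([])
        vals = vals[np.isfinite(vals)]
        if vals.size < policy.min_valid_vertices:
            raise ValueError(f"segment {s}: fewer than {policy.min_valid_vertices} valid thickness samples")
        seg_thickness[s - 1] = np.min(vals) if policy.summary == "min" else np.median(vals)
        thin[s - 1] = bool(seg_thickness[s - 1] < policy.thin_threshold_mm)
    return ThicknessMap(
        vertex_thickness=thickness,
        seg_thickness=seg_thickness,
        thin=thin,
        threshold_mm=policy.thin_threshold_mm,
    )
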