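"""Endocardial deformation tracking: segmental strain and time to peak.

Vertex correspondence across phases is assumed given (the tracking-by-
registration step that produces it is upstream of this package).  Per
segment and phase, with phase 0 as reference:

* local area change  = surface area ratio - 1
* circumferential / longitudinal strain = mean fractional edge-length
  change of the segment's edges, binned by orientation relative to the
  long axis (|cos| <= 0.5 -> circumferential, otherwise longitudinal)

Time to peak contraction (TTP) is the phase of the most negative area
change; segments whose peak-to-peak area change falls below the flat-curve
threshold are excluded from lateness ranking.
"""

from __future__ import annotations

import numpy as np

from . import aha
from .types import MeshSequence, StrainCurves

DEFAULT_FLAT_THRESHOLD = 0.05


def _segment_faces(labels):
    return {s: np.flatnonzero(labels == s) for s in range(1, 17)}


def _face_areas(verts, faces):
    tri = verts[faces]
    return 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)


def _segment_edges(faces, labels, verts0, long_axis):
    """Unique edges per segment, split into circumferential/longitudinal
    bins by orientation at the reference phase."""
    out = {}
    for s in range(1, 17):
        fs = faces[labels == s]
        if fs.size == 0:
            out[s] = (np.empty((0, 2), int), np.empty((0, 2), int))
            continue
        e = np.vstack([fs[:, [0, 1]], fs[:, [1, 2]], fs[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        d = verts0[e[:, 1]] - verts0[e[:, 0]]
        L = np.linalg.norm(d, axis=1)
        keep = L > 0
        e, d, L = e[keep], d[keep], L[keep]
        cosang = np.abs(d @ long_axis) / L
        out[s] = (e[cosang <= 0.5], e[cosang > 0.5])
    return out


def compute_strain_curves(
    seq: MeshSequence,
    faces: np.ndarray,
    labels: np.ndarray,
    long_axis: np.ndarray,
    flat_threshold: float = DEFAULT_FLAT_THRESHOLD,
) -> StrainCurves:
    """Per-segment deformation curves over the cycle plus TTP and flags.

    ``faces``/``labels`` are the endocardial triangles and their AHA ids;
    ``long_axis`` orients the circumferential/longitudinal edge bins.
    """
    if len(seq.phases) < 10:
        raise ValueError("at least 10 phases required")
    faces = np.asarray(faces, dtype=np.int64)
    labels = np.asarray(labels)
    if labels.shape[0] != faces.shape[0]:
        raise ValueError("labels must cover all endo faces")
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    verts0 = seq.vertex_positions[0]
    m = len(seq.phases)

    seg_faces = _segment_faces(labels)
    ref_area = {}
    for s, idx in seg_faces.items():
        a = _face_areas(verts0, faces[idx]).sum() if idx.size else 0.0
        if idx.size and a <= 0:
            raise ValueError(f"segment {s} has zero reference area")
        ref_area[s] = a
    edges = _segment_edges(faces, labels, verts0, axis)
    ref_len = {
        s: (
            np.linalg.norm(verts0[ec[:, 1]] - verts0[ec[:, 0]], axis=1),
            np.linalg.norm(verts0[el[:, 1]] - verts0[el[:, 0]], axis=1),
        )
        for s, (ec, el) in edges.items()
    }

    area_change = np.zeros((16, m))
    circ = np.zeros((16, m))
    lng = np.zeros((16, m))
    for i in range(m):
        v = seq.vertex_positions[i]
        for s in range(1, 17):
            idx = seg_faces[s]
            if idx.size == 0 or ref_area[s] <= 0:
                continue
            area_change[s - 1, i] = _face_areas(v, faces[idx]).sum() / ref_area[s] - 1.0
            ec, el = edges[s]
            rc, rl = ref_len[s]
            if ec.size:
                circ[s - 1, i] = float(
                    np.mean(np.linalg.norm(v[ec[:, 1]] - v[ec[:, 0]], axis=1) / rc) - 1.0
                )
            if el.size:
                lng[s - 1, i] = float(
                    np.mean(np.linalg.norm(v[el[:, 1]] - v[el[:, 0]], axis=1) / rl) - 1.0
                )

    curves = StrainCurves(
        phases=seq.phases.copy(),
        area_change=area_change,
        circ_strain=circ,
        long_strain=lng,
        ttp_phase=np.full(16, np.nan),
        ttp_ms=np.full(16, np.nan),
        flat=np.zeros(16, dtype=bool),
        peak_amplitude=np.zeros(16),
        cycle_length=seq.cycle_length,
    )
    try:
        time_to_peak(curves, flat_threshold)
    except ValueError:
        # a fully static sequence still yields curves; TTP stays undefined
        curves.flat[:] = True
    return curves


def time_to_peak(curves: StrainCurves, flat_threshold: float = DEFAULT_FLAT_THRESHOLD):
    """Recompute per-segment TTP and flat flags at the given threshold.

    Returns (ttp_phase, flat) and updates the curves in place.
    """
    if flat_threshold <= 0:
        raise ValueError("flat_threshold must be positive")
    m = curves.area_change.shape[1]
    ttp = np.full(16, np.nan)
    flat = np.zeros(16, dtype=bool)
    for s in range(16):
        ac = curves.area_change[s]
        amp = float(np.ptp(ac))
        curves.peak_amplitude[s] = amp
        if amp < flat_threshold:
            flat[s] = True
            continue
        i = int(np.argmin(ac))
        t = curves.phases[i]
        if 0 < i < m - 1:
            # sub-grid refinement: vertex of the parabola through the
            # minimum and its neighbours
            y0, y1, y2 = ac[i - 1], ac[i], ac[i + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom > 1e-12:
                step = curves.phases[i] - curves.phases[i - 1]
                t = t + 0.5 * step * (y0 - y2) / denom
        ttp[s] = float(t)
    if flat.all():
        raise ValueError("no mechanical signal: all segments flat")
    curves.ttp_phase = ttp
    curves.ttp_ms = ttp * curves.cycle_length
    curves.flat = flat
    return ttp, flat


def latest_mechanical_segment(curves: StrainCurves) -> int:
    """Latest mechanically activating segment = argmax TTP over non-flat
    segments; ties broken basal-then-lateral."""
    cand = [s for s in range(1, 17) if not curves.flat[s - 1] and np.isfinite(curves.ttp_phase[s - 1])]
    if not cand:
        raise ValueError("no mechanical signal: all segments flat")
    best = max(curves.ttp_phase[s - 1] for s in cand)
    tied = [s for s in cand if curves.ttp_phase[s - 1] == best]
    return min(tied, key=aha.basal_lateral_key)
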