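"""Reporting: AHA bull's-eye plots (SVG) and fluoroscopy-style
perspective projection of target-segment boundaries."""

from __future__ import annotations

import numpy as np

from . import aha
from .types import CArmView, LVGeometry


def render_bullseye(values, path=None, title: str = "", cmap_name: str = "viridis"):
    """Render 16 per-segment scalars on the standard bull's-eye layout
    (basal ring outermost, anterior up, septum left).

    Exactly-zero values are drawn white (no coverage); NaN segments are
    hatched and listed in the legend.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors
    from matplotlib.patches import Wedge

    values = np.asarray(values, dtype=float)
    if values.shape != (16,):
        raise ValueError("exactly 16 per-segment values required")
    radii = {0: (2.0, 3.0), 1: (1.0, 2.0), 2: (0.35, 1.0)}  # ring -> (r0, r1)
    finite = values[np.isfinite(values)]
    vmax = float(finite.max()) if finite.size else 1.0
    vmin = float(finite.min()) if finite.size else 0.0
    if vmax == vmin:
        vmax = vmin + 1.0
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    cmap = matplotlib.colormaps[cmap_name]

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    missing = []
    for s in range(1, 17):
        lo, hi = aha.SEGMENT_SPANS[s]
        r0, r1 = radii[aha.SEGMENT_RING[s]]
        v = values[s - 1]
        if not np.isfinite(v):
            fc, hatch = "lightgray", "///"
            missing.append(s)
        elif v == 0.0:
            fc, hatch = "white", None
        else:
            fc, hatch = cmap(norm(v)), None
        ax.add_patch(
            Wedge((0, 0), r1, lo, hi, width=r1 - r0, facecolor=fc, hatch=hatch,
                  edgecolor="black", linewidth=0.8)
        )
    ax.set_xlim(-3.2, 3.2)
    ax.set_ylim(-3.2, 3.2)
    ax.set_aspect("equal")
    ax.axis("off")
    legend = title
    if finite.size and np.allclose(finite, finite[0]):
        legend += f" (uniform: {finite[0]:.3g})"
    if missing:
        legend += f" missing: {missing}"
    ax.set_title(legend.strip())
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.7)
    if path is not None:
        fig.savefig(path, format="svg")
        plt.close(fig)
    return fig


def _view_frame(view: CArmView):
    """Detector frame: normal n (source->detector), in-plane axes u, v."""
    a = np.radians(view.rao_lao_deg)
    b = np.radians(view.cranial_caudal_deg)
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    rx = np.array([[1, 0, 0], [0, np.cos(b), -np.sin(b)], [0, np.sin(b), np.cos(b)]])
    rot = rz @ rx
    n = rot @ np.array([0.0, 1.0, 0.0])
    u = rot @ np.array([1.0, 0.0, 0.0])
    v = rot @ np.array([0.0, 0.0, 1.0])
    return n, u, v


def segment_boundary_polylines(geom: LVGeometry, targets) -> list:
    """Closed-ish polylines of edges bounding the target-segment patch."""
    targets = set(int(t) for t in targets)
    in_t = np.isin(geom.segment_labels, sorted(targets))
    edge_count: dict = {}
    for f, inside in zip(geom.endo_faces, in_t):
        if not inside:
            continue
        for i in range(3):
            a, b = int(f[i]), int(f[(i + 1) % 3])
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    # edges used by exactly one inside face bound the patch (mesh-rim
    # edges of the patch included)
    boundary = [e for e, c in edge_count.items() if c == 1]
    # chain edges into polylines
    adj: dict = {}
    for a, b in boundary:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    unused = set(boundary)
    polylines = []
    while unused:
        a, b = next(iter(unused))
        unused.discard((a, b))
        chain = [a, b]
        while True:
            nxt = None
            for c in adj.get(chain[-1], []):
                e = (min(chain[-1], c), max(chain[-1], c))
                if e in unused:
                    nxt = c
                    unused.discard(e)
                    break
            if nxt is None:
                break
            chain.append(nxt)
        polylines.append(geom.endo_vertices[np.array(chain)])
    return polylines


def project_points(points: np.ndarray, geom: LVGeometry, view: CArmView) -> np.ndarray:
    """Perspective projection of 3-D points onto the detector plane,
    in detector millimetres (isocenter at the LV centroid)."""
    iso = geom.endo_vertices.mean(axis=0)
    n, u, v = _view_frame(view)
    source = iso - view.source_to_isocenter_mm * n
    det_center = source + view.source_to_detector_mm * n
    rel = np.atleast_2d(points) - source
    depth = rel @ n
    if np.any(depth <= 1e-9):
        raise ValueError("point behind the source plane")
    t = view.source_to_detector_mm / depth
    proj = source + rel * t[:, None] - det_center
    return np.column_stack([proj @ u, proj @ v])


def project_overlay(geom: LVGeometry, targets, view: CArmView) -> list:
    """Project target-segment boundary polylines onto the detector.

    Returns a list of (k_i, 2) arrays in detector mm.
    """
    return [project_points(pl, geom, view) for pl in segment_boundary_polylines(geom, targets)]
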