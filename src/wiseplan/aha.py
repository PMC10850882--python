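"""AHA 16-segment model: names, bull's-eye layout, and adjacency.

The left ventricle is divided into basal (1-6), mid (7-12) and apical
(13-16) rings of circumferential sectors; the true apex (segment 17 of the
17-segment variant) is excluded.  Angles are measured in a heart-fixed
frame anchored to the septum: 0 deg points at the centre of the lateral
wall, 90 deg at the anterior wall, 180 deg at the mid-septum, 270 deg at
the inferior wall.  Longitudinal position is the normalised apex-to-base
coordinate h in [0, 1]; ring boundaries sit at h = 1/3 and 2/3.
"""

from __future__ import annotations

import numpy as np

SEGMENT_IDS = tuple(range(1, 17))

SEGMENT_NAMES = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
}

NAME_TO_ID = {v: k for k, v in SEGMENT_NAMES.items()}

# ring index: 0 = basal, 1 = mid, 2 = apical
SEGMENT_RING = {s: 0 for s in range(1, 7)}
SEGMENT_RING.update({s: 1 for s in range(7, 13)})
SEGMENT_RING.update({s: 2 for s in range(13, 17)})

# angular spans [lo, hi) in degrees in the heart-fixed frame above
_BASAL_MID_SPANS = {
    "anterolateral": (0.0, 60.0),
    "anterior": (60.0, 120.0),
    "anteroseptal": (120.0, 180.0),
    "inferoseptal": (180.0, 240.0),
    "inferior": (240.0, 300.0),
    "inferolateral": (300.0, 360.0),
}
SEGMENT_SPANS = {
    6: _BASAL_MID_SPANS["anterolateral"],
    1: _BASAL_MID_SPANS["anterior"],
    2: _BASAL_MID_SPANS["anteroseptal"],
    3: _BASAL_MID_SPANS["inferoseptal"],
    4: _BASAL_MID_SPANS["inferior"],
    5: _BASAL_MID_SPANS["inferolateral"],
    12: _BASAL_MID_SPANS["anterolateral"],
    7: _BASAL_MID_SPANS["anterior"],
    8: _BASAL_MID_SPANS["anteroseptal"],
    9: _BASAL_MID_SPANS["inferoseptal"],
    10: _BASAL_MID_SPANS["inferior"],
    11: _BASAL_MID_SPANS["inferolateral"],
    13: (45.0, 135.0),
    14: (135.0, 225.0),
    15: (225.0, 315.0),
    16: (315.0, 405.0),  # wraps through 0
}

SEPTAL_SEGMENTS = frozenset({2, 3, 8, 9, 14})

# Undirected adjacency of the 16-segment bull's-eye: ring neighbours plus
# longitudinal neighbours whose angular spans overlap.
ADJACENCY = {
    1: {2, 6, 7},
    2: {1, 3, 8},
    3: {2, 4, 9},
    4: {3, 5, 10},
    5: {4, 6, 11},
    6: {5, 1, 12},
    7: {8, 12, 1, 13},
    8: {7, 9, 2, 13, 14},
    9: {8, 10, 3, 14, 15},
    10: {9, 11, 4, 15},
    11: {10, 12, 5, 15, 16},
    12: {11, 7, 6, 16, 13},
    13: {14, 16, 7, 8, 12},
    14: {13, 15, 8, 9},
    15: {14, 16, 9, 10, 11},
    16: {15, 13, 11, 12},
}


def segment_center_angle(segment: int) -> float:
    """Centre angle of a segment's sector, degrees in [0, 360)."""
    lo, hi = SEGMENT_SPANS[segment]
    return (0.5 * (lo + hi)) % 360.0


def lateralness(segment: int) -> float:
    """Circular angular distance (deg) of the sector centre from the
    mid-septum (180 deg); larger means more lateral."""
    d = abs(segment_center_angle(segment) - 180.0)
    return min(d, 360.0 - d)


def basal_lateral_key(segment: int) -> tuple:
    """Sort key implementing the basal-then-lateral tie-break convention:
    lower key wins (more basal ring first, then more lateral sector)."""
    return (SEGMENT_RING[segment], -lateralness(segment), segment)


def are_adjacent(a: int, b: int) -> bool:
    return b in ADJACENCY[a]


def segment_of(angle_deg: float, h: float) -> int:
    """Look up the AHA id for a point at circumferential angle ``angle_deg``
    (heart-fixed frame) and normalised apex-to-base height ``h``.

    h < 1/3 is apical, 1/3 <= h < 2/3 mid, h >= 2/3 basal.
    """
    a = float(angle_deg) % 360.0
    if h >= 2.0 / 3.0:
        ids = (1, 2, 3, 4, 5, 6)
    elif h >= 1.0 / 3.0:
        ids = (7, 8, 9, 10, 11, 12)
    else:
        ids = (13, 14, 15, 16)
    for s in ids:
        lo, hi = SEGMENT_SPANS[s]
        if hi > 360.0:  # wrapped sector
            if a >= lo or a < hi - 360.0:
                return s
        elif lo <= a < hi:
            return s
    raise RuntimeError(f"no sector covers angle {a}")  # pragma: no cover


def validate_adjacency() -> None:
    """Internal consistency of the adjacency table (symmetry, no self
    loops, ring neighbours present)."""
    for s, nbrs in ADJACENCY.items():
        if s in nbrs:
            raise AssertionError(f"self loop at {s}")
        for t in nbrs:
            if s not in ADJACENCY[t]:
                raise AssertionError(f"asymmetric edge {s}-{t}")


def angular_overlap(a: int, b: int) -> float:
    """Overlap (deg) of two segments' angular spans on the circle."""
    lo_a, hi_a = SEGMENT_SPANS[a]
    lo_b, hi_b = SEGMENT_SPANS[b]
    total = 0.0
    for shift in (-360.0, 0.0, 360.0):
        lo = max(lo_a, lo_b + shift)
        hi = min(hi_a, hi_b + shift)
        total += max(0.0, hi - lo)
    return total


def heart_frame(long_axis: np.ndarray, septal_dir: np.ndarray):
    """Orthonormal frame (u, v, w) with w = long axis (apex->base),
    u = lateral direction (opposite the septum), v = anterior.

    ``septal_dir`` is any vector with a component toward the septum; it is
    projected perpendicular to the long axis.
    """
    w = np.asarray(long_axis, dtype=float)
    w = w / np.linalg.norm(w)
    s = np.asarray(septal_dir, dtype=float)
    s = s - np.dot(s, w) * w
    n = np.linalg.norm(s)
    if n < 1e-12:
        raise ValueError("septal direction parallel to long axis")
    s /= n
    u = -s
    v = np.cross(s, w)
    return u, v, w
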