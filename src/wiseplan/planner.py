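"""Target-segment selection and transmitter-site ranking.

Electrode targets: among viable segments (neither thin nor hypoperfused)
with a defined mechanical time to peak, each segment is scored by the sum
of its lateness ranks in the mechanical (TTP) and electrical (activation
time) maps.  The primary target is the best-scoring segment; the second
is its best-scoring viable neighbour in the AHA-16 adjacency graph, so
the pair is always two adjacent segments.  Ties break basal-then-lateral.

Transmitter sites: each intercostal candidate is scored by the modeled
acoustic intensity at the target-segment centroids,

    I(theta, d) = cos(theta) * exp(-mu * d),

normalised to 1 at (theta = 0, d = 0), with hard admissibility cutoffs at
theta >= 30 degrees or depth d >= 12 cm (outside the acoustic window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import aha
from .types import (
    ActivationMap,
    LVGeometry,
    PerfusionResult,
    StrainCurves,
    ThicknessMap,
    ThoraxModel,
    TransmitterCandidate,
)


@dataclass
class AcousticModel:
    mu_per_cm: float = 0.1  # attenuation coefficient
    max_angle_deg: float = 30.0
    max_depth_cm: float = 12.0


@dataclass
class SelectionPolicy:
    fusion: str = "rank_sum"  # or "mechanical" / "electrical" priority


def build_feature_table(
    thickness: ThicknessMap,
    perf: PerfusionResult,
    mech: StrainCurves,
    act: ActivationMap,
) -> pd.DataFrame:
    """Join the four per-segment maps into the planner's feature table."""
    for name, arr in (
        ("thickness", thickness.seg_thickness),
        ("perfusion", perf.mbf),
        ("mechanics", mech.ttp_phase),
        ("activation", act.seg_mean),
    ):
        if np.asarray(arr).shape[0] != 16:
            raise ValueError(f"{name} input does not cover 16 segments")
    df = pd.DataFrame(
        {
            "thickness_mm": thickness.seg_thickness,
            "thin": thickness.thin,
            "mbf": perf.mbf,
            "hypoperfused": perf.hypoperfused,
            "late_enhancement": (
                perf.late_enhancement
                if perf.late_enhancement is not None
                else np.zeros(16, dtype=bool)
            ),
            "ttp_phase": mech.ttp_phase,
            "ttp_ms": mech.ttp_ms,
            "flat": mech.flat,
            "activation_ms": act.seg_mean,
        },
        index=pd.Index(range(1, 17), name="segment"),
    )
    df["viable"] = ~df["thin"] & ~df["hypoperfused"]
    df["target"] = False
    return df


def rank_sum_targets(ttp_by_segment: dict, activation_by_segment: dict) -> tuple[int, int]:
    """Core selection rule on explicit lateness dicts over viable segments.

    Returns (primary, secondary); raises ValueError when no adjacent
    viable pair exists.
    """
    segs = sorted(set(ttp_by_segment) & set(activation_by_segment))
    if len(segs) < 2:
        raise ValueError("no viable target pair: fewer than 2 qualifying segments")
    ttp = np.array([ttp_by_segment[s] for s in segs], dtype=float)
    act = np.array([activation_by_segment[s] for s in segs], dtype=float)
    score = rankdata(ttp, method="average") + rankdata(act, method="average")
    order = sorted(
        range(len(segs)), key=lambda i: (-score[i],) + aha.basal_lateral_key(segs[i])
    )
    for i in order:
        primary = segs[i]
        nbrs = [s for s in segs if aha.are_adjacent(primary, s)]
        if not nbrs:
            continue
        j = min(
            (segs.index(s) for s in nbrs),
            key=lambda k: (-score[k],) + aha.basal_lateral_key(segs[k]),
        )
        return primary, segs[j]
    raise ValueError("no viable target pair: no adjacent viable segments")


def select_target_segments(table: pd.DataFrame, policy: SelectionPolicy | None = None):
    """Choose the 2 adjacent target segments from the feature table and
    set its ``target`` column."""
    policy = policy or SelectionPolicy()
    ok = table["viable"] & ~table["flat"] & np.isfinite(table["ttp_phase"]) & np.isfinite(
        table["activation_ms"]
    )
    segs = [int(s) for s in table.index[ok]]
    if len(segs) < 2:
        raise ValueError("no viable target pair: fewer than 2 qualifying segments")
    ttp = {s: float(table.loc[s, "ttp_phase"]) for s in segs}
    act = {s: float(table.loc[s, "activation_ms"]) for s in segs}
    if policy.fusion == "mechanical":
        act = {s: ttp[s] for s in segs}
    elif policy.fusion == "electrical":
        ttp = {s: act[s] for s in segs}
    primary, secondary = rank_sum_targets(ttp, act)
    table["target"] = False
    table.loc[[primary, secondary], "target"] = True
    return primary, secondary


def acoustic_intensity(
    candidate: TransmitterCandidate,
    segment_centroid: np.ndarray,
    model: AcousticModel | None = None,
):
    """Depth (cm), beam angle (deg), normalised intensity and coverage of
    one candidate toward one segment centroid."""
    model = model or AcousticModel()
    centroid = np.asarray(segment_centroid, dtype=float)
    vec = centroid - candidate.skin_entry_point
    dist_mm = np.linalg.norm(vec)
    if dist_mm == 0:
        return 0.0, 0.0, 1.0, True
    direction = vec / dist_mm
    cosang = float(np.clip(candidate.beam_axis @ direction, -1.0, 1.0))
    theta = float(np.degrees(np.arccos(cosang)))
    d_cm = float(dist_mm / 10.0)
    if theta >= model.max_angle_deg or d_cm >= model.max_depth_cm:
        return d_cm, theta, 0.0, False
    intensity = float(np.cos(np.radians(theta)) * np.exp(-model.mu_per_cm * d_cm))
    return d_cm, theta, intensity, intensity > 0.0


def acoustic_map(
    thorax: ThoraxModel, geom: LVGeometry, model: AcousticModel | None = None
) -> pd.DataFrame:
    """Full per-(ICS, segment) intensity table (the bull's-eye per
    candidate of the planning report)."""
    rows = []
    for cand in thorax.ics_candidates:
        for s in range(1, 17):
            d, theta, inten, cov = acoustic_intensity(cand, geom.segment_centroid(s), model)
            rows.append(
                {
                    "ics_id": cand.ics_id,
                    "segment": s,
                    "depth_cm": d,
                    "angle_deg": theta,
                    "intensity": inten,
                    "covered": cov,
                }
            )
    return pd.DataFrame(rows)


def rank_transmitter_sites(
    thorax: ThoraxModel,
    targets,
    geom: LVGeometry,
    model: AcousticModel | None = None,
):
    """Rank candidates by mean intensity over the target-segment
    centroids (descending, ics_id tie-break).

    Returns (ranked list of (ics_id, mean_intensity), acoustic map
    DataFrame, adequate_coverage flag).
    """
    model = model or AcousticModel()
    targets = sorted(int(t) for t in targets)
    amap = acoustic_map(thorax, geom, model)
    scores = []
    for cand in thorax.ics_candidates:
        sub = amap[(amap.ics_id == cand.ics_id) & (amap.segment.isin(targets))]
        scores.append((float(sub.intensity.mean()), cand.ics_id))
    ranked = sorted(scores, key=lambda t: (-t[0], t[1]))
    adequate = ranked[0][0] > 0.0
    if not adequate:
        warnings.warn("no adequate coverage: no candidate reaches a target segment", stacklevel=2)
    return [(ics, score) for score, ics in ranked], amap, adequate
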