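"""Core dataclasses shared across the planning pipeline.

Units are mm, ms, s (pressure traces and TACs), HU, mmHg and
mL/100 mL/min throughout; cardiac phase is expressed as a fraction of the
RR interval in [0, 1).  AHA segment ids are 1..16; array indices are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """A generator or analysis parameter is out of its admissible range."""


@dataclass
class LVGeometry:
    """LV endo/epi triangle surfaces with landmarks and AHA face labels."""

    endo_vertices: np.ndarray  # (n, 3) mm
    endo_faces: np.ndarray  # (f, 3) int
    epi_vertices: np.ndarray
    epi_faces: np.ndarray
    apex_point: np.ndarray  # (3,)
    base_centroid: np.ndarray  # (3,)
    long_axis: np.ndarray  # unit vector, apex -> base
    rv_pacing_site: np.ndarray  # (3,), on a septal endo face
    segment_labels: np.ndarray  # (f,) int in 1..16, per endo face

    def __post_init__(self) -> None:
        self.endo_vertices = np.asarray(self.endo_vertices, dtype=float)
        self.epi_vertices = np.asarray(self.epi_vertices, dtype=float)
        self.endo_faces = np.asarray(self.endo_faces, dtype=np.int64)
        self.epi_faces = np.asarray(self.epi_faces, dtype=np.int64)
        self.segment_labels = np.asarray(self.segment_labels, dtype=np.int64)
        for v in ("apex_point", "base_centroid", "long_axis", "rv_pacing_site"):
            setattr(self, v, np.asarray(getattr(self, v), dtype=float))
        if self.segment_labels.shape[0] != self.endo_faces.shape[0]:
            raise ValueError("one label per endo face required")
        if self.segment_labels.min() < 1 or self.segment_labels.max() > 16:
            raise ValueError("segment labels must lie in 1..16")
        if np.linalg.norm(self.base_centroid - self.apex_point) <= 0:
            raise ValueError("apex-to-base distance must be positive")
        n = np.linalg.norm(self.long_axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            self.long_axis = self.long_axis / n

    @property
    def n_endo_vertices(self) -> int:
        return self.endo_vertices.shape[0]

    def face_centroids(self) -> np.ndarray:
        return self.endo_vertices[self.endo_faces].mean(axis=1)

    def segment_centroid(self, segment: int) -> np.ndarray:
        """Area-weighted centroid of an endocardial segment's faces."""
        mask = self.segment_labels == segment
        if not mask.any():
            raise ValueError(f"segment {segment} has no faces")
        tris = self.endo_vertices[self.endo_faces[mask]]
        areas = 0.5 * np.linalg.norm(
            np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
        )
        cent = tris.mean(axis=1)
        return (cent * areas[:, None]).sum(axis=0) / areas.sum()


@dataclass
class GroundTruth:
    """Generator-side truth used as the oracle in recovery tests."""

    thin_segments: frozenset
    scar_segments: frozenset
    true_mbf: dict  # segment -> mL/100 mL/min
    true_ttp: dict = field(default_factory=dict)  # segment -> phase fraction
    true_target_segments: frozenset = frozenset()
    ahr_class: dict = field(default_factory=dict)  # segment -> class
    ischemic: bool = False

    def __post_init__(self) -> None:
        self.thin_segments = frozenset(self.thin_segments)
        self.scar_segments = frozenset(self.scar_segments)
        self.true_target_segments = frozenset(self.true_target_segments)
        if self.true_target_segments & (self.thin_segments | self.scar_segments):
            raise ValueError("target segments must be neither thin nor scarred")


@dataclass
class MeshSequence:
    """Endocardial vertex positions over one cardiac cycle."""

    phases: np.ndarray  # (m,) fraction of RR, starting at 0
    vertex_positions: np.ndarray  # (m, n, 3) mm
    cycle_length: float  # ms

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.vertex_positions = np.asarray(self.vertex_positions, dtype=float)
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if not np.isfinite(self.vertex_positions).all():
            raise ValueError("vertex positions must be finite")
        if self.phases[0] != 0.0:
            raise ValueError("phase grid must start at 0")


@dataclass
class TransmitterCandidate:
    ics_id: int  # intercostal space, 4..6
    skin_entry_point: np.ndarray  # (3,) mm
    beam_axis: np.ndarray  # unit vector

    def __post_init__(self) -> None:
        self.skin_entry_point = np.asarray(self.skin_entry_point, dtype=float)
        self.beam_axis = np.asarray(self.beam_axis, dtype=float)
        n = np.linalg.norm(self.beam_axis)
        if n == 0:
            raise ValueError("beam axis must be non-zero")
        self.beam_axis = self.beam_axis / n


@dataclass
class ThoraxModel:
    ics_candidates: list  # of TransmitterCandidate
    chest_wall_origin: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ics_candidates) < 1:
            raise ValueError("at least one ICS candidate required")
        self.chest_wall_origin = np.asarray(self.chest_wall_origin, dtype=float)


@dataclass
class TACSet:
    """Arterial input function plus regional time-attenuation curves."""

    times: np.ndarray  # (t,) s, uniform grid
    aif: np.ndarray  # (t,) HU
    regional_curves: np.ndarray  # (16, t) HU, row i = segment i+1
    baseline_hu: float
    delayed_hu: Optional[np.ndarray] = None  # (16,) delayed-phase HU

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.aif = np.asarray(self.aif, dtype=float)
        self.regional_curves = np.atleast_2d(np.asarray(self.regional_curves, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.aif.shape[0] != self.times.shape[0]:
            raise ValueError("AIF length must match time grid")
        if self.regional_curves.shape[1] != self.times.shape[0]:
            raise ValueError("regional curves must match time grid")


@dataclass
class PerfusionResult:
    mbf: np.ndarray  # (16,) mL/100 mL/min, NaN where the fit failed
    pcbv: np.ndarray  # (16,) mL/100 mL
    avg_enhancement: np.ndarray  # (16,) HU
    hypoperfused: np.ndarray  # (16,) bool
    late_enhancement: Optional[np.ndarray] = None  # (16,) bool

    def to_frame(self) -> pd.DataFrame:
        data = {
            "mbf": self.mbf,
            "pcbv": self.pcbv,
            "avg_enhancement": self.avg_enhancement,
            "hypoperfused": self.hypoperfused,
        }
        if self.late_enhancement is not None:
            data["late_enhancement"] = self.late_enhancement
        return pd.DataFrame(data, index=pd.Index(range(1, 17), name="segment"))


@dataclass
class StrainCurves:
    """Per-segment deformation curves over the cycle (reference = phase 0)."""

    phases: np.ndarray  # (m,)
    area_change: np.ndarray  # (16, m) fractional
    circ_strain: np.ndarray  # (16, m)
    long_strain: np.ndarray  # (16, m)
    ttp_phase: np.ndarray  # (16,) NaN where flat
    ttp_ms: np.ndarray  # (16,)
    flat: np.ndarray  # (16,) bool
    peak_amplitude: np.ndarray  # (16,) peak-to-peak area change
    cycle_length: float  # ms


@dataclass
class ActivationMap:
    activation_time: np.ndarray  # (n,) ms per endo vertex; inf = unreached
    seg_mean: np.ndarray  # (16,) ms
    seg_max: np.ndarray  # (16,) ms
    latest_segment: int
    cv_map: np.ndarray  # (f,) m/s per endo face
    qlv: Optional[float] = None  # ms


@dataclass
class ThicknessMap:
    vertex_thickness: np.ndarray  # (n,) mm, NaN where the ray missed
    seg_thickness: np.ndarray  # (16,) mm summary (median by default)
    thin: np.ndarray  # (16,) bool, summary < threshold
    threshold_mm: float = 5.0


@dataclass
class HemoRecord:
    """Hemodynamic assessment of one tested endocardial segment."""

    segment: int
    segment_class: str  # target | nontarget_viable | scarred
    baseline_time: np.ndarray  # (k,) s
    baseline_pressure: np.ndarray  # (k,) mmHg
    paced_time: np.ndarray
    paced_pressure: np.ndarray
    reference_dpdt: float = np.nan  # mmHg/s
    paced_dpdt_mean: float = np.nan
    ahr: float = np.nan  # percent
    capture: bool = True

    def __post_init__(self) -> None:
        if self.segment_class not in ("target", "nontarget_viable", "scarred"):
            raise ValueError(f"unknown segment class {self.segment_class!r}")


@dataclass
class GroupStats:
    """Target vs non-target AHR comparison plus per-class summaries."""

    mean_target: float
    sd_target: float
    n_target: int
    mean_nontarget: float
    sd_nontarget: float
    n_nontarget: int
    mean_nontarget_viable: float
    sd_nontarget_viable: float
    n_nontarget_viable: int
    mean_scarred: float
    sd_scarred: float
    n_scarred: int
    mean_difference: float
    t_statistic: float
    p_value: float  # two-sided Welch t, target vs nontarget
    prop_over10_target: float
    prop_over10_nontarget: float
    fisher_p: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class CArmView:
    """C-arm projection geometry (point-source / pinhole model)."""

    rao_lao_deg: float = 0.0  # >0 = LAO
    cranial_caudal_deg: float = 0.0  # >0 = cranial
    source_to_detector_mm: float = 1050.0
    detector_size_mm: float = 300.0
    source_to_isocenter_mm: float = 700.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.rao_lao_deg <= 90.0):
            raise ValueError("RAO/LAO angle out of range")
        if not (-90.0 <= self.cranial_caudal_deg <= 90.0):
            raise ValueError("cranial/caudal angle out of range")
        if self.source_to_detector_mm <= 0 or self.detector_size_mm <= 0:
            raise ValueError("distances must be positive")
        if self.source_to_isocenter_mm <= 0:
            raise ValueError("source-to-isocenter must be positive")
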