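"""Seeded generator of complete synthetic patients.

Each patient is a truncated prolate-ellipsoid left ventricle (apex at the
origin, long axis along +z) with per-segment wall thickness, an
ischemic-or-not phenotype with scar segments, a cyclic contraction model
with per-segment time to peak, dynamic-perfusion time-attenuation curves
driven by a gamma-variate arterial input, candidate intercostal
transmitter windows on a schematic chest wall, and class-conditional
baseline/paced LV pressure traces.

Defaults reproduce the cohort-level statistics the analysis stages are
calibrated against: a mean of 4.8 (SD 3.5) segments per patient thinner
than 5 mm, an ischemic phenotype in 6/11 of patients, and acute
hemodynamic response distributions of 25.5 +/- 8.8 % (target),
15.4 +/- 8.0 % (viable non-target) and 5.9 +/- 4.0 % (scarred).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import aha
from .types import (
    GroundTruth,
    HemoRecord,
    LVGeometry,
    MeshSequence,
    ParameterError,
    TACSet,
    ThoraxModel,
    TransmitterCandidate,
)


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass
class AnatomyParams:
    endo_semi_axes: tuple = (25.0, 25.0, 80.0)  # mm, (a, b, c)
    truncation_fraction: float = 0.7  # keep apex..70% of the full long axis
    n_theta: int = 24  # latitude rows below the base ring
    n_phi: int = 36  # circumferential resolution
    thin_mean: float = 4.8  # cohort mean count of <5 mm segments
    thin_sd: float = 3.5
    thin_thickness_mm: tuple = (2.5, 4.5)
    normal_thickness_mm: tuple = (6.5, 11.0)
    ischemic_probability: float = 6.0 / 11.0
    scar_count_range: tuple = (2, 5)  # inclusive, ischemic patients
    scar_flow_fraction: float = 0.35  # scar MBF as a fraction of remote
    mbf_mean: float = 75.0  # mL/100 mL/min, healthy myocardium
    mbf_sd: float = 6.0


@dataclass
class MotionParams:
    n_phases: int = 20
    cycle_length_ms: float = 850.0
    viable_amplitude: float = 0.15  # peak fractional radial contraction
    amplitude_jitter: float = 0.02
    scar_amplitude: float = 0.01  # akinetic: below the flat-curve threshold
    ttp_base: float = 0.32  # earliest segmental time to peak (RR fraction)
    ttp_spread: float = 0.12  # septal-to-lateral delay span
    ttp_jitter: float = 0.01


@dataclass
class PerfusionGenParams:
    dt_s: float = 2.0
    duration_s: float = 60.0
    baseline_hu: float = 40.0
    aif_peak_hu: float = 300.0  # above baseline
    aif_delay_s: float = 6.0
    aif_time_to_peak_s: float = 8.0
    aif_alpha: float = 3.0
    tc_s: float = 6.0  # residue mean transit time
    tc_jitter_s: float = 1.0
    tissue_delay_s: float = 1.5
    noise_sd_hu: float = 1.0
    delayed_remote_hu: float = 30.0
    delayed_scar_hu: float = 55.0
    late_enhancement_sensitivity: float = 1.0 / 3.0  # fraction of ischemic
    # patients whose scar shows late enhancement (insensitive by design)


@dataclass
class ThoraxParams:
    count_probs: tuple = (0.36, 0.37, 0.27)  # P(1), P(2), P(3) ICSs
    n_candidates: int | None = None  # explicit override
    standoff_mm: float = 45.0  # chest wall clearance beyond the epicardium
    aim_segment: int = 5  # beam aimed near the basal inferolateral wall
    angle_jitter_deg: float = 5.0


@dataclass
class HemoGenParams:
    fs_hz: float = 500.0
    duration_s: float = 12.0
    heart_rate_bpm: float = 72.0
    baseline_dpdt: float = 800.0  # mmHg/s
    diastolic_mmhg: float = 12.0
    systole_fraction: float = 0.35
    beat_noise_frac: float = 0.01
    ectopy_rate: float = 0.05
    ectopy_scale: float = 1.6
    class_ahr: dict = field(
        default_factory=lambda: {
            "target": (25.5, 8.8),
            "nontarget_viable": (15.4, 8.0),
            "scarred": (5.9, 4.0),
        }
    )


@dataclass
class CohortParams:
    """Composition of the tested-segment sample within a patient."""

    n_nontarget_range: tuple = (2, 4)  # inclusive; targets add 2
    scar_test_prob: float = 0.482  # P(tested non-target is scar | ischemic)


# ---------------------------------------------------------------------------
# geometry


def _clipped_round_mean(mu: float, sd: float) -> float:
    """Expectation of round(clip(N(mu, sd), 0, 16))."""
    from scipy.stats import norm

    ks = np.arange(17)
    upper = norm.cdf((ks + 0.5 - mu) / sd)
    lower = norm.cdf((ks - 0.5 - mu) / sd)
    p = upper - lower
    p[0] = norm.cdf((0.5 - mu) / sd)
    p[16] = 1.0 - norm.cdf((15.5 - mu) / sd)
    return float(ks @ p)


def _latent_thin_mean(target: float, sd: float) -> float:
    """Latent normal mean whose clipped/rounded draw has mean ``target``."""
    if sd <= 0:
        return target
    lo, hi = target - 3.0 * sd, target + 3.0 * sd
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _clipped_round_mean(mid, sd) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ellipsoid_point(a, b, c, theta, phi):
    return np.array(
        [a * np.sin(theta) * np.cos(phi), b * np.sin(theta) * np.sin(phi), c * (1.0 - np.cos(theta))]
    )


def _build_surface(a, b, c, theta_max, n_theta, n_phi, radial_offset=None):
    """Triangulated truncated ellipsoid with outward-oriented winding.

    ``radial_offset`` maps a vertex index on the endo parameterization to an
    outward normal displacement (used to build the epi surface).
    """
    thetas = np.linspace(0.0, theta_max, n_theta + 1)[1:]
    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
    verts = [np.array([0.0, 0.0, 0.0])]
    for th in thetas:
        for ph in phis:
            verts.append(_ellipsoid_point(a, b, c, th, ph))
    verts = np.array(verts)
    faces = []
    # apex fan (outward normal points toward -z at the apex)
    for j in range(n_phi):
        faces.append((0, 1 + (j + 1) % n_phi, 1 + j))
    for i in range(n_theta - 1):
        r0 = 1 + i * n_phi
        r1 = 1 + (i + 1) * n_phi
        for j in range(n_phi):
            j1 = (j + 1) % n_phi
            faces.append((r0 + j, r0 + j1, r1 + j1))
            faces.append((r0 + j, r1 + j1, r1 + j))
    faces = np.array(faces, dtype=np.int64)
    if radial_offset is not None:
        normals = _vertex_normals(verts, faces)
        verts = verts + radial_offset[:, None] * normals
    return verts, faces


def _vertex_normals(verts, faces):
    """Area-weighted outward vertex normals (winding is outward)."""
    tri = verts[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    n = np.linalg.norm(vn, axis=1)
    n[n == 0] = 1.0
    return vn / n[:, None]


def _label_faces(verts, faces, z_max):
    cent = verts[faces].mean(axis=1)
    h = np.clip(cent[:, 2] / z_max, 0.0, 1.0)
    # canonical frame: lateral = +x, anterior = +y, septum at 180 deg
    ang = np.round(np.degrees(np.arctan2(cent[:, 1], cent[:, 0])) % 360.0, 6) % 360.0
    return np.array([aha.segment_of(a, hh) for a, hh in zip(ang, h)], dtype=np.int64)


def _vertex_segments(n_verts, faces, labels):
    """Assign each vertex the majority label of its incident faces
    (ties to the lowest AHA id)."""
    counts = np.zeros((n_verts, 17), dtype=np.int32)
    for f, lab in zip(faces, labels):
        for v in f:
            counts[v, lab] += 1
    return counts[:, 1:].argmax(axis=1) + 1


def generate_lv_geometry(params: AnatomyParams | None = None, seed=0):
    """Generate one synthetic LV anatomy and the anatomical ground truth.

    Returns ``(LVGeometry, GroundTruth)`` where the ground truth carries
    thin/scar segment sets and the true per-segment MBF; motion- and
    target-related fields are filled by :func:`generate_patient`.
    """
    params = params or AnatomyParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a, b, c = params.endo_semi_axes
    if min(a, b, c) <= 0:
        raise ParameterError("ellipsoid semi-axes must be positive")
    if params.thin_sd < 0 or not (0.0 <= params.ischemic_probability <= 1.0):
        raise ParameterError("thin_sd must be >= 0 and scar probability in [0, 1]")
    lo_t, hi_t = params.thin_thickness_mm
    lo_n, hi_n = params.normal_thickness_mm
    if lo_t <= 0 or lo_n <= 0:
        raise ParameterError("wall thickness bounds must be positive")

    # thin-segment draw calibrated to the cohort mean count; the latent
    # normal mean is adjusted so the clipped-and-rounded count has the
    # configured expectation despite the truncation at 0 and 16
    mu = _latent_thin_mean(params.thin_mean, params.thin_sd)
    k = int(np.round(np.clip(rng.normal(mu, params.thin_sd), 0.0, 16.0)))
    thin = frozenset(rng.choice(np.arange(1, 17), size=k, replace=False).tolist()) if k else frozenset()

    ischemic = bool(rng.random() < params.ischemic_probability)
    scar: frozenset = frozenset()
    if ischemic:
        # every ischemic patient carries a perfusion defect of 2-5
        # segments, preferentially coinciding with thinned segments
        m = int(rng.integers(params.scar_count_range[0], params.scar_count_range[1] + 1))
        chosen = list(
            rng.choice(sorted(thin), size=min(m, k), replace=False)
        ) if k else []
        if m > k:
            rest = [s for s in range(1, 17) if s not in thin]
            chosen += list(rng.choice(rest, size=m - k, replace=False))
        scar = frozenset(int(s) for s in chosen)

    seg_thickness = {}
    for s in range(1, 17):
        if s in thin:
            seg_thickness[s] = float(rng.uniform(lo_t, hi_t))
        else:
            seg_thickness[s] = float(rng.uniform(lo_n, hi_n))

    mbf_normal = rng.normal(params.mbf_mean, params.mbf_sd)
    true_mbf = {}
    for s in range(1, 17):
        base = max(30.0, rng.normal(mbf_normal, 4.0))
        if s in scar:
            base = params.scar_flow_fraction * mbf_normal
        if base < 0:
            raise ParameterError("negative MBF")
        true_mbf[s] = float(base)

    cos_max = 1.0 - 2.0 * params.truncation_fraction
    theta_max = float(np.arccos(cos_max))
    endo_v, endo_f = _build_surface(a, b, c, theta_max, params.n_theta, params.n_phi)
    z_max = c * (1.0 - cos_max)
    labels = _label_faces(endo_v, endo_f, z_max)
    vseg = _vertex_segments(len(endo_v), endo_f, labels)
    thickness_per_vertex = np.array([seg_thickness[s] for s in vseg])
    epi_v, epi_f = _build_surface(
        a, b, c, theta_max, params.n_theta, params.n_phi, radial_offset=thickness_per_vertex
    )

    # RV pacing site: endo vertex at the mid-septum (180 deg), mid height
    ang = np.degrees(np.arctan2(endo_v[:, 1], endo_v[:, 0])) % 360.0
    h = endo_v[:, 2] / z_max
    score = np.abs(ang - 180.0) + 50.0 * np.abs(h - 0.5)
    score[0] = np.inf  # never the apex vertex
    rv_site = endo_v[int(np.argmin(score))].copy()

    geom = LVGeometry(
        endo_vertices=endo_v,
        endo_faces=endo_f,
        epi_vertices=epi_v,
        epi_faces=epi_f,
        apex_point=np.zeros(3),
        base_centroid=np.array([0.0, 0.0, z_max]),
        long_axis=np.array([0.0, 0.0, 1.0]),
        rv_pacing_site=rv_site,
        segment_labels=labels,
    )
    gt = GroundTruth(
        thin_segments=thin,
        scar_segments=scar,
        true_mbf=true_mbf,
        ischemic=ischemic,
    )
    return geom, gt


# ---------------------------------------------------------------------------
# motion


def contraction_waveform(phases: np.ndarray, ttp: float, sigma: float = 0.12) -> np.ndarray:
    """Single-peak waveform on [0, 1): zero at phase 0, unit peak at ``ttp``.

    A Gaussian bump rebased so the reference phase carries zero
    deformation; symmetric about the peak, so discrete sampling recovers
    the peak phase without bias.
    """
    t = np.asarray(phases, dtype=float)
    g = np.exp(-((t - ttp) ** 2) / (2.0 * sigma**2))
    g0 = np.exp(-(ttp**2) / (2.0 * sigma**2))
    return (g - g0) / (1.0 - g0)


def generate_motion(
    geom: LVGeometry,
    ttp_by_segment: dict,
    amplitude_by_segment: dict,
    params: MotionParams | None = None,
) -> MeshSequence:
    """Displace each segment's vertices radially (toward the long axis)
    with a smooth contraction pulse peaking at the segment's true TTP."""
    params = params or MotionParams()
    for s, amp in amplitude_by_segment.items():
        if not (0.0 <= amp <= 0.5):
            raise ParameterError(f"amplitude {amp} for segment {s} outside [0, 0.5]")
    for s, tp in ttp_by_segment.items():
        if not (0.0 < tp < 1.0):
            raise ParameterError(f"TTP {tp} for segment {s} outside (0, 1)")

    phases = np.arange(params.n_phases) / params.n_phases
    apex = geom.apex_point
    axis = geom.long_axis
    rel = geom.endo_vertices - apex
    axial = rel @ axis
    radial = rel - axial[:, None] * axis

    # per-vertex parameters blended over incident faces: the wall deforms
    # continuously across segment borders
    n = geom.n_endo_vertices
    amp_sum = np.zeros(n)
    ttp_sum = np.zeros(n)
    cnt = np.zeros(n)
    for f, lab in zip(geom.endo_faces, geom.segment_labels):
        a = amplitude_by_segment.get(int(lab), 0.0)
        tp = ttp_by_segment.get(int(lab), 0.4)
        for v in f:
            amp_sum[v] += a
            ttp_sum[v] += tp
            cnt[v] += 1
    cnt[cnt == 0] = 1.0
    amp_v = amp_sum / cnt
    ttp_v = ttp_sum / cnt

    sigma = 0.12
    g0 = np.exp(-(ttp_v**2) / (2.0 * sigma**2))
    positions = np.empty((len(phases), n, 3))
    for i, ph in enumerate(phases):
        g = np.exp(-((ph - ttp_v) ** 2) / (2.0 * sigma**2))
        w = (g - g0) / (1.0 - g0)
        scale = 1.0 - amp_v * w
        positions[i] = apex + axial[:, None] * axis + radial * scale[:, None]
    return MeshSequence(phases=phases, vertex_positions=positions, cycle_length=params.cycle_length_ms)


def assign_true_ttp(gt: GroundTruth, params: MotionParams, rng) -> dict:
    """Per-segment true time to peak: septal segments contract first,
    lateral and basal segments last, mirroring RV-paced activation."""
    ttp = {}
    for s in range(1, 17):
        lat = aha.lateralness(s) / 180.0  # 0 at septum, 1 at lateral wall
        ring_h = {0: 5.0 / 6.0, 1: 0.5, 2: 1.0 / 6.0}[aha.SEGMENT_RING[s]]
        proxy = lat + 0.35 * (ring_h - 0.5)
        val = params.ttp_base + params.ttp_spread * proxy + rng.normal(0.0, params.ttp_jitter)
        ttp[s] = float(np.clip(val, 0.05, 0.95))
    return ttp


# ---------------------------------------------------------------------------
# perfusion forward model


def gamma_variate_aif(times, peak_hu, delay_s, time_to_peak_s, alpha):
    """Gamma-variate first-pass bolus, zero before ``delay_s``, peaking
    ``time_to_peak_s`` later with amplitude ``peak_hu``."""
    t = np.asarray(times, dtype=float) - delay_s
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / time_to_peak_s
    out[pos] = peak_hu * (x**alpha) * np.exp(alpha * (1.0 - x))
    return out


def generate_tacs(
    gt: GroundTruth, params: PerfusionGenParams | None = None, seed=0
) -> TACSet:
    """Regional tissue curves = MBF-scaled convolution of the AIF with an
    exponential residue, plus Gaussian HU noise, on the baseline offset."""
    from .perfusion import forward_tissue_curve  # model owned by the analysis side

    params = params or PerfusionGenParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params.dt_s <= 0:
        raise ParameterError("sampling interval must be positive")
    if params.noise_sd_hu < 0:
        raise ParameterError("noise SD must be >= 0")
    times = np.arange(0.0, params.duration_s + 1e-9, params.dt_s)
    aif_enh = gamma_variate_aif(
        times, params.aif_peak_hu, params.aif_delay_s, params.aif_time_to_peak_s, params.aif_alpha
    )
    curves = np.empty((16, len(times)))
    for s in range(1, 17):
        mbf = gt.true_mbf.get(s, 0.0)
        if mbf < 0:
            raise ParameterError("negative MBF")
        tc = max(1.0, params.tc_s + rng.normal(0.0, params.tc_jitter_s))
        clean = forward_tissue_curve(times, aif_enh, mbf, tc, params.tissue_delay_s)
        noise = rng.normal(0.0, params.noise_sd_hu, size=len(times)) if params.noise_sd_hu else 0.0
        curves[s - 1] = params.baseline_hu + clean + noise

    show_le = gt.ischemic and (rng.random() < params.late_enhancement_sensitivity)
    delayed = np.full(16, params.delayed_remote_hu)
    delayed += rng.normal(0.0, 1.0, size=16)
    if show_le:
        for s in gt.scar_segments:
            delayed[s - 1] = params.delayed_scar_hu + rng.normal(0.0, 1.0)
    return TACSet(
        times=times,
        aif=params.baseline_hu + aif_enh,
        regional_curves=curves,
        baseline_hu=params.baseline_hu,
        delayed_hu=delayed,
    )


# ---------------------------------------------------------------------------
# thorax / transmitter candidates


_ICS_LAYOUT = {  # ics id -> (height fraction of apex-base span, angle deg)
    4: (0.85, 40.0),
    5: (0.65, 20.0),
    6: (0.45, 0.0),
}


def generate_thorax(geom: LVGeometry, params: ThoraxParams | None = None, seed=0) -> ThoraxModel:
    """Place 1-3 intercostal transmitter candidates anterolateral to the
    LV, beams aimed near the basal inferolateral wall."""
    params = params or ThoraxParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params.n_candidates is not None:
        n = int(params.n_candidates)
        if not (1 <= n <= 3):
            raise ParameterError("1-3 candidate spaces supported")
    else:
        n = int(rng.choice([1, 2, 3], p=np.asarray(params.count_probs) / np.sum(params.count_probs)))
    if n == 3:
        ids = [4, 5, 6]
    elif n == 2:
        ids = sorted(rng.choice([4, 5, 6], size=2, replace=False).tolist())
    else:
        ids = [int(rng.choice([4, 5, 6], p=[0.2, 0.6, 0.2]))]

    z_max = float((geom.base_centroid - geom.apex_point) @ geom.long_axis)
    r_max = float(np.max(np.linalg.norm(geom.epi_vertices[:, :2], axis=1)))
    aim = geom.segment_centroid(params.aim_segment)
    cands = []
    for ics in ids:
        hf, ang = _ICS_LAYOUT[ics]
        ang = ang + rng.normal(0.0, 3.0)
        radius = r_max + params.standoff_mm + rng.normal(0.0, 3.0)
        entry = np.array(
            [radius * np.cos(np.radians(ang)), radius * np.sin(np.radians(ang)), hf * z_max]
        )
        axis = aim - entry
        # angular jitter about the aim direction
        jit = rng.normal(0.0, np.radians(params.angle_jitter_deg), size=2)
        perp1 = np.cross(axis, [0.0, 0.0, 1.0])
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(axis, perp1)
        perp2 /= np.linalg.norm(perp2)
        axis = axis / np.linalg.norm(axis) + jit[0] * perp1 + jit[1] * perp2
        cands.append(TransmitterCandidate(ics_id=ics, skin_entry_point=entry, beam_axis=axis))
    origin = np.mean([c.skin_entry_point for c in cands], axis=0)
    return ThoraxModel(ics_candidates=cands, chest_wall_origin=origin)


# ---------------------------------------------------------------------------
# pressure traces


def _pressure_trace(rng, dpdt_target, params: HemoGenParams):
    """Beat train whose per-beat dP/dt_max averages ``dpdt_target``.

    Each beat is a half-sine-squared systolic upstroke on a diastolic
    baseline; dP/dt_max of one beat is amplitude * pi / T_sys, so the
    amplitude is set from the target and perturbed with beat-to-beat noise
    and occasional ectopic (outlier) beats.
    """
    fs = params.fs_hz
    period = 60.0 / params.heart_rate_bpm
    t_sys = params.systole_fraction * period
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    p = np.full(n, params.diastolic_mmhg)
    n_beats = int(np.ceil(params.duration_s / period))
    for k in range(n_beats):
        amp = dpdt_target * t_sys / np.pi
        amp *= 1.0 + rng.normal(0.0, params.beat_noise_frac)
        if rng.random() < params.ectopy_rate:
            amp *= params.ectopy_scale
        t0 = k * period
        mask = (t >= t0) & (t < t0 + t_sys)
        p[mask] += amp * np.sin(np.pi * (t[mask] - t0) / t_sys) ** 2
    return t, p


def generate_pressure_traces(
    ahr_class: str, params: HemoGenParams | None = None, seed=0, segment: int = 0
) -> tuple[HemoRecord, float]:
    """Baseline and biventricular-paced pressure traces for one tested
    segment; the realized AHR is drawn from the class-conditional normal.

    Returns the raw (un-analyzed) record and the drawn true AHR (%).
    """
    params = params or HemoGenParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if ahr_class not in ("target", "nontarget_viable", "scarred"):
        raise ParameterError(f"unknown AHR class {ahr_class!r}")
    if params.baseline_dpdt <= 0:
        raise ParameterError("baseline dP/dt_max must be positive")
    if params.duration_s < 10.0:
        raise ParameterError("window length must be at least 10 s")
    mean, sd = params.class_ahr[ahr_class]
    true_ahr = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
    bt, bp = _pressure_trace(rng, params.baseline_dpdt, params)
    pt, pp = _pressure_trace(rng, params.baseline_dpdt * (1.0 + true_ahr / 100.0), params)
    rec = HemoRecord(
        segment=segment,
        segment_class=ahr_class,
        baseline_time=bt,
        baseline_pressure=bp,
        paced_time=pt,
        paced_pressure=pp,
    )
    return rec, true_ahr


# ---------------------------------------------------------------------------
# full patient


@dataclass
class SyntheticPatient:
    geom: LVGeometry
    gt: GroundTruth
    motion: MeshSequence
    tacs: TACSet
    thorax: ThoraxModel
    amplitude_by_segment: dict


def generate_patient(
    seed: int = 0,
    anatomy: AnatomyParams | None = None,
    motion: MotionParams | None = None,
    perfusion: PerfusionGenParams | None = None,
    thorax: ThoraxParams | None = None,
) -> SyntheticPatient:
    """Assemble one complete synthetic patient from a single seed.

    Fills the remaining ground-truth fields: true TTP per segment and the
    true target pair obtained by applying the documented rank-sum selection
    rule to the generator's own lateness fields.
    """
    from . import planner

    anatomy = anatomy or AnatomyParams()
    motion = motion or MotionParams()
    perfusion = perfusion or PerfusionGenParams()
    thorax = thorax or ThoraxParams()
    rng = np.random.default_rng(seed)
    geom, gt = generate_lv_geometry(anatomy, rng)
    gt.true_ttp = assign_true_ttp(gt, motion, rng)

    amps = {}
    for s in range(1, 17):
        if s in gt.scar_segments:
            amps[s] = motion.scar_amplitude
        else:
            a = motion.viable_amplitude + rng.normal(0.0, motion.amplitude_jitter)
            amps[s] = float(np.clip(a, 0.05, 0.5))
    seq = generate_motion(geom, gt.true_ttp, amps, motion)
    tacs = generate_tacs(gt, perfusion, rng)
    thx = generate_thorax(geom, thorax, rng)

    # true targets: the documented selection rule on the true features
    viable = [s for s in range(1, 17) if s not in gt.thin_segments and s not in gt.scar_segments]
    act_proxy = {s: aha.lateralness(s) / 180.0 + 0.35 * ({0: 5.0 / 6.0, 1: 0.5, 2: 1.0 / 6.0}[aha.SEGMENT_RING[s]] - 0.5) for s in range(1, 17)}
    try:
        targets = planner.rank_sum_targets(
            {s: gt.true_ttp[s] for s in viable}, {s: act_proxy[s] for s in viable}
        )
    except ValueError:
        targets = frozenset()
    gt.true_target_segments = frozenset(targets)
    gt.ahr_class = {
        s: (
            "target"
            if s in gt.true_target_segments
            else ("scarred" if s in gt.scar_segments else "nontarget_viable")
        )
        for s in range(1, 17)
    }
    return SyntheticPatient(
        geom=geom, gt=gt, motion=seq, tacs=tacs, thorax=thx, amplitude_by_segment=amps
    )
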