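"""dP/dt_max extraction, acute hemodynamic response, group comparisons.

dP/dt_max is the per-beat maximum of the centered-difference pressure
derivative; beats are delimited by diastolic pressure minima and beats
whose dP/dt_max lies beyond 3 SD of the window's beats (ectopy) are
excluded before averaging.  AHR is the percent change from the reference
(baseline) dP/dt_max to the mean biventricular-paced dP/dt_max.

Group comparison: two-sided Welch t-test of AHR between target and
non-target segments, plus a Fisher exact test on the 2x2 table of
(group x AHR > 10 %).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .types import GroupStats, HemoRecord


@dataclass
class BeatPolicy:
    min_rate_hz: float = 100.0
    outlier_sd: float = 3.0
    min_beats: int = 3
    ahr_threshold_pct: float = 10.0


def beat_dpdt_values(time_s, pressure_mmhg, policy: BeatPolicy | None = None) -> np.ndarray:
    """Per-beat dP/dt_max (mmHg/s) before outlier rejection."""
    policy = policy or BeatPolicy()
    t = np.asarray(time_s, dtype=float)
    p = np.asarray(pressure_mmhg, dtype=float)
    dt = np.median(np.diff(t))
    fs = 1.0 / dt
    if fs < policy.min_rate_hz:
        raise ValueError(f"sampling rate {fs:.0f} Hz below {policy.min_rate_hz} Hz")
    if t[-1] - t[0] < 10.0:
        raise ValueError("window shorter than 10 s")
    if np.ptp(p) < 1e-9:
        raise ValueError("beat detection failed: constant pressure trace")
    dpdt = np.gradient(p, t)
    # beats delimited by pressure minima
    inv = -p
    min_dist = max(1, int(0.4 * fs * 60.0 / 200.0))  # >= 0.12 s apart
    mins, _ = signal.find_peaks(inv, distance=min_dist, prominence=0.1 * np.ptp(p))
    edges = np.concatenate([[0], mins, [len(p) - 1]])
    vals = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 3:
            continue
        seg = dpdt[a:b]
        if seg.max() > 0:
            vals.append(float(seg.max()))
    if len(vals) < policy.min_beats:
        raise ValueError("beat detection failed: fewer than 3 beats")
    return np.array(vals)


def dpdt_max(time_s, pressure_mmhg, policy: BeatPolicy | None = None):
    """Mean dP/dt_max over retained (non-ectopic) beats.

    Returns (mean, retained per-beat values).  Ectopic beats are excluded
    iteratively at the 3-SD level.
    """
    policy = policy or BeatPolicy()
    vals = beat_dpdt_values(time_s, pressure_mmhg, policy)
    keep = np.ones(len(vals), dtype=bool)
    # 3-sigma rejection with a robust (median/MAD) scale, so several
    # ectopic beats in one window cannot inflate the threshold and mask
    # each other; iterated to a fixed point
    for _ in range(8):
        kept = vals[keep]
        center = np.median(kept)
        mad = np.median(np.abs(kept - center))
        scale = 1.4826 * mad if mad > 0 else kept.std(ddof=1) if kept.size > 1 else 0.0
        if scale == 0:
            break
        new = np.abs(vals - center) <= policy.outlier_sd * scale
        if new.sum() < policy.min_beats or np.array_equal(new, keep):
            break
        keep = new
    return float(vals[keep].mean()), vals[keep]


def compute_ahr(baseline_dpdt: float, paced_dpdt_mean: float) -> float:
    """AHR (%) = 100 * (paced - reference) / reference."""
    if baseline_dpdt <= 0:
        raise ValueError("reference dP/dt_max must be positive")
    return 100.0 * (paced_dpdt_mean - baseline_dpdt) / baseline_dpdt


def analyze_record(rec: HemoRecord, policy: BeatPolicy | None = None) -> HemoRecord:
    """Fill reference/paced dP/dt_max and AHR of a raw record in place."""
    rec.reference_dpdt, _ = dpdt_max(rec.baseline_time, rec.baseline_pressure, policy)
    rec.paced_dpdt_mean, _ = dpdt_max(rec.paced_time, rec.paced_pressure, policy)
    if rec.capture:
        rec.ahr = compute_ahr(rec.reference_dpdt, rec.paced_dpdt_mean)
    else:
        rec.ahr = np.nan
    return rec


def compare_groups(records, policy: BeatPolicy | None = None) -> GroupStats:
    """Target vs non-target AHR comparison over analyzed records."""
    policy = policy or BeatPolicy()
    ahr = {"target": [], "nontarget_viable": [], "scarred": []}
    for r in records:
        if r.capture and np.isfinite(r.ahr):
            ahr[r.segment_class].append(r.ahr)
    tgt = np.array(ahr["target"])
    ntv = np.array(ahr["nontarget_viable"])
    scr = np.array(ahr["scarred"])
    non = np.concatenate([ntv, scr]) if (ntv.size or scr.size) else np.array([])
    if tgt.size < 2 or non.size < 2:
        raise ValueError("need at least 2 records per compared group")

    t_stat, p = stats.ttest_ind(tgt, non, equal_var=False)
    thr = policy.ahr_threshold_pct
    table = [
        [int((tgt > thr).sum()), int((tgt <= thr).sum())],
        [int((non > thr).sum()), int((non <= thr).sum())],
    ]
    _, fisher_p = stats.fisher_exact(table)

    def _m(x):
        return (float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else np.nan, int(x.size))

    mt, st_, nt = _m(tgt)
    mn, sn, nn = _m(non)
    mv, sv, nv = _m(ntv) if ntv.size else (np.nan, np.nan, 0)
    ms, ss, ns = _m(scr) if scr.size else (np.nan, np.nan, 0)
    return GroupStats(
        mean_target=mt,
        sd_target=st_,
        n_target=nt,
        mean_nontarget=mn,
        sd_nontarget=sn,
        n_nontarget=nn,
        mean_nontarget_viable=mv,
        sd_nontarget_viable=sv,
        n_nontarget_viable=nv,
        mean_scarred=ms,
        sd_scarred=ss,
        n_scarred=ns,
        mean_difference=mt - mn,
        t_statistic=float(t_stat),
        p_value=float(p),
        prop_over10_target=float((tgt > thr).mean()),
        prop_over10_nontarget=float((non > thr).mean()),
        fisher_p=float(fisher_p),
    )
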