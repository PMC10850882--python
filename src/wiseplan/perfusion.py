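"""Dynamic-perfusion quantification from time-attenuation curves.

The tissue curve is modeled as a single-compartment system driven by the
arterial input function (AIF):

    C_tissue(t) = MBF * (AIF (*) R)(t - t0),   R(t) = exp(-t / T_c)

with MBF in mL/100 mL/min (converted internally to a per-second flow
fraction), T_c the mean transit time of the exponential residue and t0 a
bolus-arrival delay.  Perfused capillary blood volume follows from the
central-volume principle, PCBV = MBF * T_c (flow times mean transit time),
reported in mL/100 mL.  Average enhancement is the time average of the
baseline-subtracted tissue curve.

Hypoperfused segments (the scar surrogate) are flagged relative to a
remote reference: a segment is hypoperfused when its MBF falls below a
configurable fraction of the median MBF of the remaining segments,
iterated to a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .types import PerfusionResult, TACSet

MBF_TO_PER_SECOND = 1.0 / (100.0 * 60.0)  # mL/100 mL/min -> mL/mL/s


def forward_tissue_curve(times, aif_enhancement, mbf, tc_s, t0_s=0.0):
    """Forward model: baseline-subtracted tissue enhancement (HU).

    ``aif_enhancement`` is the AIF above baseline on the same uniform grid.
    """
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0]
    residue = np.exp(-(times - times[0]) / tc_s)
    conv = np.convolve(aif_enhancement, residue)[: len(times)] * dt
    shifted = np.interp(times - t0_s, times, conv, left=0.0, right=conv[-1])
    return mbf * MBF_TO_PER_SECOND * shifted


@dataclass
class FitConfig:
    tc_bounds_s: tuple = (1.0, 20.0)
    t0_bounds_s: tuple = (0.0, 5.0)
    grid_tc: int = 12
    grid_t0: int = 6
    mbf_max: float = 500.0


@dataclass
class HypoperfusionPolicy:
    fraction: float = 0.6  # flag when MBF < fraction * remote median
    absolute_floor: float = 5.0  # mL/100 mL/min; guards the remote reference
    max_iter: int = 16


@dataclass
class LateEnhancementPolicy:
    margin: float = 0.5  # flag when delayed HU > (1 + margin) * remote median


def _fit_one(times, aif_enh, tissue_enh, cfg: FitConfig):
    """Grid-initialized bounded least squares for (MBF, T_c, t0)."""
    dt = times[1] - times[0]
    best = None
    tcs = np.linspace(cfg.tc_bounds_s[0], cfg.tc_bounds_s[1], cfg.grid_tc)
    t0s = np.linspace(cfg.t0_bounds_s[0], cfg.t0_bounds_s[1], cfg.grid_t0)
    for tc in tcs:
        residue = np.exp(-(times - times[0]) / tc)
        conv = np.convolve(aif_enh, residue)[: len(times)] * dt
        for t0 in t0s:
            shape = np.interp(times - t0, times, conv, left=0.0, right=conv[-1])
            denom = float(shape @ shape)
            if denom <= 0:
                continue
            k = max(0.0, float(shape @ tissue_enh) / denom)
            sse = float(np.sum((tissue_enh - k * shape) ** 2))
            if best is None or sse < best[0]:
                best = (sse, k / MBF_TO_PER_SECOND, tc, t0)
    if best is None:
        raise RuntimeError("degenerate AIF")
    _, mbf0, tc0, t00 = best

    def resid(p):
        return forward_tissue_curve(times, aif_enh, p[0], p[1], p[2]) - tissue_enh

    sol = least_squares(
        resid,
        x0=[mbf0, tc0, t00],
        bounds=([0.0, cfg.tc_bounds_s[0], cfg.t0_bounds_s[0]],
                [cfg.mbf_max, cfg.tc_bounds_s[1], cfg.t0_bounds_s[1]]),
        xtol=1e-12,
        ftol=1e-12,
    )
    if not sol.success:
        raise RuntimeError("fit did not converge")
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])


def fit_compartment_model(tac: TACSet, cfg: FitConfig | None = None) -> PerfusionResult:
    """Fit the compartment model per segment; returns MBF, PCBV and
    average enhancement.  Non-convergent segments carry NaN and a warning
    is emitted (never a silent zero)."""
    cfg = cfg or FitConfig()
    if len(tac.times) < 10:
        raise ValueError("at least 10 time points required")
    aif_enh = tac.aif - tac.baseline_hu
    if aif_enh.max() <= 3.0 * max(1e-9, np.abs(aif_enh[0])):
        raise ValueError("AIF peak not distinguishable from baseline")
    mbf = np.full(16, np.nan)
    pcbv = np.full(16, np.nan)
    avg_enh = np.full(16, np.nan)
    for s in range(16):
        tissue_enh = tac.regional_curves[s] - tac.baseline_hu
        avg_enh[s] = float(np.mean(tissue_enh))
        # a flat curve is zero flow, not a failed fit
        if np.ptp(tissue_enh) < 1e-9 or np.max(np.abs(tissue_enh)) < 1e-9:
            mbf[s] = 0.0
            pcbv[s] = 0.0
            continue
        try:
            m, tc, _ = _fit_one(tac.times, aif_enh, tissue_enh, cfg)
        except RuntimeError as exc:
            warnings.warn(f"segment {s + 1}: compartment fit failed ({exc})", stacklevel=2)
            continue
        mbf[s] = m
        pcbv[s] = m * tc / 60.0  # mL/100 mL
    return PerfusionResult(
        mbf=mbf, pcbv=pcbv, avg_enhancement=avg_enh, hypoperfused=np.zeros(16, dtype=bool)
    )


def classify_hypoperfusion(
    result: PerfusionResult, policy: HypoperfusionPolicy | None = None
) -> np.ndarray:
    """Iterative remote-reference thresholding of the MBF map.

    Flags are recomputed against the median MBF of currently-unflagged
    segments until a fixed point; deterministic given the inputs.
    """
    policy = policy or HypoperfusionPolicy()
    mbf = np.asarray(result.mbf, dtype=float)
    valid = np.isfinite(mbf)
    if valid.sum() < 3:
        raise ValueError("need at least 3 segments with valid MBF")
    flags = np.zeros(16, dtype=bool)
    for _ in range(policy.max_iter):
        remote = mbf[valid & ~flags]
        if remote.size == 0 or np.median(remote) < policy.absolute_floor:
            raise ValueError("no remote reference: all segments below the absolute floor")
        thr = policy.fraction * np.median(remote)
        new = valid & (mbf < thr)
        if np.array_equal(new, flags):
            break
        flags = new
    result.hypoperfused = flags
    return flags


def detect_late_enhancement(
    delayed_hu, policy: LateEnhancementPolicy | None = None
) -> np.ndarray:
    """Advisory late-enhancement flag: delayed HU above the remote median
    by the configured margin."""
    policy = policy or LateEnhancementPolicy()
    vals = np.asarray(delayed_hu, dtype=float)
    if vals.ndim != 1 or vals.size != 16:
        raise ValueError("one delayed-phase value per segment required")
    flags = np.zeros(16, dtype=bool)
    for _ in range(8):
        remote = np.median(vals[~flags]) if (~flags).any() else np.median(vals)
        new = vals > (1.0 + policy.margin) * remote
        if np.array_equal(new, flags):
            break
        flags = new
    return flags


def analyze(tac: TACSet, fit_cfg=None, hypo_policy=None, le_policy=None) -> PerfusionResult:
    """Full perfusion stage: fit, hypoperfusion flags, late enhancement."""
    res = fit_compartment_model(tac, fit_cfg)
    classify_hypoperfusion(res, hypo_policy)
    if tac.delayed_hu is not None:
        res.late_enhancement = detect_late_enhancement(tac.delayed_hu, le_policy)
    return res
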