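"""End-to-end cohort pipeline: generate -> perfusion -> mechanics ->
activation -> anatomy -> planner -> hemodynamics, per patient, with
cohort-level group statistics at the end.

A stage failure marks the patient as failed in the manifest and the run
continues; the cohort statistics pool the remaining patients.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hemodynamics, io, mechanics
from . import activation as activation_mod
from . import anatomy as anatomy_mod
from . import perfusion as perfusion_mod
from . import planner as planner_mod
from . import synthetic_heart as sh
from .types import GroupStats, HemoRecord

log = logging.getLogger("wiseplan")


@dataclass
class PipelineConfig:
    seed: int = 7
    n_patients: int = 10
    anatomy: sh.AnatomyParams = field(default_factory=sh.AnatomyParams)
    motion: sh.MotionParams = field(default_factory=sh.MotionParams)
    perfusion_gen: sh.PerfusionGenParams = field(default_factory=sh.PerfusionGenParams)
    thorax: sh.ThoraxParams = field(default_factory=sh.ThoraxParams)
    hemo: sh.HemoGenParams = field(default_factory=sh.HemoGenParams)
    cohort: sh.CohortParams = field(default_factory=sh.CohortParams)
    fit: perfusion_mod.FitConfig = field(default_factory=perfusion_mod.FitConfig)
    hypoperfusion: perfusion_mod.HypoperfusionPolicy = field(
        default_factory=perfusion_mod.HypoperfusionPolicy
    )
    thickness: anatomy_mod.ThicknessPolicy = field(default_factory=anatomy_mod.ThicknessPolicy)
    conduction: activation_mod.ConductionParams = field(default_factory=activation_mod.ConductionParams)
    acoustic: planner_mod.AcousticModel = field(default_factory=planner_mod.AcousticModel)
    flat_threshold: float = mechanics.DEFAULT_FLAT_THRESHOLD
    thickness_subsample: int = 40
    output_dir: str | None = None
    make_plots: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            val = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "anatomy", "motion", "perfusion_gen", "thorax", "hemo", "cohort",
                "fit", "hypoperfusion", "thickness", "conduction", "acoustic",
            ):
                sub = cls.__dataclass_fields__[f.name].default_factory()  # type: ignore
                for k, v in val.items():
                    cur = getattr(sub, k)
                    if isinstance(cur, tuple):
                        v = tuple(v)
                    elif isinstance(cur, dict):
                        v = {
                            kk: tuple(vv) if isinstance(vv, list) else vv
                            for kk, vv in v.items()
                        }
                    setattr(sub, k, v)
                val = sub
            kwargs[f.name] = val
        return cls(**kwargs)


@dataclass
class PatientResult:
    patient_id: int
    seed: int
    ok: bool = False
    error: str | None = None
    patient: sh.SyntheticPatient | None = None
    thickness: object | None = None
    perf: object | None = None
    strain: object | None = None
    act: object | None = None
    features: pd.DataFrame | None = None
    targets: tuple | None = None
    transmitter_ranking: list | None = None
    acoustic_map: pd.DataFrame | None = None
    adequate_coverage: bool | None = None
    qlv_ms: float | None = None
    records: list = field(default_factory=list)


@dataclass
class CohortResult:
    config: PipelineConfig
    patients: list
    stats: GroupStats | None
    n_failed: int


def run_patient(cfg: PipelineConfig, patient_id: int, seed: int) -> PatientResult:
    res = PatientResult(patient_id=patient_id, seed=seed)
    rng = np.random.default_rng(seed)
    t0 = time.perf_counter()
    try:
        pat = sh.generate_patient(
            seed=rng,
            anatomy=cfg.anatomy,
            motion=cfg.motion,
            perfusion=cfg.perfusion_gen,
            thorax=cfg.thorax,
        )
        res.patient = pat
        geom = pat.geom

        labels = anatomy_mod.parcellate_aha(geom)
        geom.segment_labels = labels
        res.thickness = anatomy_mod.compute_wall_thickness(
            geom, cfg.thickness, subsample=cfg.thickness_subsample
        )
        res.perf = perfusion_mod.analyze(pat.tacs, cfg.fit, cfg.hypoperfusion)
        res.strain = mechanics.compute_strain_curves(
            pat.motion, geom.endo_faces, labels, geom.long_axis, cfg.flat_threshold
        )
        scar_meas = {s for s in range(1, 17) if res.perf.hypoperfused[s - 1]}
        res.act = activation_mod.simulate_activation(
            geom, geom.rv_pacing_site, cfg.conduction, scar_segments=scar_meas
        )
        res.features = planner_mod.build_feature_table(res.thickness, res.perf, res.strain, res.act)
        res.targets = planner_mod.select_target_segments(res.features)
        res.qlv_ms = activation_mod.compute_qlv(
            res.act, geom, geom.segment_centroid(res.targets[0])
        )
        ranking, amap, adequate = planner_mod.rank_transmitter_sites(
            pat.thorax, res.targets, geom, cfg.acoustic
        )
        res.transmitter_ranking = ranking
        res.acoustic_map = amap
        res.adequate_coverage = adequate

        res.records = _test_segments(cfg, pat, res.targets, rng)
        res.ok = True
    except Exception as exc:  # stage failure: record, keep the cohort going
        res.error = f"{type(exc).__name__}: {exc}"
        log.warning("patient %d failed: %s", patient_id, res.error)
    log.info("patient %d done in %.2f s", patient_id, time.perf_counter() - t0)
    return res


def _test_segments(cfg: PipelineConfig, pat: sh.SyntheticPatient, targets, rng):
    """Choose the tested segments (2 targets + 2-4 non-targets) and run
    the hemodynamic protocol on each."""
    gt = pat.gt
    lo, hi = cfg.cohort.n_nontarget_range
    n_non = int(rng.integers(lo, hi + 1))
    viable_pool = [
        s
        for s in range(1, 17)
        if s not in targets and s not in gt.thin_segments and s not in gt.scar_segments
    ]
    scar_pool = sorted(gt.scar_segments)
    rng.shuffle(viable_pool)
    rng.shuffle(scar_pool)
    tested = [(t, "target") for t in targets]
    for _ in range(n_non):
        take_scar = gt.ischemic and scar_pool and rng.random() < cfg.cohort.scar_test_prob
        if take_scar:
            tested.append((scar_pool.pop(), "scarred"))
        elif viable_pool:
            tested.append((viable_pool.pop(), "nontarget_viable"))
        elif scar_pool:
            tested.append((scar_pool.pop(), "scarred"))

    records = []
    for seg, cls in tested:
        rec, _ = sh.generate_pressure_traces(cls, cfg.hemo, rng, segment=int(seg))
        hemodynamics.analyze_record(rec)
        records.append(rec)
    return records


def run_pipeline(cfg: PipelineConfig | None = None) -> CohortResult:
    """Run the full cohort and, when an output directory is configured,
    write every intermediate artifact plus a manifest."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=cfg.n_patients)
    patients = [run_patient(cfg, i, int(s)) for i, s in enumerate(seeds)]
    n_failed = sum(1 for p in patients if not p.ok)
    records = [r for p in patients if p.ok for r in p.records]
    stats = None
    if records:
        try:
            stats = hemodynamics.compare_groups(records)
        except ValueError as exc:
            log.warning("cohort statistics unavailable: %s", exc)
    result = CohortResult(config=cfg, patients=patients, stats=stats, n_failed=n_failed)
    if cfg.output_dir:
        write_cohort(result, Path(cfg.output_dir))
    if n_failed == cfg.n_patients:
        raise RuntimeError("all patients failed")
    return result


def records_frame(result: CohortResult) -> pd.DataFrame:
    rows = []
    for p in result.patients:
        if not p.ok:
            continue
        for r in p.records:
            rows.append(
                {
                    "patient": p.patient_id,
                    "segment": r.segment,
                    "class": r.segment_class,
                    "reference_dpdt": r.reference_dpdt,
                    "paced_dpdt_mean": r.paced_dpdt_mean,
                    "ahr_pct": r.ahr,
                    "capture": r.capture,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(result: CohortResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(out / "config.json", result.config.to_dict())
    manifest = {"seed": result.config.seed, "patients": []}
    for p in result.patients:
        pdir = out / f"patient_{p.patient_id:02d}"
        entry = {"id": p.patient_id, "seed": p.seed, "ok": p.ok, "error": p.error, "files": []}
        if p.ok:
            pdir.mkdir(exist_ok=True)
            g = p.patient.geom
            io.write_vtk_polydata(
                pdir / "endo.vtk",
                g.endo_vertices,
                g.endo_faces,
                point_data={"activation_ms": p.act.activation_time},
                cell_data={"segment": g.segment_labels},
            )
            io.write_vtk_polydata(pdir / "epi.vtk", g.epi_vertices, g.epi_faces)
            io.write_off(pdir / "endo.off", g.endo_vertices, g.endo_faces)
            io.write_tac_csv(pdir / "tacs.csv", p.patient.tacs)
            p.features.to_csv(pdir / "features.csv")
            p.perf.to_frame().to_csv(pdir / "perfusion.csv")
            p.acoustic_map.to_csv(pdir / "acoustic_map.csv", index=False)
            io.write_json(
                pdir / "targets.json",
                {
                    "targets": list(p.targets),
                    "transmitter_ranking": p.transmitter_ranking,
                    "adequate_coverage": p.adequate_coverage,
                    "qlv_ms": p.qlv_ms,
                    "ground_truth": {
                        "thin": sorted(p.patient.gt.thin_segments),
                        "scar": sorted(p.patient.gt.scar_segments),
                        "true_targets": sorted(p.patient.gt.true_target_segments),
                    },
                },
            )
            entry["files"] = sorted(f.name for f in pdir.iterdir())
            if result.config.make_plots:
                from . import report

                report.render_bullseye(
                    p.features["activation_ms"].to_numpy(),
                    path=pdir / "activation_bullseye.svg",
                    title="activation time (ms)",
                )
                entry["files"].append("activation_bullseye.svg")
        manifest["patients"].append(entry)
    df = records_frame(result)
    df.to_csv(out / "hemo_records.csv", index=False)
    manifest["files"] = ["config.json", "hemo_records.csv"]
    if result.stats is not None:
        io.write_json(out / "cohort_stats.json", result.stats.to_dict())
        manifest["files"].append("cohort_stats.json")
    io.write_json(out / "manifest.json", manifest)
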