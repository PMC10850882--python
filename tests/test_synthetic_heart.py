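"""Generator contracts: determinism, calibration, ground-truth
consistency, and the forward models the analysis stages invert."""

import numpy as np
import pytest

from wiseplan import aha, perfusion
from wiseplan import synthetic_heart as sh
from wiseplan.types import ParameterError


def test_seed_determinism_bytewise():
    a = sh.generate_patient(seed=11)
    b = sh.generate_patient(seed=11)
    assert np.array_equal(a.geom.endo_vertices, b.geom.endo_vertices)
    assert np.array_equal(a.geom.epi_vertices, b.geom.epi_vertices)
    assert a.gt.thin_segments == b.gt.thin_segments
    assert a.gt.scar_segments == b.gt.scar_segments
    assert a.gt.true_ttp == b.gt.true_ttp
    assert np.array_equal(a.motion.vertex_positions, b.motion.vertex_positions)
    assert np.array_equal(a.tacs.regional_curves, b.tacs.regional_curves)


def test_geometry_invariants():
    geom, gt = sh.generate_lv_geometry(seed=5)
    assert geom.segment_labels.min() >= 1 and geom.segment_labels.max() <= 16
    assert len(np.unique(geom.segment_labels)) == 16
    span = np.linalg.norm(geom.base_centroid - geom.apex_point)
    assert span > 0
    # RV pacing site sits on a septal-labeled face
    d = np.linalg.norm(geom.endo_vertices - geom.rv_pacing_site, axis=1)
    vidx = int(np.argmin(d))
    septal_faces = [
        lab for f, lab in zip(geom.endo_faces, geom.segment_labels) if vidx in f
    ]
    assert any(s in (2, 3, 8, 9) for s in septal_faces)


def test_thin_count_degenerate_and_calibrated():
    p = sh.AnatomyParams(thin_mean=0.0, thin_sd=0.0)
    geom, gt = sh.generate_lv_geometry(p, seed=0)
    assert gt.thin_segments == frozenset()
    # expectation of the clipped/rounded draw is bias-corrected
    assert sh._clipped_round_mean(sh._latent_thin_mean(4.8, 3.5), 3.5) == pytest.approx(4.8, abs=1e-6)
    seeds = np.random.default_rng(3).integers(0, 2**31 - 1, size=300)
    counts = [len(sh.generate_lv_geometry(seed=int(s))[1].thin_segments) for s in seeds]
    assert np.mean(counts) == pytest.approx(4.8, abs=3.0 * 3.5 / np.sqrt(300))


def test_ground_truth_consistency_over_seeds():
    for seed in range(12):
        pat = sh.generate_patient(seed=seed)
        gt = pat.gt
        assert not (gt.true_target_segments & (gt.thin_segments | gt.scar_segments))
        normal = np.median([gt.true_mbf[s] for s in range(1, 17) if s not in gt.scar_segments])
        for s in gt.scar_segments:
            assert gt.true_mbf[s] < 0.5 * normal
            assert pat.amplitude_by_segment[s] < 0.05
        assert set(gt.ahr_class) == set(range(1, 17))


def test_anatomy_parameter_errors():
    with pytest.raises(ParameterError):
        sh.generate_lv_geometry(sh.AnatomyParams(endo_semi_axes=(25, 25, -1)), seed=0)
    with pytest.raises(ParameterError):
        sh.generate_lv_geometry(sh.AnatomyParams(thin_thickness_mm=(0.0, 4.0)), seed=0)
    with pytest.raises(ParameterError):
        sh.generate_lv_geometry(sh.AnatomyParams(ischemic_probability=1.5), seed=0)


def test_motion_zero_amplitude_is_static():
    geom, _ = sh.generate_lv_geometry(seed=2)
    seq = sh.generate_motion(geom, {s: 0.4 for s in range(1, 17)}, {s: 0.0 for s in range(1, 17)})
    for i in range(len(seq.phases)):
        assert np.allclose(seq.vertex_positions[i], geom.endo_vertices)
    assert np.array_equal(seq.vertex_positions[0], geom.endo_vertices)


def test_motion_peak_displacement_at_true_ttp():
    geom, _ = sh.generate_lv_geometry(seed=2)
    ttp = {s: 0.30 for s in range(1, 17)}
    ttp[5] = 0.45
    amps = {s: 0.15 for s in range(1, 17)}
    seq = sh.generate_motion(geom, ttp, amps, sh.MotionParams(n_phases=20))
    # vertices interior to segment 5 (all incident faces labeled 5)
    vseg = sh._vertex_segments(geom.n_endo_vertices, geom.endo_faces, geom.segment_labels)
    counts = np.zeros((geom.n_endo_vertices, 17))
    for f, lab in zip(geom.endo_faces, geom.segment_labels):
        for v in f:
            counts[v, lab] += 1
    interior5 = [
        v for v in range(geom.n_endo_vertices)
        if counts[v, 5] > 0 and counts[v, 5] == counts[v].sum()
    ]
    disp = np.linalg.norm(
        seq.vertex_positions[:, interior5, :] - geom.endo_vertices[None, interior5, :], axis=2
    ).mean(axis=1)
    assert seq.phases[int(np.argmax(disp))] == pytest.approx(0.45, abs=1e-9)


def test_motion_rejects_out_of_range_amplitude():
    geom, _ = sh.generate_lv_geometry(seed=2)
    with pytest.raises(ParameterError):
        sh.generate_motion(geom, {1: 0.4}, {1: 0.7})
    with pytest.raises(ParameterError):
        sh.generate_motion(geom, {1: 1.2}, {1: 0.1})


def test_tacs_noiseless_match_forward_model_and_linearity():
    gt = sh.GroundTruth(
        thin_segments=frozenset(),
        scar_segments=frozenset(),
        true_mbf={s: 80.0 for s in range(1, 17)},
    )
    gt.true_mbf[2] = 160.0  # double flow
    gt.true_mbf[3] = 0.0  # zero flow
    p = sh.PerfusionGenParams(noise_sd_hu=0.0, tc_jitter_s=0.0)
    tac = sh.generate_tacs(gt, p, seed=0)
    aif_enh = tac.aif - p.baseline_hu
    expect = perfusion.forward_tissue_curve(tac.times, aif_enh, 80.0, p.tc_s, p.tissue_delay_s)
    assert np.allclose(tac.regional_curves[0] - p.baseline_hu, expect, atol=1e-9)
    # doubling MBF doubles the enhancement
    assert np.allclose(
        tac.regional_curves[1] - p.baseline_hu, 2.0 * (tac.regional_curves[0] - p.baseline_hu)
    )
    # zero flow: flat at baseline
    assert np.allclose(tac.regional_curves[2], p.baseline_hu)


def test_tacs_parameter_errors():
    gt = sh.GroundTruth(frozenset(), frozenset(), {s: 80.0 for s in range(1, 17)})
    with pytest.raises(ParameterError):
        sh.generate_tacs(gt, sh.PerfusionGenParams(dt_s=0.0), seed=0)
    with pytest.raises(ParameterError):
        sh.generate_tacs(gt, sh.PerfusionGenParams(noise_sd_hu=-1.0), seed=0)
    gt.true_mbf[4] = -5.0
    with pytest.raises(ParameterError):
        sh.generate_tacs(gt, seed=0)


def test_pressure_trace_class_means_and_degenerate_sd():
    params = sh.HemoGenParams(ectopy_rate=0.0, beat_noise_frac=0.0)
    params.class_ahr["target"] = (20.0, 0.0)
    rec, true_ahr = sh.generate_pressure_traces("target", params, seed=4)
    assert true_ahr == 20.0
    from wiseplan import hemodynamics

    hemodynamics.analyze_record(rec)
    assert rec.ahr == pytest.approx(20.0, abs=0.05)

    with pytest.raises(ParameterError):
        sh.generate_pressure_traces("unknown_class", seed=0)
    with pytest.raises(ParameterError):
        sh.generate_pressure_traces("target", sh.HemoGenParams(duration_s=5.0), seed=0)


def test_pressure_trace_monte_carlo_calibration():
    """Empirical class means within 2 SE of the configured means."""
    rng = np.random.default_rng(11)
    params = sh.HemoGenParams()
    for cls in ("target", "nontarget_viable", "scarred"):
        mean, sd = params.class_ahr[cls]
        draws = [sh.generate_pressure_traces(cls, params, rng)[1] for _ in range(500)]
        se = sd / np.sqrt(500)
        assert np.mean(draws) == pytest.approx(mean, abs=2.0 * se + 1e-9)


def test_thorax_candidates():
    geom, _ = sh.generate_lv_geometry(seed=2)
    thx = sh.generate_thorax(geom, sh.ThoraxParams(n_candidates=3), seed=0)
    ids = [c.ics_id for c in thx.ics_candidates]
    assert sorted(ids) == [4, 5, 6]
    for c in thx.ics_candidates:
        assert np.linalg.norm(c.beam_axis) == pytest.approx(1.0)
    with pytest.raises(ParameterError):
        sh.generate_thorax(geom, sh.ThoraxParams(n_candidates=0), seed=0)


def test_thorax_count_distribution():
    geom, _ = sh.generate_lv_geometry(seed=2)
    rng = np.random.default_rng(5)
    counts = [len(sh.generate_thorax(geom, seed=rng).ics_candidates) for _ in range(1000)]
    frac_one = np.mean([c == 1 for c in counts])
    assert frac_one == pytest.approx(0.36, abs=0.05)
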