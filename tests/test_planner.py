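"""Target selection rule and acoustic transmitter ranking."""

import numpy as np
import pandas as pd
import pytest

from wiseplan import aha, planner
from wiseplan import synthetic_heart as sh
from wiseplan.types import (
    ActivationMap,
    LVGeometry,
    PerfusionResult,
    StrainCurves,
    ThicknessMap,
    ThoraxModel,
    TransmitterCandidate,
)


def _maps(thickness, hypo, ttp, act, flat=None):
    thickness = np.asarray(thickness, dtype=float)
    ttp = np.asarray(ttp, dtype=float)
    flat = np.isnan(ttp) if flat is None else np.asarray(flat, dtype=bool)
    tm = ThicknessMap(
        vertex_thickness=np.zeros(1),
        seg_thickness=thickness,
        thin=thickness < 5.0,
    )
    perf = PerfusionResult(
        mbf=np.where(np.asarray(hypo, bool), 25.0, 80.0),
        pcbv=np.zeros(16),
        avg_enhancement=np.zeros(16),
        hypoperfused=np.asarray(hypo, dtype=bool),
    )
    sc = StrainCurves(
        phases=np.arange(20) / 20.0,
        area_change=np.zeros((16, 20)),
        circ_strain=np.zeros((16, 20)),
        long_strain=np.zeros((16, 20)),
        ttp_phase=ttp,
        ttp_ms=ttp * 850.0,
        flat=flat,
        peak_amplitude=np.where(flat, 0.01, 0.2),
        cycle_length=850.0,
    )
    act = np.asarray(act, dtype=float)
    amap = ActivationMap(
        activation_time=np.zeros(1),
        seg_mean=act,
        seg_max=act,
        latest_segment=int(np.argmax(act)) + 1,
        cv_map=np.zeros(1),
    )
    return tm, perf, sc, amap


def _worked_example_table():
    """Ischemic phenotype: anteroseptal/anterior/inferior hypoperfusion
    basal to apical, apical anterior+inferior thinning, latest mechanics
    mid inferior/inferolateral, latest activation basal-mid inferolateral."""
    scar = {1, 2, 4, 7, 8, 10, 13, 14, 15}
    thin = {13, 15}
    thickness = [4.0 if s in thin else 8.0 for s in range(1, 17)]
    hypo = [s in scar for s in range(1, 17)]
    ttp = np.full(16, 0.32)
    for s, v in {11: 0.45, 10: 0.44, 5: 0.40, 12: 0.38, 6: 0.37, 16: 0.36}.items():
        ttp[s - 1] = v
    ttp[[s - 1 for s in scar]] = np.nan  # akinetic -> flat
    act = np.full(16, 60.0)
    for s, v in {5: 140.0, 11: 135.0, 6: 110.0, 12: 108.0, 16: 90.0, 4: 120.0}.items():
        act[s - 1] = v
    return _maps(thickness, hypo, ttp, act)


def test_feature_table_viability_counts():
    tm, perf, sc, amap = _maps([8.0] * 16, [False] * 16, np.full(16, 0.35), np.full(16, 80.0))
    table = planner.build_feature_table(tm, perf, sc, amap)
    assert int(table["viable"].sum()) == 16

    thickness = [8.0] * 16
    thickness[0] = 4.0  # segment 1 thin
    hypo = [False] * 16
    hypo[6] = True  # segment 7 hypoperfused
    tm, perf, sc, amap = _maps(thickness, hypo, np.full(16, 0.35), np.full(16, 80.0))
    table = planner.build_feature_table(tm, perf, sc, amap)
    assert int(table["viable"].sum()) == 14


def test_worked_example_selects_basal_and_mid_inferolateral():
    table = planner.build_feature_table(*_worked_example_table())
    targets = planner.select_target_segments(table)
    assert set(targets) == {5, 11}
    assert table.loc[[5, 11], "target"].all()


def test_dominant_winner_is_primary():
    ttp = np.full(16, 0.30)
    ttp[10] = 0.50
    act = np.full(16, 60.0)
    act[10] = 150.0
    table = planner.build_feature_table(
        *_maps([8.0] * 16, [False] * 16, ttp, act)
    )
    primary, secondary = planner.select_target_segments(table)
    assert primary == 11
    assert aha.are_adjacent(primary, secondary)


def test_scarred_latest_segment_is_never_selected():
    tm, perf, sc, amap = _worked_example_table()
    perf.hypoperfused[4] = True  # scar the latest electrically activating segment
    perf.mbf[4] = 25.0
    table = planner.build_feature_table(tm, perf, sc, amap)
    targets = planner.select_target_segments(table)
    assert 5 not in targets
    assert all(table.loc[t, "viable"] for t in targets)
    assert aha.are_adjacent(*targets)


def test_too_few_viable_segments_raises():
    thickness = [4.0] * 16
    thickness[0] = 8.0
    tm, perf, sc, amap = _maps(thickness, [False] * 16, np.full(16, 0.35), np.full(16, 80.0))
    table = planner.build_feature_table(tm, perf, sc, amap)
    with pytest.raises(ValueError, match="no viable target pair"):
        planner.select_target_segments(table)


def test_randomized_tables_targets_always_viable_and_adjacent():
    rng = np.random.default_rng(123)
    n_ok = 0
    for _ in range(300):
        thickness = rng.uniform(3.0, 11.0, size=16)
        hypo = rng.random(16) < 0.25
        ttp = rng.uniform(0.2, 0.6, size=16)
        ttp[rng.random(16) < 0.15] = np.nan
        act = rng.uniform(20.0, 160.0, size=16)
        table = planner.build_feature_table(*_maps(thickness, hypo, ttp, act))
        try:
            a, b = planner.select_target_segments(table)
        except ValueError:
            continue
        n_ok += 1
        assert table.loc[a, "viable"] and table.loc[b, "viable"]
        assert not table.loc[a, "thin"] and not table.loc[a, "hypoperfused"]
        assert aha.are_adjacent(a, b)
    assert n_ok > 200


def test_acoustic_intensity_anchors_and_cutoffs():
    cand = TransmitterCandidate(ics_id=5, skin_entry_point=[0, 0, 0], beam_axis=[1, 0, 0])
    d, th, inten, cov = planner.acoustic_intensity(cand, [0.0, 0.0, 0.0])
    assert (d, th, inten, cov) == (0.0, 0.0, 1.0, True)
    # 30 degrees: hard zero
    p = 50.0 * np.array([np.cos(np.radians(30.0)), np.sin(np.radians(30.0)), 0.0])
    d, th, inten, cov = planner.acoustic_intensity(cand, p)
    assert th == pytest.approx(30.0)
    assert inten == 0.0 and not cov
    # 12 cm on-axis: hard zero
    d, th, inten, cov = planner.acoustic_intensity(cand, [120.0, 0.0, 0.0])
    assert d == pytest.approx(12.0)
    assert inten == 0.0 and not cov
    # strictly decreasing along the axis inside the window
    vals = [
        planner.acoustic_intensity(cand, [x, 0.0, 0.0])[2] for x in np.linspace(5.0, 115.0, 23)
    ]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        TransmitterCandidate(ics_id=5, skin_entry_point=[0, 0, 0], beam_axis=[0, 0, 0])


def test_ranking_prefers_aligned_candidate(default_patient):
    g = default_patient.geom
    c6 = g.segment_centroid(6)
    aligned = TransmitterCandidate(
        ics_id=4, skin_entry_point=c6 + 80.0 * np.array([1.0, 0, 0]), beam_axis=-np.array([1.0, 0, 0])
    )
    axis_off = np.array([np.cos(np.radians(40.0)), np.sin(np.radians(40.0)), 0.0])
    off = TransmitterCandidate(
        ics_id=6, skin_entry_point=c6 + 80.0 * np.array([1.0, 0, 0]), beam_axis=-axis_off
    )
    thorax = ThoraxModel(ics_candidates=[off, aligned], chest_wall_origin=np.zeros(3))
    ranked, amap, adequate = planner.rank_transmitter_sites(thorax, (6, 12), g)
    assert ranked[0][0] == 4  # the aligned candidate wins
    assert adequate
    # a candidate with zero intensity at the basal anterolateral target
    # must not be ranked first when segment 6 is targeted
    zero6 = amap[(amap.ics_id == 6) & (amap.segment == 6)].intensity.iloc[0]
    assert zero6 == 0.0
    assert ranked[-1][0] == 6


def test_ranking_invariant_to_candidate_order(default_patient):
    g = default_patient.geom
    thorax = sh.generate_thorax(g, sh.ThoraxParams(n_candidates=3), seed=2)
    ranked1, _, _ = planner.rank_transmitter_sites(thorax, (5, 11), g)
    flipped = ThoraxModel(
        ics_candidates=list(reversed(thorax.ics_candidates)),
        chest_wall_origin=thorax.chest_wall_origin,
    )
    ranked2, _, _ = planner.rank_transmitter_sites(flipped, (5, 11), g)
    assert ranked1 == ranked2


def test_ranking_invariant_under_joint_rigid_motion(default_patient):
    g = default_patient.geom
    thorax = sh.generate_thorax(g, sh.ThoraxParams(n_candidates=3), seed=2)
    ranked1, _, _ = planner.rank_transmitter_sites(thorax, (5, 11), g)
    rng = np.random.default_rng(1)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = np.array([5.0, 40.0, -12.0])
    g2 = LVGeometry(
        endo_vertices=g.endo_vertices @ Q.T + t,
        endo_faces=g.endo_faces,
        epi_vertices=g.epi_vertices @ Q.T + t,
        epi_faces=g.epi_faces,
        apex_point=g.apex_point @ Q.T + t,
        base_centroid=g.base_centroid @ Q.T + t,
        long_axis=g.long_axis @ Q.T,
        rv_pacing_site=g.rv_pacing_site @ Q.T + t,
        segment_labels=g.segment_labels,
    )
    thorax2 = ThoraxModel(
        ics_candidates=[
            TransmitterCandidate(
                ics_id=c.ics_id,
                skin_entry_point=c.skin_entry_point @ Q.T + t,
                beam_axis=c.beam_axis @ Q.T,
            )
            for c in thorax.ics_candidates
        ],
        chest_wall_origin=thorax.chest_wall_origin @ Q.T + t,
    )
    ranked2, _, _ = planner.rank_transmitter_sites(thorax2, (5, 11), g2)
    assert [i for i, _ in ranked1] == [i for i, _ in ranked2]
    for (_, s1), (_, s2) in zip(ranked1, ranked2):
        assert s1 == pytest.approx(s2, rel=1e-9)
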