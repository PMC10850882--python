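# Methods

This note documents the models behind each pipeline stage, the synthetic
data they are exercised on, the parameter defaults and why they were
chosen, and the limits of what the synthetic experiments demonstrate.

## Synthetic patients

**Anatomy.** The LV endocardium is a truncated prolate ellipsoid (default
semi-axes 25×25×80 mm, truncated at 70 % of the full long axis, ~860
vertices), apex at the origin, long axis +z. It is simple enough that
parcellation, thickness and geodesic quantities have analytic cross-checks,
while still having realistic dimensions for a dilated failing ventricle
(cavity length ≈ 112 mm). The epicardium shares the endo topology, offset
along outward vertex normals by per-segment wall thickness. Per patient,
the number of segments thinner than 5 mm is drawn as
round(clip(N(μ*, 3.5), 0, 16)); μ* is solved numerically so the
expectation of the clipped, rounded draw equals the configured cohort
mean of 4.8 — naive clipping would inflate it by ≈0.14. Thin segments get
thickness U(2.5, 4.5) mm, others U(6.5, 11) mm, leaving a ≥0.5 mm margin
on either side of the 5 mm threshold so classification is a property of
the measurement, not of borderline draws.

**Phenotype.** A patient is ischemic with probability 6/11. Ischemic
patients always carry a perfusion defect of 2–5 segments, placed
preferentially on thin segments (ischemic scar is thinned and akinetic)
and supplemented from non-thin segments when the thin set is smaller.
Scar segments get MBF reduced to 35 % of the patient's remote mean and
sub-threshold contraction amplitude.

**Motion.** Each endocardial vertex moves radially toward the long axis
with scale 1 − A·w(t), where w is a Gaussian bump in phase, rebased so
w(0) = 0 and w(TTP) = 1 (σ = 0.12 RR). The bump is symmetric about its
peak on purpose: discrete phase sampling then recovers the peak without
bias (an asymmetric pulse shifts the sampled argmin by a sizable fraction
of a phase step). Per-vertex amplitude/TTP are blended over incident
faces so the wall deforms continuously across segment borders. True TTP
rises from septum to lateral wall and toward the base
(0.32 + 0.12·proxy + N(0, 0.01)), mirroring RV-paced activation, so the
mechanically and electrically latest segments usually coincide — with
occasional dissociation when scar intervenes. Default 20 phases,
cycle 850 ms; viable amplitude 0.15, scar 0.01.

**Perfusion forward model.** The arterial input is a gamma-variate bolus
(peak 300 HU above a 40 HU baseline, delay 6 s, time-to-peak 8 s,
α = 3). Tissue curves are MBF-scaled convolutions of the AIF with an
exponential residue exp(−t/T_c) (T_c = 6 ± 1 s), delayed 1.5 s, sampled
every 2 s for 60 s, plus N(0, 1 HU) noise. Healthy MBF ≈ 75 mL/100 mL/min.
The forward model is owned by the `perfusion` module so that the
noiseless generator output inverts exactly (closing the loop).

**Pressure traces.** Beats are half-sine-squared systolic upstrokes on a
12 mmHg diastolic baseline; the amplitude is set so each beat's
dP/dt_max hits the target (dP/dt_max = amplitude·π/T_sys), with 1 %
beat-to-beat noise and isolated ectopic beats (rate 5 %, amplitude ×1.6).
Baseline dP/dt_max 800 mmHg/s, 72 bpm, 500 Hz, 12 s windows. The realized
AHR of a tested segment is drawn from its class-conditional normal:
target 25.5 ± 8.8 %, viable non-target 15.4 ± 8.0 %, scarred 5.9 ± 4.0 %
(the scarred SD is not reported anywhere and is a free calibration of
this package). End-to-end trace analysis reproduces the drawn AHR with
SD ≈ 0.45 pp.

**Tested-segment composition.** Each synthetic procedure tests the 2
planner targets plus 2–4 non-target segments. For the pooled non-target
mean to sit at 12.9 % given class means of 15.4 % (viable) and 5.9 %
(scarred), the scarred share of tested non-targets must be
(15.4−12.9)/(15.4−5.9) = 0.263; with ischemic prevalence 6/11 the
per-draw probability of testing a scar segment in an ischemic patient is
0.263/(6/11) ≈ 0.48.

**Thorax.** 1–3 intercostal candidates (probabilities 0.36/0.37/0.27 of
1/2/3 usable spaces), placed anterolateral to the LV at the epicardial
radius + 45 mm, beams aimed near the basal inferolateral wall with 5°
jitter.

What the generator does **not** emulate: image noise and segmentation
error in the meshes (vertex correspondence across phases is exact, where
real pipelines obtain it by deformable registration), papillary muscles
and trabeculation, the right ventricle, respiratory/cardiac motion
artifacts in perfusion, rib shadowing of the ultrasound beam, and any
correlation between a patient's anatomy and their hemodynamic response
beyond the class labels. Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, not robustness to real
image-derived inputs.

## Analysis stages

**Perfusion inversion.** Per segment, (MBF, T_c, t0) are fit to
C(t) = MBF·(AIF ⊛ e^{−t/T_c})(t−t0) by bounded least squares; for each
(T_c, t0) on a coarse grid the scale is solved linearly, and the best
grid point initializes the refinement. t0 is bounded to [0, 5] s, T_c to
[1, 20] s, MBF ≥ 0; this sidesteps the ill-posedness of unconstrained
deconvolution. PCBV = MBF·T_c/60 (central volume principle), in
mL/100 mL. A flat curve is reported as zero flow; a non-convergent fit
as NaN with a warning, never a silent zero. Hypoperfusion: MBF below 0.6
× the median of unflagged segments, iterated to a fixed point — the
fraction is exposed in config because no quantitative criterion for
"significant hypoperfusion" is available. Late enhancement (delayed HU >
1.5 × remote median) is advisory only; it is known to be insensitive.

**Strain and TTP.** Area change is the segment's surface-area ratio to
phase 0 minus 1; circumferential/longitudinal strains are mean fractional
edge-length changes with edges binned by |cos| ≤ 0.5 of their angle to
the long axis. TTP is the phase of the most negative area change,
refined by fitting a parabola through the discrete minimum and its
neighbors. Segments with peak-to-peak area change below 0.05 ("flat
volume curves") are excluded from lateness ranking; the 0.05 default is
this package's operationalization of a qualitative criterion. "Volume
curves" are represented by segmental area-change curves (endocardial
surface proxy).

**Activation.** Isotropic surface eikonal |∇T| = 1/v solved by
fast marching with the planar-wavefront triangle update and edge-update
fallback; the source's 3-ring is seeded from a finely subdivided local
Dijkstra solve because pure vertex-path updates overestimate short
diagonal routes near the source. Defaults: 0.6 m/s healthy endocardium,
0.2 m/s scar (slow, not blocked, so nothing becomes artificially
unreachable); both literature-typical and config-exposed. Accuracy
contract: within 5 % of a subdivided-Dijkstra geodesic oracle on
cohort-size meshes (measured ≤ 4.1 %). The latest electrically
activating segment is the argmax of per-segment *mean* activation time
(max available via config). QLV is measured from the pacing stimulus to
local activation — clinical QLV is measured from QRS onset on the ECG;
here the two are equated.

**Anatomy.** AHA-16: longitudinal thirds of the normalized apex-to-base
coordinate × circumferential sectors (6/6/4) anchored at the septum; the
anchor is synthesized from the RV pacing-site direction when no RV
insertion landmark exists. Sector angles are snapped to 10⁻⁶ degrees so
faces sitting exactly on a sector boundary label identically under rigid
motion of the full input. Thickness: per-vertex ray cast along the
outward endo normal to the epi surface (vectorized Möller–Trumbore,
nearest hit, 60 mm cap); per-segment summary is the **median** (robust
to basal-rim artifacts; min available for conservative screening); thin
means median < 5.0 mm, strict.

**Planner.** Viable = neither thin nor hypoperfused. Each viable segment
with defined TTP is scored by rank(TTP) + rank(activation time); the
primary target is the best score and the second target its best-scoring
viable neighbor in the explicit AHA-16 adjacency graph, so the pair is
adjacent by construction. Ties break toward the more basal, then more
lateral segment (matching the basal-lateral implant preference); the
rank-sum fusion is this package's resolution of mechanical/electrical
disagreement, with config switches to prioritize either. Acoustic
intensity: I(θ, d) = cos θ·e^{−μd}, μ = 0.1 cm⁻¹, normalized to 1 at
(0°, 0 cm), hard zeros at θ ≥ 30° or d ≥ 12 cm. The functional form is a
monotone surrogate — the testable contract is qualitative: candidates
with zero intensity at a target are never ranked first, rankings are
invariant to candidate order and joint rigid motion. θ is measured at
the skin entry point; the aperture is a point source.

**Hemodynamics.** Beats are delimited by pressure minima; per-beat
dP/dt_max is the max of the centered-difference derivative (≤0.003 %
error on a 1 Hz sinusoid at 500 Hz). Ectopy rejection removes beats
beyond 3σ of the window, with σ estimated robustly (1.4826·MAD about the
median, iterated): a plain mean/SD filter lets two or three ectopics in
one window mask each other, which corrupts AHR by up to ~13 pp.
AHR = 100·(mean paced dP/dt_max − reference)/reference. Group comparison
is an unpaired two-sided Welch t-test on pooled segments (the unit of
analysis is the tested segment, not the patient; per-patient averaging
is a config option), plus Fisher's exact test on (group × AHR > 10 %).

**Reporting.** Bull's-eye plots use the standard layout (basal ring
outermost, anterior up, septum left); exactly-zero intensities render
white (no coverage), missing segments hatched. The fluoroscopy overlay
is a pinhole projection of target-segment boundary polylines onto a
detector plane (RAO/LAO about z, cranial/caudal about x, default
source–isocenter 700 mm, source–detector 1050 mm); only forward
projection geometry is modeled, not CT-to-fluoro registration.

## Numerical and design choices

- Seeds: every generator takes a seed or `numpy` Generator; the pipeline
  derives per-patient integer child seeds (< 2³¹) from the master seed,
  and 200-patient anatomy samples use the same child-seed scheme.
- Tie-breaks (latest segment, target ranking, transmitter ranking) are
  all deterministic and documented above; reruns are byte-stable.
- Degenerate inputs fail loudly: zero-area segments, constant pressure
  traces, all-flat strain, unreachable mesh components, all-hypoperfused
  MBF maps and out-of-range generator parameters each raise a specific
  error; a cohort run marks the patient failed and continues.
- Problem sizes are desk-scale by design: ~860-vertex meshes, 31-point
  TACs, 10-patient cohorts, 20-replicate pooling in the acceptance
  script. These sizes keep every analysis comfortably in the regime
  where its accuracy contracts (5 % eikonal, 1 % noiseless MBF, half a
  phase step for TTP) were verified.

## Known limitations

- The compartment model is a single-exponential residue; vendor
  perfusion software uses richer (unpublished) intravascular/
  extravascular models, so absolute MBF agreement with any scanner
  product is out of scope.
- The eikonal model is surface-only, isotropic, and has no His–Purkinje
  system; activation times are plausible rather than patient-accurate.
- The acoustic model ignores rib shadowing and lung encroachment; it
  orders candidate windows, it does not predict absolute power.
- At the calibrated effect size and cohort size, the target-vs-non-target
  comparison has ≈89 % power at the 0.001 level (≈100 % at 0.05), so a
  minority of seeded cohorts do not reach p ≤ 0.001 — an inherent
  property of the calibration, not a defect of the test.
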