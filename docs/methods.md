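# Methods

`fixtrack` turns a manual image-editor workflow for measuring eccentric
fixation into a deterministic computation. This note records the model behind
each stage, the defaults and why they were chosen, what the synthetic data do
and do not emulate, and the numerical conventions a maintainer needs.

## The measurement

A patient whose fovea no longer supports fixation adopts a *preferred retinal
locus* (PRL) elsewhere on the retina. Microperimetry tracks the eye 25 times
per second during an exam and reports two cluster centers of the fixation
cloud: PRLi (samples of the initial window, default 10 s) and PRLf (the whole
exam, the reference for every stability metric). The measurement of interest
is the **distance from the foveal center** (DFC): the straight-line distance,
in microns, between the anatomic foveal center (FC) and PRLf, after all
images of the eye have been brought into one frame.

The pipeline:

1. **Registration.** The OCT infrared en-face image, the microperimeter SLO
   image and the 30° autofluorescence (FAF) frame are related by planar
   similarity transforms (scale *s*, rotation *θ*, translation *t*) estimated
   from user-supplied landmark pairs (vessel bifurcations, optic-nerve
   silhouette) by the closed-form orthogonal-Procrustes-with-scale solution.
   Similarity is the default family because a manual overlay with zoom has
   exactly those degrees of freedom; an affine fit is opt-in for modality
   distortion. Transforms compose along OCT-IR → SLO → FAF; the FAF frame is
   the common frame because it carries the scale bar.
2. **Foveal center.** The FC is the intersection of the *infinite* lines
   through the registered endpoints of the chosen horizontal and vertical
   transfoveal scan lines — the scans are chords through the fovea, so their
   crossing, not a segment midpoint, defines the anatomic point. Which
   B-scans are "most anatomically accurate" is an image-reading judgement
   made upstream and encoded in the annotation files.
3. **Calibration.** The FAF export carries a 200 µm scale bar; its measured
   pixel length defines the per-eye ruler µm/px (e.g. 23 px ⇒
   200/23 ≈ 8.696 µm/px). Degree-valued quantities (the 1°/2° stability
   radii) are converted with a global 288 µm/° schematic-eye factor,
   configurable because the device's internal conversion is unpublished. No
   axial-length (Littmann/Bennett) correction is applied.
4. **Metrics.** With PRL positions mapped into the common frame:
   - DFC = ‖FC − PRLf‖ · (µm/px); DPRL = ‖PRLi − PRLf‖ likewise.
   - Quadrant: two perpendicular axes through the FC; superior means smaller
     raster *y* (display is superior-up); laterality maps image left/right to
     temporal/nasal (OD: temporal = image left; OS mirrored). Ties within
     1e-9 px on either axis are `on_axis`.
   - BCEA(P) = χ²₂(P) · π · σx · σy · √(1 − ρ²) in deg², from sample SDs and
     correlation of the cloud; default coverage 0.95 (χ²₂ = 5.991), 0.63
     selectable.
   - P1/P2: percentage of samples within 1°/2° of PRLf, **inclusive** radii.
   - Stability: strict thresholds — stable if P1 > 75; relatively unstable if
     P1 ≤ 75 < P2; else unstable. Exactly 75/75 is therefore unstable.
   - Exam validity: fixation loss ≤ 15 %, inclusive.
   - Longitudinal change: ‖PRLf(t₁) − PRLf(t₀)‖ in µm — the third side of the
     FC/PRLf(t₀)/PRLf(t₁) triangle, independent of the FC, reducing to
     |DFC₁ − DFC₀| when collinear.
5. **Agreement.** Inter-grader repeatability uses per-grader mean/SD/range
   (sample, n−1 SDs), Pearson r, and Bland–Altman with differences taken
   grader 2 − grader 1 and limits of agreement at bias ± 1.96·SD(diff).

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `scale_bar_microns` | 200 | µm | length of the device scale bar |
| `microns_per_degree` | 288 | µm/° | emmetropic schematic eye; device factor unpublished |
| `bcea_coverage` | 0.95 | — | common reporting convention; 0.63 also used in the field |
| `max_rms` | 2 | px | registration acceptance gate; no residual criterion is published, this is this package's own guard |
| `window_initial` | 10 | s | device's grid-centering phase |
| stability threshold | 75 | % | fixed by the classification rules |
| fixation-loss limit | 15 | % | device reliability criterion |

## Synthetic data

The generator exists because device exports are proprietary. It emulates the
*geometry* of the problem, not retinal biology:

- **Phantoms**: random-walk vessel trees with Gaussian profiles rendered on a
  512 px common frame and warped into each modality by known similarity
  transforms (scales 0.85–1.2, rotations ±8°, shifts ±25 px — the range a
  manual overlay absorbs). Landmark tables are emitted *analytically* from
  the true transforms, so registration tests measure estimation, not
  rendering. Scan lines are constructed to cross exactly at the programmed FC.
- **Fixation clouds**: bivariate normal at 25 Hz with programmed center
  offset (µm from FC), per-axis σ (deg), correlation ρ, plus an optional
  second cluster for the non-normal patterns real fixation shows. The `drift`
  parameter is defined as the *expected PRLi→PRLf separation* in µm and is
  realized as a linear positional drift whose velocity is calibrated against
  the sample-time grid, so the programmed DPRL is exact in expectation.

What passing tests therefore show: the pipeline recovers programmed geometry
(FC to < 0.01 px on noise-free landmarks; DFC to < 1 px-equivalent median
over random phantoms with realistic cloud spread). What they do not show:
robustness to landmark-picking error beyond isotropic noise, torsional eye
movements, nonrigid modality distortion, or atrophic retinas where the scan
selection itself is uncertain.

## Numerical conventions and edge cases

- Pixel coordinates are 0-based, origin top-left, y down; fixation CSVs store
  y-up visual degrees and are flipped to y-down at load, so one convention
  holds in memory.
- Rotation angles follow the y-down frame: θ = 90° maps (1, 0) → (0, 1).
- Similarity estimation rejects reflections (SVD sign correction) and raises
  on zero source spread; affine requires ≥ 3 non-collinear points
  (rank test, tol 1e-7).
- Scan-line crossings within 5° of parallel raise; separations folded to
  (0°, 90°] below 60° are flagged unreliable rather than rejected. An
  intersection farther than a configurable distance from *both* segments
  raises an out-of-frame error.
- A fixation cloud numerically collinear (1 − |ρ| < 1e-12) or with zero
  variance on an axis returns BCEA = 0 with a degenerate flag instead of a
  NaN.
- PRL centroids use the arithmetic mean (matching the BCEA's moment basis);
  the coordinate-wise median is available for robustness. PRLf deliberately
  averages the *whole* exam: it is the cumulative reference the stability
  metrics are defined against.
- Result JSON refuses non-finite numerics before writing; every numeric field
  carries an explicit unit.

## Problem sizes

The test suite and the acceptance script use 50 random phantom eyes with
750-sample exams (30 s at 25 Hz) for end-to-end recovery, 10⁵ draws for the
BCEA containment check, and 20 random transforms for exact-recovery sweeps —
sizes at which the Monte-Carlo noise floors (≈ 0.3–0.5 px median DFC error,
±0.15 % containment) sit well inside the asserted bounds.

## Known limitations

- Landmarks are supplied, not detected; automatic vessel registration is out
  of scope by design (the step being replaced is explicitly manual).
- A single global µm/° factor ignores per-eye magnification; so does the
  scale-bar ruler (no axial-length correction).
- The quadrant rule assumes standard fundus display orientation; rotated
  exports would need their rotation registered out first.
- Inter-grader statistics implement simple Bland–Altman; ICC and
  repeated-measures variants are out of scope.
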