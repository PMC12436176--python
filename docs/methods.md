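# Methods

## The model

`hffm` implements a functional four-segment foot model for marker-based
clinical gait analysis.  The segments are shank (Sh), hindfoot (Hf), forefoot
(Ff) and hallux (Hal), instrumented with the 17-marker Heidelberg foot marker
set (LEP, MEP, TTU, SH1, SH2, LML, MML on the leg; LCL, CCL, MCL on the
calcaneus; NAV, DMT1, PMT1, DMT2, DMT5, PMT5 on the midfoot/forefoot; HLX on
the hallux).  Instead of placing joints at marker midpoints only, the model
uses functionally motivated reference points:

* **KJC / AJC** — epicondyle and malleolar midpoints; **KJA** the MEP→LEP
  line.
* **HRC** (heel rotation center) — the pivot of heel rolling in early stance,
  regressed from CCL/LCL/MCL:
  `HRC = (0.54·CCLx − 0.15·LCLx + 0.15·MCLx, 0.28·CCLy + 0.43·LCLy + 0.42·MCLy,
  0.29·CCLz + 0.025·LCLz + 1.74·MCLz)` in local foot coordinates.
* **MFJC** (midfoot joint center) — the functional center of
  hindfoot–forefoot angular motion, regressed from NAV/PMT1/PMT5:
  `MFJC = (0.16·NAVx + 0.25·PMT1x + 0.30·PMT5x, 0.52·NAVy − 0.17·PMT1y +
  0.26·PMT5y, 0.5·NAVz + 0.5·PMT5z)`.
* **MRA** (metatarsal rotation axis) — the third-rocker axis: the DMT1–DMT5
  line shifted 11 mm plantarward (8 mm metatarsal head radius + 3 mm marker
  radius).  **FFC** is the orthogonal projection of DMT2 onto the MRA.

Segment frames (Table-style definitions): shank from KJC, AJC and the knee
axis; hindfoot from HRC, MFJC and AJC; forefoot from MFJC, FFC and the MRA;
the hallux is the single axis FFC→HLX.  Inter-segment angles are intrinsic
X–Y–Z (sagittal, frontal, transverse) Cardan angles of
`R_rel = R_proximalᵀ · R_distal`, the standard Grood–Suntay/ISB reading for
that order, reported in degrees for the pairs Sh/Hf, Hf/Ff and Sh/Ff.
Four phenomenological channels complete the 15-channel angle set: medial arch
(apex angle MCL–NAV–DMT1; smaller = higher arch), medial arch inclination
(first-ray line MCL→DMT1 against the sole plane, anterior-down positive),
metatarsal I–V angle (divergence of the first and fifth rays projected onto
the sole plane), and subtalar eversion (calcaneal vs. malleolar mediolateral
lines projected onto the frontal plane of the foot, eversion positive), plus
hallux flexion/abduction as projected angles of the hallux axis in the
forefoot frame.

## Design choices that were genuinely open

**Local frame for the regressions.**  The published regression coefficients
presuppose a "local coordinate system of the foot" whose exact definition is
not recoverable from the coefficients alone.  This package anchors the frame
entirely in markers: origin CCL, x toward the DMT1/DMT5 midpoint, z the
CCL–DMT1–DMT5 sole-plane normal, y lateral (the DMT5 side).  A marker-anchored
frame — rather than one referencing the lab vertical — keeps the regressed
points rigid under any rigid motion of the foot, which is what makes every
angle channel exactly invariant under global rigid transforms and makes
noiseless synthetic gait recoverable to machine precision.  The absolute
position of HRC/MFJC therefore inherits this frame choice and should not be
read as a claim about the original coefficients' frame.

**Calibrate-then-track.**  For trajectories, joint centers and segment frames
are constructed once on a calibration sample (a static pose if supplied,
otherwise the first trial sample) and then tracked rigidly with each
segment's marker cluster via least-squares rigid fits (Kabsch).  Per-frame
re-evaluation of the regressions would couple the segments through the shared
local foot frame (the 1.74·MCLz term amplifies a ~2° frame tilt into ~1 mm of
HRC drift), producing degree-level artifacts in the recovered angles.
Tracking removes that coupling; the per-sample construction remains available
as `compute_angles_frame` for static analyses.  No static *offsets* are
subtracted — calibration only locates points within segments.

**Left/right convention.**  Left-foot segment frames are the mirrored
construction rotated 180° about their own mediolateral axis (x posterior,
y medial, z proximal).  Under this anti-aligned convention the change of
basis between sides is `−I`, whose conjugation is the identity, so
anatomically equivalent left and right motions yield identical angles with
one clinical sign convention: dorsiflexion +, varus/inversion/supination +,
internal rotation and adduction +, eversion + on the subtalar channel.  (The
simpler "negate the y axis" rule flips frontal/transverse signs and was
rejected after verification.)  The MRA's 11 mm shift direction is the
plantar sole-plane normal at calibration (identical to the lab vertical for
a flat-standing foot), again for rigid invariance.

**Smoothing.**  Marker components are filtered with a discrete penalized
least-squares smoother (Whittaker graduation) with a third-order difference
penalty — the uniform-grid analogue of a quintic smoothing spline.  The
default penalty is set analytically so the amplitude response is −3 dB at
6 Hz for the trial's sampling rate (λ = (√2−1)/(2 sin(π·6/fs))⁶ ≈ 150 at
100 Hz), a conventional gait-analysis bandwidth.  Gaps (NaN) up to 0.1 s are
bridged by zero-weight interpolation; longer gaps reject the trial.  A
single-sample 10 mm artifact is attenuated about six-fold at the default
bandwidth.

**Gait events.**  Initial contact: heel-height (CCL z) minima located between
consecutive swing peaks of the heel lift; toe off: the first sample per cycle
where the forward velocity of DMT2 exceeds 5% of its swing peak.
User-supplied events always override detection.  On noiseless synthetic gait
the detector matches the generator's exact events within ±2 samples at
100 Hz; with 1 mm marker noise IC localization is within ±5 samples because
the heel-height minimum is shallow.

**Classification.**  The equinovarus screen is the sign of the least-squares
slope of the hindfoot/shank flexion curve over the first 5% of the gait cycle
(six points of the 101-point curve): a positive slope — the ankle
dorsiflexing immediately after contact — indicates forefoot-first contact.
A multi-point window is used because a one-sample derivative would be
noise-dominated; the window length is configurable.

**Statistics.**  Classic (equal-variance) one-way ANOVA per (angle, outcome)
with the Bonferroni factor fixed at 3 — the mean/max/ROM family of one angle —
and never across angles; pairwise contrasts are Bonferroni-adjusted two-sample
t-tests within the same family.  The statistical unit is the foot; bilateral
correlation is ignored.  Group summary tables report mean ± SD across feet,
each foot's value being its cycle-averaged curve summary.

## The synthetic generator

The generator is forward kinematics on a rigid, stylized adult foot template
(foot length ≈ 205 mm at scale 1).  The template is *designed*, not measured:
marker heights are solved so that the regressed HRC, MFJC and FFC are
collinear along the foot axis at neutral, making all four segment frames
exactly aligned and every rigid-segment angle zero in the neutral pose, and
so that the navicular sits above the MCL–DMT1 chord (the medial arch angle
then decreases strictly monotonically as NAV rises).  The hindfoot follows a
gait-like global motion (foot-flat stance, heel lift from 60% cycle, swing
repositioning, 1.2 m forward travel per stride at 110 steps/min); the shank
is derived by inverting the prescribed ankle rotation about the AJC, the
forefoot rotates about the MFJC, and the hallux about the FFC.  Because each
joint pivots on the model's own regressed centers, cross-segment reference
points (AJC, MFJC) are stationary in both adjacent segments and the measured
angles equal the prescribed waveforms exactly in the noiseless case.

Joint waveforms are sums of at most three stride-locked sinusoids plus an
offset.  The default (typically developing) ankle curve has the physiologic
shape: slight dorsiflexion at contact, loading-response plantarflexion
(negative early slope), a ~13° stance dorsiflexion peak near 38% cycle and
~−15° push-off plantarflexion near 69%.  Presets modify the baseline:

| preset | ankle sagittal | hindfoot varus | neutral arch |
|--------|----------------|----------------|--------------|
| TD     | baseline       | baseline       | baseline     |
| CV     | +4° offset     | +5° offset     | −10° (NAV raised) |
| EV     | equinus pattern: −12° offset, positive slope at contact | +7° offset | −18° |

The arch offsets are realized geometrically: a dorsal navicular raise solved
by root-finding to lower the neutral apex angle by the stated amount.  Preset
constants encode the *direction* of the published group contrasts (equinus
contact pattern, added varus, higher arch, EV arch < CV arch); they are not
claims of reproducing any cohort's values.  Marker noise is isotropic
Gaussian (default SD 1 mm, seeded); amplitudes above 80° are rejected as a
gimbal guard.

What the generator does **not** emulate: soft-tissue artifact (noise is
white and isotropic, real skin motion is correlated and task-dependent),
marker occlusion beyond simple gaps, within-subject stride variability,
double support asymmetries, and any deformity feature other than the preset
offsets.  Passing round-trip tests therefore demonstrates the correctness of
the geometric pipeline, not clinical validity on real feet.

## Numerical conventions and degenerate inputs

* Angles in degrees everywhere; positions in mm.
* Rotation matrices are validated orthonormal (‖RᵀR − I‖ < 1e−9, det = +1).
* Cardan decomposition warns and sets γ = 0 (α carries the combined
  rotation) at |β| ≥ 89°.
* Near-parallel construction vectors (< 1° separation), coincident markers
  and zero-length axes raise named `DegenerateGeometryError`s; missing
  markers raise `MissingMarkerError` listing the labels, and in the angle
  pipeline null only the affected channels (NaN).
* Problem sizes used in validation: 5-cycle trials at 100 Hz (~600 samples),
  20 seeds per preset for the classification check, 2000 replicates of
  n = 20/20/20 for the ANOVA type-I calibration.

## Known limitations

* The regression-frame definition is this package's own reconstruction; HRC
  and MFJC positions are plausible but not traceable to the original
  implementation.
* C3D support needs the optional `ezc3d` dependency; the CSV dialect is the
  first-class format.
* Kinetics/inverse dynamics, radiographic angle acquisition and clinical
  examination data are out of scope; Pearson correlation against external
  scalar measures is provided as a generic operation.
* Absolute values of the phenomenological channels on the stylized template
  (e.g. a ~173° neutral arch) are flatter than adult norms; only their
  orderings and responses are meaningful in synthetic experiments.
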