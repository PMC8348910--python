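# Methods

## Model and assumptions

The worker is an articulated tree of 16 rigid bars joined by ball joints:
pelvis (root), lumbar, thorax, head, and bilateral arm–forearm–hand and
thigh–shin–foot chains.  The global frame has *y* vertical up, *x* lateral
(to the worker's left) and *z* anterior; the neutral pose is upright with
arms hanging.  Joint rotations are Euler angles (Rx, Ry, Rz, degrees,
right-hand rule) composed intrinsically x-y-z.  The composition order is a
convention choice; the risk score consumes per-axis angles and acceleration
moduli, which limits its sensitivity to it.

Segment masses are fixed fractions of body weight and CGs fixed fractions
of bone length, per sex (tabulated in `data/anthropometry.yaml`).  Segment
inertia tensors are diagonal 3×3 matrices expressed in the global axis
convention, tabulated at the P05/P50/P95 population percentiles and
interpolated component-wise on body weight.  Keeping the diagonal fixed in
the global frame (rather than transporting it with the segment) is an
approximation; for the dominant sagittal/frontal movements of manual work
the moments about the swing axis are near-invariant, and the inertial-torque
term is small against the gravity and lever terms at working speeds.

Bone lengths are not part of the mass/inertia tables; the package scales a
standard stature-proportional segment-length table (Drillis–Contini type:
shin 0.246·H, thigh 0.245·H, trunk 0.288·H split 0.078/0.090/0.120, head
0.182·H, arm 0.186·H, forearm 0.146·H, hand 0.108·H, foot 0.152·H, hip
width 0.191·H, biacromial 0.259·H), arranged so the vertical chain sums
exactly to stature.  The fractions are editable in the same data file.
Body weight, when not supplied, is interpolated on stature between the
percentile anchors (linear extrapolation with a warning outside them).
Shoulder width comes from the measured elbow span via a configurable linear
ratio (default 0.85 — olecranons sit slightly outside the shoulder centres
in the neutral pose); absent a span it defaults to the biacromial stature
fraction.

## Kinematics and differentiation

Forward kinematics composes rotations from the pelvis origin; a segment's
CG lies at its CG fraction along the bone.  Angular velocity/acceleration
are first/second central differences of the per-joint Euler curves
(one-sided at the ends), reported in °/s and °/s² because every scoring
threshold is printed in those units; CG linear kinematics are differenced
the same way.  No smoothing is applied by default — the scoring thresholds
were built from directly differenced captures — but a Savitzky–Golay option
(odd window, polyorder 3) is available for noisy recordings.  For the
inertial torque, each segment's absolute angular rates are extracted from
its orientation matrices ([ω]× = Ṙ Rᵀ) rather than from the relative joint
curves, which the scoring keeps using.

## Kinetics

Stage one balances the whole body per frame: support reactions equal minus
the sum of segment weights, d'Alembert inertial forces (−m·a) and external
hand loads, so the net-force residual is zero to machine precision.  Feet
are detected as supports when their lowest point stays within 5 cm of the
frame's lowest foot and their CG speed under 0.25 m/s (both thresholds
configurable); declared seated or hand-support ranges override detection,
and frames with nothing detected fall back to both feet with a warning.
Between two supports the resultant is split by the lever rule on the
horizontal projection of the load centre (clamped to [0, 1]); with more
supports a minimal-norm least-squares split balances the horizontal
moments, clamping negative weights.  An `equal` split is available for
comparison.  Reactions are applied at the supporting segment's CG; the
seat reaction at the pelvis centre.

Stage two recurses from wrists and ankles toward the pelvis.  External
hand actions are declared per frame range in a pelvis-linked frame (yaw
rotates with the pelvis, *y* stays vertical); "both hands" actions split
50/50.  Frame ranges are inclusive and 0-based.  Inertial torque is
−(T·α + ω×(T·ω))/g₀ with g₀ = 9.81 m/s² used purely as the kgf/N
conversion constant; the `gravity` argument scales segment weights only, so
zero-gravity runs isolate the inertial response.

An idealized aligned neutral pose puts every trunk and arm CG on the joint
axis, so *static* joint torques are essentially zero.  Static torque
minima measured on real subjects (anterior CG offsets of a real standing
posture) are therefore not reproduced by the engine — the packaged torque
thresholds carry the measured minima instead.  Static force minima, by
contrast, depend only on mass fractions and are reproduced within 0.15 kgf
for lumbar, cervical, shoulders, elbows and wrists.  The knee static force
depends on the foot reaction point and the measured value reflects a
slightly asymmetric stance; the engine's idealized value is ~1 kgf lower.

## Risk scoring

Factor curves are piecewise-linear lookups, never stepped.  The packaged
AngleScore graphs are explicit *defaults* (band edges adapted from ISO
11226 / REBA / RULA, score 1 at neutral, saturating at the joint ceiling —
2.0, or 1.6 at the wrist); the shoulder uses a two-input
antero-posterior × elevation table evaluated bilinearly from two band
curves.  All graphs load from `data/angle_graphs.yaml` so calibrated
curves can be dropped in verbatim.  Force/torque bounds resolve per sex
and worker height by interpolating between the percentile columns (P50
bounds times the P05/P95 coefficients); the preparation level (0 sensitive
… 3 specially trained) scales the upper bounds by 0.9/1.0/1.1/1.2.
Acceleration scores rise linearly from the slow threshold to the maximum
(Table `data/thresholds.yaml`, `angular`), both tied by the 0.2-s stop
rule to the speed thresholds.

Cycle aggregation: the repetitiveness weight defaults to a linear 0 %→1,
100 %→2 map of RiskPerPosture (configurable anchors; the abscissa can
equally be raw factors by pre-scaling).  General factors:
RecoveryFactor = 1 + 0.2·h capped at 2.6; MicroPausesFactor is entered
directly (1.0 none, 0.9/0.8/0.7 for increasing rest); DurationFactor is
piecewise-linear through (0 h, 0.5), (8 h, 1.1), (16 h, 2.0);
AdditionalFactor = 1 + 0.18·proportion.  The recovery, duration and
repetitiveness curve *shapes* are package defaults honouring the published
ranges and anchors; all are configurable.  Report percentages round
half-up to one decimal.

## Calibration

Maximum thresholds are the 99th percentile (linear interpolation) of
pooled per-frame load moduli from wide-arc captures processed with a
declared (0, −8, 0) kgf load in each hand; minima are static standing
loads with empty hands, measured on the P50 model and transported to other
percentiles with the dynamic P05/P95 coefficients.  Bilateral sides are
averaged; coefficients are reported half-up to 2 decimals.  Whether the
99th percentile is taken per capture then averaged or pooled is a free
choice; the implementation pools.  `simulate_calibration_protocol`
exercises this arithmetic end-to-end on synthetic captures.

## Synthetic data

The generator produces C²-continuous trajectories (quintic smoothstep
transitions, sinusoidal oscillation) at a configurable frame rate (60 Hz
default, matching the capture hardware the thresholds were built with).
Scenario defaults are the study conditions: `lift_place` carries a 3.5-kgf
part with both hands (hook grasp) over the middle of the cycle;
`screw_task` applies a 0.2 kg·m forward tool torque; `wide_arcs` sweeps
every joint with small seeded amplitude jitter; `static_stand` is the
resting reference.  Synthetic captures are kinematically ideal: no sensor
noise, soft-tissue artefact, drift, or foot-ground compliance.  Passing
tests therefore validate the arithmetic and the model's internal
consistency, not the field accuracy of any particular capture system.

## Numerical choices and problem sizes

Central differences are exact for linear ramps and attenuate a sinusoid of
frequency f by ~(2πf/fs)²/6, <0.2 % at 60 Hz for 1-Hz movements; the
pendulum cross-check runs a 0.5-Hz swing at 60 Hz, where the discretization
error is ~0.3 %.  Test and acceptance runs use short captures (2–8 s,
60 Hz) and a 3–6 s calibration sweep; all quantities checked are
per-frame or per-cycle statistics that do not grow with capture length.
Degenerate inputs are rejected with named errors: captures under 3 frames,
zero supports, unknown joints/segments/scenarios, non-positive cycle
times, grasp codes outside 0–9.

## Known limitations

- Ball-joint chain without joint-limit or closed-loop (two feet on the
  ground while seated) constraints; multi-support indeterminacy is resolved
  by the lever rule, not contact mechanics.
- No muscle-level estimation; internal loads are resultant joint loads.
- The fixed-orientation diagonal inertia approximation above.
- Default angle graphs and general-factor curve shapes are stated
  defaults, not measured calibrations; replace the data files for
  site-specific use.
- BVH support is a read-only subset (hierarchy + Euler rotation channels).
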