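# ergoforces

Ergonomic risk assessment for repetitive industrial work, computed from
joint-angle motion capture.  The package is aimed at prevention technicians,
occupational-health engineers and biomechanics researchers who have per-frame
joint rotations of a worker (from an IMU suit or any capture pipeline) and
want objective, per-joint musculoskeletal-disorder risk figures for a
workstation — and for combinations of workstations in a job rotation —
instead of observational scores taken at hand-picked instants.

## What it computes

**Kinetics.** A worker is modelled as an articulated chain of rigid segments
(pelvis, lumbar and thoracic trunk, head, and bilateral arm/forearm/hand and
thigh/shin/foot chains).  Segment masses are population mass fractions of
body weight, CGs sit at fixed fractions of bone length, and inertia tensors
are diagonal matrices interpolated between P05/P50/P95 population anchors.
Whole-body support reactions (feet, seat, supported hands) are estimated
first so the net force on the body vanishes at every frame; internal loads
then propagate from the distal joints toward the pelvis:

    f_J = w_CG + if_CG + f_P + ef_P + r_P
    t_J = l_CG × (w_CG + if_CG) + l_P × (f_P + ef_P + r_P) + it_CG + t_P + et_P

with *w* segment weight, *if*/*it* inertial force/torque (d'Alembert),
*ef*/*et* declared external hand actions, *r* support reactions and *l*
lever vectors.  Forces are reported in kgf, torques in kg·m.

**Risk scoring.** Per frame and joint, five factor scores multiply:
AngleScore (1–2), AngularAccelerationScore (1–1.5), ForceScore (1–2),
TorqueScore (1–2.5), GripScore (wrists only, 1–2):

    FactorsPerPosture = AngleScore·AccelScore·ForceScore·TorqueScore·GripScore − 1
    RiskPerPosture %  = 100 · FactorsPerPosture / MaxFactorsPerPosture

where MaxFactorsPerPosture is 14 for every joint except the wrist (23).  The
cycle aggregates into a per-minute risk,

    RiskPerMinute % = 100 · Σ(Factors·Repetitiveness) · (60/CycleTime)
                      / (MaxFactorsPerPosture · 3600) · GeneralFactors

with GeneralFactors = Recovery × MicroPauses × Duration × Additional, and is
banded into a continuous 0–5 risk level (≤10 % acceptable … >40 %
unacceptable).  Risk maps and job rotations are weighted means of
RiskPerMinute rows.

## Worked example

Generate a synthetic lift-and-place cycle (a 3.5-kgf part carried with both
hands), then assess it for a P50 male under a 30-s cycle, 5 unrecovered
hours, 0.8 micro-pauses, 7.33 repetitive hours and 20 % additional factors:

```sh
ergoforces simulate --scenario lift_place --seed 7 \
    --out-capture cap.csv --out-actions act.csv
ergoforces assess --capture cap.csv --actions act.csv --config ctx.yaml
```

```
joint,risk_per_minute_pct,risk_level,valuation,interpretation,color
lumbar,1.9,0.19,No risk,Acceptable,#2e7d32
cervical,0.8,0.08,No risk,Acceptable,#2e7d32
shoulder_r,1.9,0.19,No risk,Acceptable,#2e7d32
elbow_r,0.7,0.07,No risk,Acceptable,#2e7d32
wrist_r,1.4,0.14,No risk,Acceptable,#2e7d32
...
```

Each row is one joint's whole-cycle risk: the light synthetic lift keeps
every joint far below the 10 % acceptability bound.  Combining captured
variants of one workstation (or workstations into a rotation) is the same
weighted mean everywhere:

```sh
ergoforces combine --map map.csv --label P003_COMBI
```

```
label,lumbar,cervical,...,elbow_l
P003_Medium,22.9,22.6,...,26.9
P003_Low,34.2,24.1,...,27.3
P003_Top,21.8,20.7,...,29.7
P003_COMBI,25.8,22.5,...,27.8
```

The same operations are available as a library: `build_human_model`,
`run_inverse_dynamics`, `assess`, `combine_rows`,
`simulate_calibration_protocol` (see `docs/methods.md` for the model
details and every tunable default).

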