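# Risk-scoring threshold tables.
#
# force: per-joint internal force bounds (kgf) for the P50 model of each sex,
#   plus the multiplicative coefficients that convert the P50 bounds to P05 /
#   P95.  Below `min` the ForceScore is 1, above `max` it is 2, linear between.
# torque: same structure, kg*m, TorqueScore in [1, 2.5].
# angular: per-joint angular-speed (deg/s) and angular-acceleration (deg/s^2)
#   thresholds; the acceleration column equals speed / 0.2 s (the stop rule).
#   Below `slow` the AngularAccelerationScore is 1, above `max` it is 1.5.
# grip: grasp-code -> GripScore lookup (wrist joints only).
# factor_maxima: the per-joint ceiling of each factor score; the maximum
#   factors-per-posture is their product minus 1 (14 everywhere, 23 at the
#   wrist).

force:
  lumbar:
    male:   {min: 44.6, max: 65.1, coef_p05: 0.87, coef_p95: 1.16}
    female: {min: 27.7, max: 46.9, coef_p05: 0.90, coef_p95: 1.13}
  cervical:
    male:   {min: 6.8, max: 8.8, coef_p05: 0.82, coef_p95: 1.20}
    female: {min: 5.5, max: 7.1, coef_p05: 0.83, coef_p95: 1.21}
  shoulder:
    male:   {min: 4.2, max: 13.6, coef_p05: 0.96, coef_p95: 1.05}
    female: {min: 3.1, max: 12.7, coef_p05: 0.96, coef_p95: 1.04}
  elbow:
    male:   {min: 1.9, max: 11.6, coef_p05: 0.98, coef_p95: 1.02}
    female: {min: 1.4, max: 11.2, coef_p05: 0.98, coef_p95: 1.02}
  wrist:
    male:   {min: 0.5, max: 10.6, coef_p05: 0.99, coef_p95: 1.01}
    female: {min: 0.4, max: 10.5, coef_p05: 0.99, coef_p95: 1.01}
  knee:
    male:   {min: 36.9, max: 80.6, coef_p05: 0.83, coef_p95: 1.18}
    female: {min: 27.2, max: 60.4, coef_p05: 0.84, coef_p95: 1.18}

torque:
  lumbar:
    male:   {min: 1.81, max: 22.95, coef_p05: 0.82, coef_p95: 1.22}
    female: {min: 1.08, max: 15.92, coef_p05: 0.85, coef_p95: 1.20}
  cervical:
    male:   {min: 0.15, max: 0.90, coef_p05: 0.73, coef_p95: 1.32}
    female: {min: 0.11, max: 0.62, coef_p05: 0.72, coef_p95: 1.35}
  shoulder:
    male:   {min: 0.49, max: 5.85, coef_p05: 0.92, coef_p95: 1.09}
    female: {min: 0.34, max: 5.15, coef_p05: 0.93, coef_p95: 1.09}
  elbow:
    male:   {min: 0.33, max: 3.20, coef_p05: 0.93, coef_p95: 1.08}
    female: {min: 0.23, max: 2.81, coef_p05: 0.93, coef_p95: 1.08}
  wrist:
    male:   {min: 0.04, max: 0.83, coef_p05: 0.97, coef_p95: 1.03}
    female: {min: 0.03, max: 0.70, coef_p05: 0.97, coef_p95: 1.03}
  knee:
    male:   {min: 3.73, max: 26.34, coef_p05: 0.86, coef_p95: 1.41}
    female: {min: 2.32, max: 17.66, coef_p05: 0.84, coef_p95: 1.44}

angular:
  lumbar:   {speed_slow: 10, speed_max: 51,  accel_slow: 50,  accel_max: 255}
  cervical: {speed_slow: 41, speed_max: 223, accel_slow: 205, accel_max: 1115}
  shoulder: {speed_slow: 53, speed_max: 247, accel_slow: 265, accel_max: 1235}
  elbow:    {speed_slow: 54, speed_max: 233, accel_slow: 270, accel_max: 1165}
  wrist:    {speed_slow: 66, speed_max: 224, accel_slow: 330, accel_max: 1120}
  knee:     {speed_slow: 40, speed_max: 133, accel_slow: 200, accel_max: 665}

grip:
  0: 1.0   # not specified
  1: 1.3   # appropriate wrap
  2: 1.8   # unprepared wrap
  3: 1.3   # appropriate hook
  4: 1.6   # reasonably appropriate hook
  5: 1.9   # unprepared hook
  6: 1.3   # pinch
  7: 1.6   # precision pinch
  8: 1.7   # appropriate open hand
  9: 2.0   # unprepared open hand

factor_maxima:
  lumbar:   {angle: 2.0, accel: 1.5, force: 2.0, torque: 2.5, grip: 1.0}
  cervical: {angle: 2.0, accel: 1.5, force: 2.0, torque: 2.5, grip: 1.0}
  shoulder: {angle: 2.0, accel: 1.5, force: 2.0, torque: 2.5, grip: 1.0}
  elbow:    {angle: 2.0, accel: 1.5, force: 2.0, torque: 2.5, grip: 1.0}
  wrist:    {angle: 1.6, accel: 1.5, force: 2.0, torque: 2.5, grip: 2.0}
  knee:     {angle: 2.0, accel: 1.5, force: 2.0, torque: 2.5, grip: 1.0}
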