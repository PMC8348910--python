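# Anthropometric reference data for the articulated human model.
#
# `percentiles` gives stature (m) and body weight (kg) anchors per sex for the
# P05/P50/P95 population percentiles (Huston's tables).  `segments` gives, per
# body segment: the fraction of total body weight (weight_fraction), the
# centre-of-gravity position as a fraction of bone length from the bone origin
# (cg_fraction), and the diagonal of the segment inertia tensor (kg*m^2,
# expressed in the global axis convention: x lateral, y vertical, z anterior)
# for each sex/percentile.  Bilateral segments carry per-side values (the two
# sides together with the axial segments sum to 1.0).
#
# The lumbar male P50 z-inertia is symmetrized to 0.148 to match the y entry,
# consistent with the structure of every neighbouring row.

percentiles:
  male:
    P05: {height: 1.649, weight: 66.21}
    P50: {height: 1.759, weight: 80.50}
    P95: {height: 1.869, weight: 96.41}
  female:
    P05: {height: 1.518, weight: 49.44}
    P50: {height: 1.618, weight: 59.85}
    P95: {height: 1.724, weight: 72.43}

segments:
  pelvis:
    bilateral: false
    weight_fraction: {male: 0.1242, female: 0.1672}
    cg_fraction: {male: 0.500, female: 0.500}
    inertia:
      male:
        P05: [0.065, 0.105, 0.105]
        P50: [0.091, 0.148, 0.148]
        P95: [0.122, 0.199, 0.190]
      female:
        P05: [0.052, 0.083, 0.086]
        P50: [0.075, 0.120, 0.123]
        P95: [0.106, 0.169, 0.174]
  lumbar:
    bilateral: false
    weight_fraction: {male: 0.1360, female: 0.1102}
    cg_fraction: {male: 0.500, female: 0.500}
    inertia:
      male:
        P05: [0.065, 0.105, 0.105]
        P50: [0.091, 0.148, 0.148]
        P95: [0.122, 0.199, 0.199]
      female:
        P05: [0.031, 0.050, 0.051]
        P50: [0.045, 0.072, 0.074]
        P95: [0.064, 0.102, 0.104]
  thorax:
    bilateral: false
    weight_fraction: {male: 0.2319, female: 0.1555}
    cg_fraction: {male: 0.497, female: 0.497}
    inertia:
      male:
        P05: [0.052, 0.075, 0.075]
        P50: [0.073, 0.106, 0.106]
        P95: [0.098, 0.142, 0.142]
      female:
        P05: [0.021, 0.031, 0.031]
        P50: [0.030, 0.044, 0.044]
        P95: [0.042, 0.062, 0.062]
  head:
    bilateral: false
    weight_fraction: {male: 0.0839, female: 0.0913}
    cg_fraction: {male: 0.300, female: 0.300}
    inertia:
      male:
        P05: [0.027, 0.014, 0.027]
        P50: [0.038, 0.019, 0.038]
        P95: [0.051, 0.026, 0.051]
      female:
        P05: [0.017, 0.009, 0.017]
        P50: [0.025, 0.013, 0.025]
        P95: [0.035, 0.018, 0.035]
  arm:
    bilateral: true
    weight_fraction: {male: 0.0277, female: 0.0285}
    cg_fraction: {male: 0.380, female: 0.379}
    inertia:
      male:
        P05: [0.002, 0.019, 0.019]
        P50: [0.003, 0.027, 0.027]
        P95: [0.004, 0.036, 0.036]
      female:
        P05: [0.001, 0.012, 0.012]
        P50: [0.002, 0.017, 0.017]
        P95: [0.003, 0.024, 0.024]
  forearm:
    bilateral: true
    weight_fraction: {male: 0.0173, female: 0.0171}
    cg_fraction: {male: 0.495, female: 0.496}
    inertia:
      male:
        P05: [0.001, 0.014, 0.014]
        P50: [0.001, 0.020, 0.020]
        P95: [0.001, 0.027, 0.027]
      female:
        P05: [0.001, 0.009, 0.009]
        P50: [0.001, 0.013, 0.013]
        P95: [0.001, 0.018, 0.018]
  hand:
    bilateral: true
    weight_fraction: {male: 0.0065, female: 0.0069}
    cg_fraction: {male: 0.800, female: 0.800}
    inertia:
      male:
        P05: [0.001, 0.001, 0.003]
        P50: [0.001, 0.001, 0.004]
        P95: [0.001, 0.001, 0.005]
      female:
        P05: [0.001, 0.001, 0.001]
        P50: [0.001, 0.001, 0.002]
        P95: [0.001, 0.001, 0.003]
  thigh:
    bilateral: true
    weight_fraction: {male: 0.1049, female: 0.1257}
    cg_fraction: {male: 0.532, female: 0.530}
    inertia:
      male:
        P05: [0.069, 0.017, 0.069]
        P50: [0.097, 0.024, 0.097]
        P95: [0.130, 0.032, 0.130]
      female:
        P05: [0.049, 0.013, 0.049]
        P50: [0.071, 0.018, 0.071]
        P95: [0.100, 0.025, 0.100]
  shin:
    bilateral: true
    weight_fraction: {male: 0.0428, female: 0.0453}
    cg_fraction: {male: 0.498, female: 0.494}
    inertia:
      male:
        P05: [0.006, 0.001, 0.006]
        P50: [0.008, 0.001, 0.008]
        P95: [0.011, 0.001, 0.011]
      female:
        P05: [0.003, 0.001, 0.003]
        P50: [0.005, 0.001, 0.005]
        P95: [0.007, 0.001, 0.007]
  foot:
    bilateral: true
    weight_fraction: {male: 0.0128, female: 0.0144}
    cg_fraction: {male: 0.500, female: 0.500}
    inertia:
      male:
        P05: [0.005, 0.005, 0.001]
        P50: [0.007, 0.007, 0.001]
        P95: [0.009, 0.009, 0.001]
      female:
        P05: [0.003, 0.003, 0.001]
        P50: [0.004, 0.005, 0.001]
        P95: [0.006, 0.007, 0.001]

# Segment lengths as fractions of stature (Drillis & Contini proportions,
# arranged so the vertical chain ankle+shin+thigh+pelvis+lumbar+thorax+head
# sums exactly to 1.0).  Editable; the paper-derived tables above do not
# constrain them.
length_fractions:
  ankle_height: 0.039
  shin: 0.246
  thigh: 0.245
  pelvis: 0.078
  lumbar: 0.090
  thorax: 0.120
  head: 0.182
  arm: 0.186
  forearm: 0.146
  hand: 0.108
  foot: 0.152
  hip_width: 0.191
  shoulder_width: 0.259
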