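# Default AngleScore graphs (editable).
#
# The scoring engine evaluates one piecewise-linear curve per rotation axis
# (breakpoints are [angle_deg, score] pairs, scores clamped at the curve
# ends), takes the maximum over axes, and caps the result at the joint's
# angle-factor ceiling.  The shoulder additionally uses a two-input table
# (antero-posterior rotation x elevation) built from the two band curves
# below and evaluated by bilinear interpolation.
#
# These defaults are NOT measured values: they are band edges adapted from
# the usual postural-load references (ISO 11226, REBA, RULA), with score 1.0
# at the neutral posture and saturation at the joint ceiling.  Replace them
# with calibrated curves by pointing the config at another file of the same
# shape.

lumbar:
  Rx: [[-20, 2.0], [0, 1.0], [20, 1.0], [60, 2.0]]   # extension- / flexion+
  Ry: [[-45, 2.0], [-10, 1.0], [10, 1.0], [45, 2.0]] # axial rotation
  Rz: [[-30, 2.0], [-10, 1.0], [10, 1.0], [30, 2.0]] # lateral bending

cervical:
  Rx: [[-20, 2.0], [0, 1.0], [20, 1.0], [45, 2.0]]
  Ry: [[-45, 2.0], [-15, 1.0], [15, 1.0], [45, 2.0]]
  Rz: [[-30, 2.0], [-10, 1.0], [10, 1.0], [30, 2.0]]

shoulder:
  table2d:
    # grid = outer max of the two band curves, bilinear between nodes
    x_axis: Rx   # antero-posterior rotation (extension- / flexion+)
    y_axis: Rz   # elevation / abduction
    x_bands: [[-60, 2.0], [-20, 1.3], [0, 1.0], [20, 1.0], [60, 1.5], [100, 1.8], [180, 2.0]]
    y_bands: [[-180, 2.0], [-90, 1.7], [-30, 1.2], [0, 1.0], [30, 1.2], [90, 1.7], [180, 2.0]]
  Ry: [[-90, 1.5], [-30, 1.0], [30, 1.0], [90, 1.5]]

elbow:
  Rx: [[-30, 2.0], [0, 1.0], [100, 1.0], [150, 2.0]]  # hyperextension- / flexion+
  Ry: [[-135, 2.0], [-60, 1.2], [0, 1.0], [60, 1.2], [135, 2.0]]  # pronosupination
  Rz: [[-30, 2.0], [-10, 1.0], [10, 1.0], [30, 2.0]]

wrist:
  Rx: [[-53, 1.6], [-15, 1.0], [15, 1.0], [53, 1.6]]  # flexion / extension
  Ry: [[-90, 1.6], [-30, 1.1], [0, 1.0], [30, 1.1], [90, 1.6]]
  Rz: [[-40, 1.6], [-10, 1.0], [10, 1.0], [40, 1.6]]  # radial / ulnar deviation

knee:
  Rx: [[-10, 2.0], [0, 1.0], [30, 1.0], [120, 2.0]]
  Ry: [[-30, 2.0], [-10, 1.0], [10, 1.0], [30, 2.0]]
  Rz: [[-30, 2.0], [-10, 1.0], [10, 1.0], [30, 2.0]]
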