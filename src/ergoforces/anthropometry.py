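"""Articulated human model scaled from worker anthropometry.

The body is modelled as a tree of rigid bars (pelvis root, trunk chain,
head, and bilateral arm/leg chains).  Segment masses are fixed fractions of
body weight, centres of gravity sit at a fixed fraction of each bone's
length, and segment inertia tensors are diagonal matrices interpolated
between population-percentile anchors on body weight.  All reference data
live in ``data/anthropometry.yaml`` and can be overridden.

Forces are carried in kilogram-force (kgf) and torques in kg·m throughout
the package; ``G0`` is the conversion constant to SI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

G0 = 9.81  # m/s^2, kgf <-> N conversion constant

SEXES = ("male", "female")
PERCENTILES = ("P05", "P50", "P95")

#: axial segments appear once, these appear once per side
BILATERAL_BASES = ("arm", "forearm", "hand", "thigh", "shin", "foot")
AXIAL_SEGMENTS = ("pelvis", "lumbar", "thorax", "head")

#: capture joints (rotation inputs), one per bone of the kinematic tree
JOINTS = (
    "pelvis", "lumbar", "thorax", "cervical",
    "shoulder_r", "elbow_r", "wrist_r", "hip_r", "knee_r", "ankle_r",
    "shoulder_l", "elbow_l", "wrist_l", "hip_l", "knee_l", "ankle_l",
)

#: joints that receive a risk score
SCORED_JOINTS = (
    "lumbar", "cervical",
    "shoulder_r", "elbow_r", "wrist_r", "knee_r",
    "shoulder_l", "elbow_l", "wrist_l", "knee_l",
)

JOINT_TO_BONE = {
    "pelvis": "pelvis", "lumbar": "lumbar", "thorax": "thorax",
    "cervical": "head",
    "shoulder_r": "arm_r", "elbow_r": "forearm_r", "wrist_r": "hand_r",
    "hip_r": "thigh_r", "knee_r": "shin_r", "ankle_r": "foot_r",
    "shoulder_l": "arm_l", "elbow_l": "forearm_l", "wrist_l": "hand_l",
    "hip_l": "thigh_l", "knee_l": "shin_l", "ankle_l": "foot_l",
}
BONE_TO_JOINT = {v: k for k, v in JOINT_TO_BONE.items()}


def load_reference_data(path=None) -> dict:
    """Load the anthropometric reference tables (packaged YAML by default)."""
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    text = resources.files("ergoforces.data").joinpath("anthropometry.yaml").read_text()
    return yaml.safe_load(text)


_REFERENCE = load_reference_data()


def _interp_extrap(x: float, xs, ys) -> float:
    """Piecewise-linear interpolation, linear extrapolation beyond the ends."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if x <= xs[0]:
        i = 0
    elif x >= xs[-1]:
        i = len(xs) - 2
    else:
        return float(np.interp(x, xs, ys))
    slope = (ys[i + 1] - ys[i]) / (xs[i + 1] - xs[i])
    return float(ys[i] + slope * (x - xs[i]))


@dataclass(frozen=True)
class SegmentSpec:
    """One rigid segment: mass fraction, CG position and inertia diagonal."""

    name: str
    weight_fraction: float     # fraction of body weight, per side for limbs
    cg_fraction: float         # CG position along the bone, 0 = origin joint
    inertia_diag: np.ndarray   # kg*m^2, diagonal in the global convention
    length: float              # m

    def __post_init__(self):
        if not 0 < self.weight_fraction < 1:
            raise ValueError(f"{self.name}: weight_fraction out of (0,1)")
        if not 0 < self.cg_fraction <= 1:
            raise ValueError(f"{self.name}: cg_fraction out of (0,1]")
        if np.any(np.asarray(self.inertia_diag) <= 0):
            raise ValueError(f"{self.name}: inertia components must be > 0")
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be > 0")


@dataclass(frozen=True)
class HumanModel:
    """Scaled articulated model of one worker."""

    sex: str
    height: float              # m
    body_weight: float         # kg
    shoulder_width: float      # m, between shoulder joint centres
    hip_width: float           # m, between hip joint centres
    root_height: float         # m, pelvis centre above ground in neutral pose
    segments: Mapping[str, SegmentSpec] = field(repr=False)
    preparation: int = 1       # 0 sensitive .. 3 specially trained

    def __post_init__(self):
        total = sum(s.weight_fraction for s in self.segments.values())
        if abs(total - 1.0) > 0.005:
            raise ValueError(f"segment weight fractions sum to {total:.4f}, not 1")
        if self.preparation not in (0, 1, 2, 3):
            raise ValueError("preparation level must be 0..3")

    def segment(self, name: str) -> SegmentSpec:
        try:
            return self.segments[name]
        except KeyError:
            raise KeyError(f"unknown segment {name!r}") from None

    def segment_mass(self, name: str) -> float:
        """Segment mass in kg."""
        return self.segment(name).weight_fraction * self.body_weight


def _segment_specs(sex: str, height: float, body_weight: float,
                   reference: dict) -> dict[str, SegmentSpec]:
    frac = reference["length_fractions"]
    lengths = {
        "pelvis": frac["pelvis"], "lumbar": frac["lumbar"],
        "thorax": frac["thorax"], "head": frac["head"],
        "arm": frac["arm"], "forearm": frac["forearm"], "hand": frac["hand"],
        "thigh": frac["thigh"], "shin": frac["shin"], "foot": frac["foot"],
    }
    anchors = reference["percentiles"][sex]
    anchor_w = [anchors[p]["weight"] for p in PERCENTILES]

    specs: dict[str, SegmentSpec] = {}
    for base, entry in reference["segments"].items():
        tensors = np.array([entry["inertia"][sex][p] for p in PERCENTILES])
        diag = np.array([
            _interp_extrap(body_weight, anchor_w, tensors[:, k]) for k in range(3)
        ])
        diag = np.maximum(diag, 1e-6)
        spec = dict(
            weight_fraction=entry["weight_fraction"][sex],
            cg_fraction=entry["cg_fraction"][sex],
            inertia_diag=diag,
            length=lengths[base] * height,
        )
        if entry["bilateral"]:
            for side in ("r", "l"):
                specs[f"{base}_{side}"] = SegmentSpec(name=f"{base}_{side}", **spec)
        else:
            specs[base] = SegmentSpec(name=base, **spec)
    return specs


def interpolate_weight(height: float, sex: str, reference: dict | None = None) -> float:
    """Body weight (kg) for a stature, from the sex's percentile anchors."""
    reference = reference or _REFERENCE
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    anchors = reference["percentiles"][sex]
    hs = [anchors[p]["height"] for p in PERCENTILES]
    ws = [anchors[p]["weight"] for p in PERCENTILES]
    if not hs[0] <= height <= hs[-1]:
        warnings.warn(
            f"height {height:.3f} m outside the tabulated [{hs[0]}, {hs[-1]}] m "
            "range; extrapolating linearly", stacklevel=2)
    return _interp_extrap(height, hs, ws)


def build_human_model(height: float, elbow_span: float | None = None,
                      sex: str = "male", weight: float | None = None,
                      preparation: int = 1,
                      shoulder_span_ratio: float = 0.85,
                      reference: dict | None = None) -> HumanModel:
    """Build a worker model from stature, elbow span and (optionally) weight.

    When ``weight`` is omitted it is interpolated on ``height`` between the
    population percentile anchors for ``sex``.  The elbow span (distance
    between olecranons in the neutral posture, projected on the frontal
    plane) sets the shoulder width through the configurable linear ratio
    ``shoulder_span_ratio``; without it the shoulder width defaults to its
    stature proportion.
    """
    reference = reference or _REFERENCE
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    if not 1.30 <= height <= 2.10:
        raise ValueError(f"height {height} m outside the supported [1.30, 2.10] m range")
    if elbow_span is not None and elbow_span <= 0:
        raise ValueError("elbow_span must be > 0")

    body_weight = float(weight) if weight is not None else interpolate_weight(height, sex, reference)
    frac = reference["length_fractions"]
    if elbow_span is not None:
        shoulder_width = shoulder_span_ratio * elbow_span
    else:
        shoulder_width = frac["shoulder_width"] * height
    return HumanModel(
        sex=sex,
        height=float(height),
        body_weight=body_weight,
        shoulder_width=shoulder_width,
        hip_width=frac["hip_width"] * height,
        root_height=(frac["ankle_height"] + frac["shin"] + frac["thigh"]) * height,
        segments=_segment_specs(sex, height, body_weight, reference),
        preparation=preparation,
    )


def scale_to_percentile(model: HumanModel, sex: str, percentile: str,
                        reference: dict | None = None) -> HumanModel:
    """Return the model rescaled to a population percentile of ``sex``.

    The captured joint rotations stay applicable: only the anthropometry
    (stature, weight, widths, tensors) changes.
    """
    reference = reference or _REFERENCE
    if percentile not in PERCENTILES:
        raise ValueError(f"unknown percentile {percentile!r}; expected one of {PERCENTILES}")
    anchors = reference["percentiles"][sex]
    return build_human_model(
        height=anchors[percentile]["height"],
        sex=sex,
        weight=anchors[percentile]["weight"],
        preparation=model.preparation,
        reference=reference,
    )


def segment_weight_force(model: HumanModel, segment: str,
                         gravity: float = G0) -> np.ndarray:
    """Gravity load of one segment as a kgf vector (global frame, -y down)."""
    mass = model.segment_mass(segment)
    return np.array([0.0, -mass * gravity / G0, 0.0])


# ---------------------------------------------------------------------------
# skeleton topology (neutral pose: y up, x lateral to the worker's left,
# z anterior; arms hanging at the sides)

@dataclass(frozen=True)
class Bone:
    name: str
    parent: str | None
    attach: str              # "root" | "parent_end" | "shoulder" | "hip"
    side: int                # +1 left, -1 right, 0 axial
    direction: tuple         # bone axis in its local frame (unit vector)


SKELETON: tuple[Bone, ...] = (
    Bone("pelvis", None, "root", 0, (0, 1, 0)),
    Bone("lumbar", "pelvis", "parent_end", 0, (0, 1, 0)),
    Bone("thorax", "lumbar", "parent_end", 0, (0, 1, 0)),
    Bone("head", "thorax", "parent_end", 0, (0, 1, 0)),
    Bone("arm_r", "thorax", "shoulder", -1, (0, -1, 0)),
    Bone("forearm_r", "arm_r", "parent_end", -1, (0, -1, 0)),
    Bone("hand_r", "forearm_r", "parent_end", -1, (0, -1, 0)),
    Bone("arm_l", "thorax", "shoulder", +1, (0, -1, 0)),
    Bone("forearm_l", "arm_l", "parent_end", +1, (0, -1, 0)),
    Bone("hand_l", "forearm_l", "parent_end", +1, (0, -1, 0)),
    Bone("thigh_r", "pelvis", "hip", -1, (0, -1, 0)),
    Bone("shin_r", "thigh_r", "parent_end", -1, (0, -1, 0)),
    Bone("foot_r", "shin_r", "parent_end", -1, (0, 0, 1)),
    Bone("thigh_l", "pelvis", "hip", +1, (0, -1, 0)),
    Bone("shin_l", "thigh_l", "parent_end", +1, (0, -1, 0)),
    Bone("foot_l", "shin_l", "parent_end", +1, (0, 0, 1)),
)

BONE_ORDER = tuple(b.name for b in SKELETON)
BONE_INDEX = {name: i for i, name in enumerate(BONE_ORDER)}
CHILDREN: dict[str, tuple[str, ...]] = {
    b.name: tuple(c.name for c in SKELETON if c.parent == b.name) for b in SKELETON
}


def neutral_model(sex: str = "male", percentile: str = "P50",
                  preparation: int = 1) -> HumanModel:
    """Convenience constructor for an exact percentile model."""
    anchors = _REFERENCE["percentiles"][sex]
    return build_human_model(
        height=anchors[percentile]["height"], sex=sex,
        weight=anchors[percentile]["weight"], preparation=preparation)
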