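"""Forward kinematics and numerical differentiation of capture series.

A capture is a uniformly sampled series of per-joint Euler rotations
(Rx, Ry, Rz, degrees, right-hand rule, intrinsic x-y-z composition) relative
to the neutral posture.  Forward kinematics composes these rotations along
the skeleton tree to obtain joint-centre and segment-CG trajectories in the
global frame (y vertical up, x lateral, z anterior).  Velocities and
accelerations are central differences (one-sided at the series ends), per
axis for the angular curves and per component for the CG displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial.transform import Rotation

from .anthropometry import BONE_INDEX, BONE_ORDER, JOINTS, SKELETON, HumanModel


@dataclass
class CaptureSeries:
    """Per-frame joint rotations at a fixed frame rate.

    ``angles`` has shape (n_frames, n_joints, 3) in degrees; joint order is
    given by ``joints``.
    """

    frame_rate: float
    joints: tuple
    angles: np.ndarray

    def __post_init__(self):
        self.joints = tuple(self.joints)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.angles.ndim != 3 or self.angles.shape[1:] != (len(self.joints), 3):
            raise ValueError("angles must have shape (n_frames, n_joints, 3)")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("capture contains non-finite rotation values")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def joint_index(self, joint: str) -> int:
        try:
            return self.joints.index(joint)
        except ValueError:
            raise KeyError(f"joint {joint!r} not present in capture") from None

    def joint_angles(self, joint: str) -> np.ndarray:
        return self.angles[:, self.joint_index(joint), :]

    def select(self, start: int | None = None, end: int | None = None) -> "CaptureSeries":
        """Inclusive frame-range selection."""
        sl = slice(start, None if end is None else end + 1)
        return CaptureSeries(self.frame_rate, self.joints, self.angles[sl])


def empty_capture(n_frames: int, frame_rate: float = 60.0) -> CaptureSeries:
    """All-zero (neutral pose) capture over the full joint set."""
    return CaptureSeries(frame_rate, JOINTS, np.zeros((n_frames, len(JOINTS), 3)))


def _rotations(series: CaptureSeries) -> dict[str, np.ndarray]:
    """Per-bone stacks of local rotation matrices, shape (n, 3, 3)."""
    n = series.n_frames
    eye = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    out = {}
    for bone in BONE_ORDER:
        joint = _bone_joint(bone)
        if joint in series.joints:
            ang = series.joint_angles(joint)
            out[bone] = Rotation.from_euler("XYZ", ang, degrees=True).as_matrix()
        else:
            out[bone] = eye
    return out


def _bone_joint(bone: str) -> str:
    from .anthropometry import BONE_TO_JOINT
    return BONE_TO_JOINT[bone]


@dataclass
class ForwardKinematics:
    """Global-frame bone trajectories: origins, ends, CGs and orientations."""

    bones: tuple
    origins: np.ndarray   # (n, n_bones, 3) joint centres, m
    ends: np.ndarray      # (n, n_bones, 3) distal bone ends, m
    cg: np.ndarray        # (n, n_bones, 3) segment CGs, m
    R: np.ndarray         # (n, n_bones, 3, 3) global bone orientations

    def bone_slice(self, bone: str) -> int:
        return BONE_INDEX[bone]


def forward_kinematics(model: HumanModel, series: CaptureSeries) -> ForwardKinematics:
    """Compose rotations along the skeleton from the pelvis origin.

    Joint centres follow parent orientation and bone lengths; the CG of a
    segment sits at its ``cg_fraction`` along the bone from its origin.
    Raises ``KeyError`` naming the joint if a required chain joint is absent.
    """
    for joint in ("pelvis",):
        if joint not in series.joints:
            raise KeyError(f"capture misses required joint {joint!r}")
    n = series.n_frames
    nb = len(BONE_ORDER)
    R_local = _rotations(series)
    origins = np.zeros((n, nb, 3))
    ends = np.zeros((n, nb, 3))
    cg = np.zeros((n, nb, 3))
    R = np.zeros((n, nb, 3, 3))

    for bone in SKELETON:
        i = BONE_INDEX[bone.name]
        seg = model.segment(bone.name)
        if bone.parent is None:
            origin = np.broadcast_to(
                np.array([0.0, model.root_height, 0.0]), (n, 3)).copy()
            R_parent = np.broadcast_to(np.eye(3), (n, 3, 3))
        else:
            j = BONE_INDEX[bone.parent]
            R_parent = R[:, j]
            parent_seg = model.segment(bone.parent)
            parent_axis = np.asarray(SKELETON[j].direction, dtype=float)
            if bone.attach == "parent_end":
                offset = parent_axis * parent_seg.length
            elif bone.attach == "shoulder":
                offset = parent_axis * parent_seg.length + np.array(
                    [bone.side * model.shoulder_width / 2.0, 0.0, 0.0])
            elif bone.attach == "hip":
                offset = np.array([bone.side * model.hip_width / 2.0, 0.0, 0.0])
            else:  # pragma: no cover - topology is static
                raise ValueError(f"unknown attachment {bone.attach!r}")
            origin = origins[:, j] + np.einsum("nij,j->ni", R_parent, offset)
        R[:, i] = np.einsum("nij,njk->nik", R_parent, R_local[bone.name])
        axis = np.asarray(bone.direction, dtype=float)
        bone_vec = np.einsum("nij,j->ni", R[:, i], axis * seg.length)
        origins[:, i] = origin
        ends[:, i] = origin + bone_vec
        cg[:, i] = origin + bone_vec * seg.cg_fraction
    return ForwardKinematics(BONE_ORDER, origins, ends, cg, R)


@dataclass
class Derivatives:
    """First and second time derivatives of the capture."""

    ang_vel: np.ndarray   # (n, n_joints, 3) deg/s
    ang_acc: np.ndarray   # (n, n_joints, 3) deg/s^2
    cg_vel: np.ndarray    # (n, n_bones, 3) m/s
    cg_acc: np.ndarray    # (n, n_bones, 3) m/s^2


def differentiate(series: CaptureSeries, fk: ForwardKinematics | None = None,
                  smooth_window: int | None = None,
                  smooth_polyorder: int = 3) -> Derivatives:
    """Central-difference velocities and accelerations.

    ``smooth_window`` enables Savitzky–Golay pre-smoothing of the angle and
    CG curves before differencing (odd window length, in frames); the
    default differentiates the raw curves.
    """
    if series.n_frames < 3:
        raise ValueError("differentiation needs at least 3 frames")
    dt = 1.0 / series.frame_rate
    angles = series.angles
    if smooth_window is not None:
        angles = savgol_filter(angles, smooth_window, smooth_polyorder, axis=0)
    ang_vel = np.gradient(angles, dt, axis=0)
    ang_acc = np.gradient(ang_vel, dt, axis=0)

    if fk is None:
        from .anthropometry import neutral_model
        fk = forward_kinematics(neutral_model(), series)
    cg = fk.cg
    if smooth_window is not None:
        cg = savgol_filter(cg, smooth_window, smooth_polyorder, axis=0)
    cg_vel = np.gradient(cg, dt, axis=0)
    cg_acc = np.gradient(cg_vel, dt, axis=0)
    return Derivatives(ang_vel, ang_acc, cg_vel, cg_acc)


def joint_angular_modulus(series: CaptureSeries, deriv: Derivatives,
                          joint: str, order: int = 2) -> np.ndarray:
    """Modulus of the angular velocity (order=1) or acceleration (order=2)."""
    j = series.joint_index(joint)
    arr = deriv.ang_vel if order == 1 else deriv.ang_acc
    return np.linalg.norm(arr[:, j, :], axis=1)
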