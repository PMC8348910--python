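"""Two-stage inverse dynamics over the articulated model.

Stage one treats the body as a whole and estimates the reactions at the
active support points (feet, seat, supported hands) so that the net force
on the body is zero at every frame: reactions balance segment weights,
inertial forces (d'Alembert, opposite the CG accelerations) and declared
external hand actions.  With several simultaneous supports the resultant is
distributed by a lever rule on the horizontal projection of the load centre
between the support points.

Stage two isolates each segment and propagates force and torque vectors
joint by joint from the distal ends (wrists, ankles) toward the pelvis:

    f_J = w_CG + if_CG + sum(f_child) + ef + r
    t_J = l_CG x (w_CG + if_CG + ef + r) + sum(l_child x f_child + t_child)
          + it_CG + et

where ``w`` is the segment weight at its CG, ``if``/``it`` the inertial
force/torque, ``ef``/``et`` external hand actions (applied at the hand CG),
``r`` support reactions, and ``l`` lever vectors from the joint.  Forces are
kgf, torques kg·m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .anthropometry import (
    BONE_INDEX,
    BONE_ORDER,
    BONE_TO_JOINT,
    CHILDREN,
    G0,
    HumanModel,
)
from .kinematics import CaptureSeries, Derivatives, ForwardKinematics, differentiate, forward_kinematics

logger = logging.getLogger(__name__)

HANDS = ("right", "left", "both")


@dataclass(frozen=True)
class ExternalAction:
    """One hand action over an inclusive, 0-based frame range.

    Force (kgf) and torque (kg·m) are expressed in the pelvis-linked frame:
    y vertical, x/z parallel to the ground, rotating with the pelvis yaw.
    """

    frame_start: int
    frame_end: int
    hand: str
    force: tuple = (0.0, 0.0, 0.0)
    torque: tuple = (0.0, 0.0, 0.0)
    grasp: int = 0

    def __post_init__(self):
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}")
        if self.frame_start > self.frame_end:
            raise ValueError("frame_start must be <= frame_end")
        if self.frame_start < 0:
            raise ValueError("frame ranges are 0-based and non-negative")
        if self.grasp not in range(10):
            raise ValueError("grasp code must be 0..9")


@dataclass(frozen=True)
class SupportDeclaration:
    """User-declared support over an inclusive frame range."""

    frame_start: int
    frame_end: int
    kind: str  # seated | hand_l | hand_r

    def __post_init__(self):
        if self.kind not in ("seated", "hand_l", "hand_r"):
            raise ValueError("kind must be seated, hand_l or hand_r")
        if self.frame_start > self.frame_end:
            raise ValueError("frame_start must be <= frame_end")


@dataclass
class SupportState:
    """Per-frame support flags: feet, seat, hands."""

    foot_r: np.ndarray
    foot_l: np.ndarray
    seated: np.ndarray
    hand_r: np.ndarray
    hand_l: np.ndarray

    def any_support(self) -> np.ndarray:
        return self.foot_r | self.foot_l | self.seated | self.hand_r | self.hand_l


def detect_foot_support(series: CaptureSeries, fk: ForwardKinematics,
                        deriv: Derivatives | None = None,
                        height_threshold: float = 0.05,
                        speed_threshold: float = 0.25,
                        declarations: list[SupportDeclaration] | None = None,
                        ) -> SupportState:
    """Flag supported feet from foot height and speed.

    A foot is supported when its height above the frame's lowest foot point
    stays under ``height_threshold`` (m) and its CG speed under
    ``speed_threshold`` (m/s).  Declared seated/hand-support ranges override
    detection: seated frames drop the foot flags in favour of a seat support.
    Frames with nothing supported fall back to both feet, with a warning.
    """
    if deriv is None:
        deriv = differentiate(series, fk)
    n = series.n_frames
    idx_r, idx_l = BONE_INDEX["foot_r"], BONE_INDEX["foot_l"]
    # lowest point of each foot (origin=ankle or distal end)
    h_r = np.minimum(fk.origins[:, idx_r, 1], fk.ends[:, idx_r, 1])
    h_l = np.minimum(fk.origins[:, idx_l, 1], fk.ends[:, idx_l, 1])
    ground = np.minimum(h_r, h_l)
    sp_r = np.linalg.norm(deriv.cg_vel[:, idx_r], axis=1)
    sp_l = np.linalg.norm(deriv.cg_vel[:, idx_l], axis=1)
    foot_r = (h_r - ground < height_threshold) & (sp_r < speed_threshold)
    foot_l = (h_l - ground < height_threshold) & (sp_l < speed_threshold)

    seated = np.zeros(n, dtype=bool)
    hand_r = np.zeros(n, dtype=bool)
    hand_l = np.zeros(n, dtype=bool)
    for decl in declarations or ():
        sl = slice(decl.frame_start, min(decl.frame_end, n - 1) + 1)
        {"seated": seated, "hand_r": hand_r, "hand_l": hand_l}[decl.kind][sl] = True
    foot_r = foot_r & ~seated
    foot_l = foot_l & ~seated

    none = ~(foot_r | foot_l | seated | hand_r | hand_l)
    if np.any(none):
        logger.warning("no support detected on %d frame(s); assuming both feet",
                       int(none.sum()))
        foot_r = foot_r | none
        foot_l = foot_l | none
    return SupportState(foot_r, foot_l, seated, hand_r, hand_l)


@dataclass
class JointLoadSeries:
    """Per-frame, per-joint force/torque vectors plus support reactions."""

    joints: tuple
    force: np.ndarray        # (n, n_joints, 3) kgf
    torque: np.ndarray       # (n, n_joints, 3) kg*m
    reactions: list          # per frame: dict support-name -> kgf vector
    support: SupportState

    def joint_index(self, joint: str) -> int:
        try:
            return self.joints.index(joint)
        except ValueError:
            raise KeyError(f"no load computed for joint {joint!r}") from None

    def force_modulus(self, joint: str) -> np.ndarray:
        return np.linalg.norm(self.force[:, self.joint_index(joint)], axis=1)

    def torque_modulus(self, joint: str) -> np.ndarray:
        return np.linalg.norm(self.torque[:, self.joint_index(joint)], axis=1)

    def total_reaction(self) -> np.ndarray:
        """Summed support reaction per frame, shape (n, 3) kgf."""
        out = np.zeros((len(self.reactions), 3))
        for i, r in enumerate(self.reactions):
            for v in r.values():
                out[i] += v
        return out


def _pelvis_yaw_matrix(R_pelvis: np.ndarray) -> np.ndarray:
    """Yaw-only (rotation about global y) part of the pelvis orientation."""
    fwd = R_pelvis[..., :, 2]  # pelvis z axis in global frame
    yaw = np.arctan2(fwd[..., 0], fwd[..., 2])
    c, s = np.cos(yaw), np.sin(yaw)
    out = np.zeros(R_pelvis.shape[:-2] + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def resolve_actions(series: CaptureSeries, fk: ForwardKinematics,
                    actions: list[ExternalAction] | None):
    """Per-frame external hand loads in the global frame.

    Returns (force, torque, grasp): force/torque arrays of shape
    (n, 2, 3) for (right, left) hands and an int grasp-code array (n, 2).
    Declared vectors live in the pelvis-linked yaw frame; a "both" action
    splits its vector 50/50 between the hands.
    """
    n = series.n_frames
    force = np.zeros((n, 2, 3))
    torque = np.zeros((n, 2, 3))
    grasp = np.zeros((n, 2), dtype=int)
    if not actions:
        return force, torque, grasp
    yaw = _pelvis_yaw_matrix(fk.R[:, BONE_INDEX["pelvis"]])
    for act in actions:
        if act.frame_end >= n:
            raise ValueError(
                f"action frames [{act.frame_start}, {act.frame_end}] exceed capture ({n} frames)")
        sl = slice(act.frame_start, act.frame_end + 1)
        f_glob = np.einsum("nij,j->ni", yaw[sl], np.asarray(act.force, dtype=float))
        t_glob = np.einsum("nij,j->ni", yaw[sl], np.asarray(act.torque, dtype=float))
        sides = {"right": (0,), "left": (1,), "both": (0, 1)}[act.hand]
        share = 0.5 if act.hand == "both" else 1.0
        for s in sides:
            force[sl, s] += share * f_glob
            torque[sl, s] += share * t_glob
            grasp[sl, s] = act.grasp
    return force, torque, grasp


def _support_points(fk: ForwardKinematics, state: SupportState, frame: int) -> dict:
    pts = {}
    if state.foot_r[frame]:
        pts["foot_r"] = fk.cg[frame, BONE_INDEX["foot_r"]]
    if state.foot_l[frame]:
        pts["foot_l"] = fk.cg[frame, BONE_INDEX["foot_l"]]
    if state.seated[frame]:
        pts["seat"] = fk.origins[frame, BONE_INDEX["pelvis"]]
    if state.hand_r[frame]:
        pts["hand_r"] = fk.cg[frame, BONE_INDEX["hand_r"]]
    if state.hand_l[frame]:
        pts["hand_l"] = fk.cg[frame, BONE_INDEX["hand_l"]]
    return pts


def distribute_reaction(total: np.ndarray, points: dict, load_centre: np.ndarray,
                        scheme: str = "lever") -> dict:
    """Split the whole-body reaction among support points.

    ``lever`` projects the horizontal load centre on the segment between two
    supports (clamped to [0, 1]); with more than two supports a minimal-norm
    least-squares split balancing the horizontal moments is used, and
    ``equal`` splits uniformly.  Weights always sum to 1, so force
    equilibrium is exact regardless of scheme.
    """
    names = list(points)
    if not names:
        raise ValueError("no active support points")
    if scheme == "equal" or len(names) == 1:
        w = np.full(len(names), 1.0 / len(names))
    elif len(names) == 2:
        a = points[names[0]][[0, 2]]
        b = points[names[1]][[0, 2]]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.5 if denom < 1e-12 else float(np.clip((load_centre[[0, 2]] - a) @ ab / denom, 0.0, 1.0))
        w = np.array([1.0 - t, t])
    else:
        M = np.ones((3, len(names)))
        for k, nm in enumerate(names):
            M[1, k] = points[nm][0]
            M[2, k] = points[nm][2]
        b = np.array([1.0, load_centre[0], load_centre[2]])
        w, *_ = np.linalg.lstsq(M, b, rcond=None)
        w = np.clip(w, 0.0, None)
        s = w.sum()
        w = np.full(len(names), 1.0 / len(names)) if s < 1e-12 else w / s
    return {nm: wk * total for nm, wk in zip(names, w)}


def run_inverse_dynamics(model: HumanModel, series: CaptureSeries,
                         actions: list[ExternalAction] | None = None,
                         supports: list[SupportDeclaration] | None = None,
                         gravity: float = G0,
                         support_scheme: str = "lever",
                         smooth_window: int | None = None,
                         ) -> JointLoadSeries:
    """Full per-frame inverse dynamics ending at the pelvis.

    Returns the load series for every joint of the tree (the scored set plus
    hips, ankles, thorax and lumbar).  ``gravity`` scales the segment
    weights only (kgf stays defined through the standard constant), letting
    callers examine the purely inertial response.
    """
    fk = forward_kinematics(model, series)
    deriv = differentiate(series, fk, smooth_window=smooth_window)
    state = detect_foot_support(series, fk, deriv, declarations=supports)
    ef, et, _ = resolve_actions(series, fk, actions)

    n = series.n_frames
    nb = len(BONE_ORDER)
    masses = np.array([model.segment_mass(b) for b in BONE_ORDER])
    tensors = np.array([model.segment(b).inertia_diag for b in BONE_ORDER])

    # per-bone point loads at the CG
    weight = np.zeros((n, nb, 3))
    weight[:, :, 1] = -masses * gravity / G0
    inertial = -masses[None, :, None] * deriv.cg_acc / G0

    # inertial torque from each segment's absolute angular rates (rad/s),
    # extracted from the global orientation matrices: [omega]x = R' R^T
    dt = 1.0 / series.frame_rate
    R_dot = np.gradient(fk.R, dt, axis=0)
    W = np.einsum("nbij,nbkj->nbik", R_dot, fk.R)
    omega = np.stack([W[..., 2, 1], W[..., 0, 2], W[..., 1, 0]], axis=-1)
    alpha = np.gradient(omega, dt, axis=0)
    t_alpha = tensors[None, :, :] * alpha
    t_omega = tensors[None, :, :] * omega
    inertial_torque = -(t_alpha + np.cross(omega, t_omega)) / G0

    # external loads land on the hand segments
    ext_f = np.zeros((n, nb, 3))
    ext_t = np.zeros((n, nb, 3))
    ext_f[:, BONE_INDEX["hand_r"]] = ef[:, 0]
    ext_f[:, BONE_INDEX["hand_l"]] = ef[:, 1]
    ext_t[:, BONE_INDEX["hand_r"]] = et[:, 0]
    ext_t[:, BONE_INDEX["hand_l"]] = et[:, 1]

    support_bone = {"foot_r": "foot_r", "foot_l": "foot_l",
                    "hand_r": "hand_r", "hand_l": "hand_l", "seat": "pelvis"}

    force = np.zeros((n, nb, 3))
    torque = np.zeros((n, nb, 3))
    reactions: list[dict] = []

    # postorder over the static topology (children before parents)
    order = []

    def _visit(bone):
        for c in CHILDREN[bone]:
            _visit(c)
        order.append(bone)

    _visit("pelvis")

    for t in range(n):
        body_load = weight[t] + inertial[t] + ext_f[t]
        total_reaction = -body_load.sum(axis=0)
        vert = body_load[:, 1]
        wsum = vert.sum()
        if abs(wsum) > 1e-9:
            centre = (fk.cg[t] * vert[:, None]).sum(axis=0) / wsum
        else:
            centre = (fk.cg[t] * masses[:, None]).sum(axis=0) / masses.sum()
        pts = _support_points(fk, state, t)
        try:
            reac = distribute_reaction(total_reaction, pts, centre, support_scheme)
        except ValueError as exc:  # pragma: no cover - detection guarantees support
            raise ValueError(f"frame {t}: {exc}") from exc
        reactions.append(reac)

        reac_at = np.zeros((nb, 3))
        for nm, vec in reac.items():
            reac_at[BONE_INDEX[support_bone[nm]]] += vec

        for bone in order:
            i = BONE_INDEX[bone]
            point_load = weight[t, i] + inertial[t, i] + ext_f[t, i] + reac_at[i]
            f = point_load.copy()
            lever_cg = fk.cg[t, i] - fk.origins[t, i]
            tq = np.cross(lever_cg, point_load) + inertial_torque[t, i] + ext_t[t, i]
            for child in CHILDREN[bone]:
                j = BONE_INDEX[child]
                f += force[t, j]
                lever = fk.origins[t, j] - fk.origins[t, i]
                tq += np.cross(lever, force[t, j]) + torque[t, j]
            force[t, i] = f
            torque[t, i] = tq

    joints = tuple(BONE_TO_JOINT[b] for b in BONE_ORDER)
    return JointLoadSeries(joints, force, torque, reactions, state)


def joint_force(model: HumanModel, series: CaptureSeries, joint: str,
                actions: list[ExternalAction] | None = None,
                supports: list[SupportDeclaration] | None = None,
                **kwargs) -> np.ndarray:
    """Per-frame force vector at one joint (convenience wrapper)."""
    loads = run_inverse_dynamics(model, series, actions, supports, **kwargs)
    return loads.force[:, loads.joint_index(joint)]


def joint_torque(model: HumanModel, series: CaptureSeries, joint: str,
                 actions: list[ExternalAction] | None = None,
                 supports: list[SupportDeclaration] | None = None,
                 **kwargs) -> np.ndarray:
    """Per-frame torque vector at one joint (convenience wrapper)."""
    loads = run_inverse_dynamics(model, series, actions, supports, **kwargs)
    return loads.torque[:, loads.joint_index(joint)]


def equilibrium_residual(model: HumanModel, series: CaptureSeries,
                         loads: JointLoadSeries,
                         actions: list[ExternalAction] | None = None,
                         gravity: float = G0) -> np.ndarray:
    """Whole-body net force per frame (kgf); ~0 when reactions balance."""
    fk = forward_kinematics(model, series)
    deriv = differentiate(series, fk)
    ef, _, _ = resolve_actions(series, fk, actions)
    masses = np.array([model.segment_mass(b) for b in BONE_ORDER])
    weight = np.zeros((series.n_frames, len(BONE_ORDER), 3))
    weight[:, :, 1] = -masses * gravity / G0
    inertial = -masses[None, :, None] * deriv.cg_acc / G0
    net = weight.sum(axis=1) + inertial.sum(axis=1) + ef.sum(axis=1)
    return net + loads.total_reaction()
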