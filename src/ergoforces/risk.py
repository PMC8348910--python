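"""Per-posture and per-minute musculoskeletal-disorder risk scoring.

Each captured frame of each joint receives five multiplicative factor
scores — posture angle (1–2), angular acceleration (1–1.5), internal force
(1–2), internal torque (1–2.5) and, at the wrists, grip quality (1–2).
Their product minus one is the ``FactorsPerPosture``; expressed against the
joint's achievable maximum it gives the ``RiskPerPosture`` percentage.  The
per-minute risk weights every posture by a repetitiveness factor, rescales
the cycle to one minute, normalises by the maximum factor a minute can
accumulate, and multiplies by the general (context) factors: recovery,
micro-pauses, duration and additional conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .anthropometry import PERCENTILES, SCORED_JOINTS, HumanModel
from .kinematics import CaptureSeries, differentiate, forward_kinematics
from .kinetics import (
    ExternalAction,
    JointLoadSeries,
    SupportDeclaration,
    resolve_actions,
    run_inverse_dynamics,
)

PREPARATION_COEF = {0: 0.9, 1: 1.0, 2: 1.1, 3: 1.2}

RISK_BANDS = (
    # (upper RiskPerMinute bound, upper level, valuation, interpretation, color)
    (10.0, 1.0, "No risk", "Acceptable", "#2e7d32"),
    (15.0, 2.0, "Low risk", "Acceptable", "#7cb342"),
    (25.0, 3.0, "Medium risk", "Acceptable", "#c0ca33"),
    (40.0, 4.0, "High risk", "Conditional", "#f9a825"),
    (70.0, 5.0, "Very high risk", "Unacceptable", "#e65100"),
    (math.inf, math.inf, "Severe risk", "Unacceptable", "#b71c1c"),
)


def _load_yaml(name: str, path=None) -> dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    text = resources.files("ergoforces.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def load_thresholds(path=None) -> "ThresholdTable":
    return ThresholdTable(_load_yaml("thresholds.yaml", path))


def load_angle_graphs(path=None) -> dict:
    return _load_yaml("angle_graphs.yaml", path)


def base_joint(joint: str) -> str:
    """Strip the side suffix: shoulder_r -> shoulder."""
    return joint[:-2] if joint.endswith(("_r", "_l")) else joint


class ThresholdTable:
    """Force/torque/acceleration thresholds, grip table and factor maxima."""

    def __init__(self, data: dict):
        self.force = data["force"]
        self.torque = data["torque"]
        self.angular = data["angular"]
        self.grip = {int(k): float(v) for k, v in data["grip"].items()}
        self.factor_maxima = data["factor_maxima"]
        for table in (self.force, self.torque):
            for joint, per_sex in table.items():
                for sex, row in per_sex.items():
                    if row["max"] <= row["min"]:
                        raise ValueError(f"{joint}/{sex}: max must exceed min")

    def max_factors_per_posture(self, joint: str) -> float:
        """Product of the factor maxima minus 1 (14 everywhere, 23 at wrists)."""
        m = self.factor_maxima[base_joint(joint)]
        # one-decimal ceilings: round away float fuzz (1.6*1.5*2*2.5*2 = 24)
        return round(m["angle"] * m["accel"] * m["force"] * m["torque"] * m["grip"], 9) - 1.0

    def stress_bounds(self, kind: str, joint: str, sex: str, height: float,
                      preparation: int = 1, percentile: str | None = None,
                      reference: dict | None = None) -> tuple[float, float]:
        """(min, max) force or torque bounds for a worker.

        Percentile columns are built from the P50 bounds and the P05/P95
        coefficients; for an arbitrary worker the bounds are interpolated on
        height between the three percentile statures.  The preparation level
        rescales the max only (0.9 / 1.0 / 1.1 / 1.2).
        """
        from .anthropometry import _REFERENCE
        reference = reference or _REFERENCE
        row = {"force": self.force, "torque": self.torque}[kind][base_joint(joint)][sex]
        cols = {
            "P05": (row["min"] * row["coef_p05"], row["max"] * row["coef_p05"]),
            "P50": (row["min"], row["max"]),
            "P95": (row["min"] * row["coef_p95"], row["max"] * row["coef_p95"]),
        }
        if percentile is not None:
            lo, hi = cols[percentile]
        else:
            anchors = reference["percentiles"][sex]
            hs = [anchors[p]["height"] for p in PERCENTILES]
            lo = float(np.interp(height, hs, [cols[p][0] for p in PERCENTILES]))
            hi = float(np.interp(height, hs, [cols[p][1] for p in PERCENTILES]))
        return lo, hi * PREPARATION_COEF[preparation]


@dataclass
class WorkstationContext:
    """Work-cycle context entered by the assessor."""

    frame_start: int | None = None
    frame_end: int | None = None        # inclusive
    cycle_time: float | None = None     # s; default: selected frame span
    nonrecovery_hours: int = 0
    micropauses_factor: float = 1.0
    repetitive_hours: float = 8.0
    additional_proportion: float = 0.0
    preparation: int = 1

    def __post_init__(self):
        if self.cycle_time is not None and self.cycle_time <= 0:
            raise ValueError("cycle_time must be > 0")
        if self.nonrecovery_hours < 0:
            raise ValueError("nonrecovery_hours must be >= 0")
        if not 0.7 <= self.micropauses_factor <= 1.0:
            raise ValueError("micropauses_factor must lie in [0.7, 1.0]")
        if not 0 < self.repetitive_hours <= 16:
            raise ValueError("repetitive_hours must lie in (0, 16]")
        if not 0 <= self.additional_proportion <= 1:
            raise ValueError("additional_proportion must lie in [0, 1]")


# ---------------------------------------------------------------------------
# factor scores

def _piecewise(x, breakpoints) -> np.ndarray:
    pts = np.asarray(breakpoints, dtype=float)
    return np.interp(x, pts[:, 0], pts[:, 1])


def angle_score(joint: str, rx, ry, rz, graphs: dict | None = None) -> np.ndarray:
    """Posture score in [1, joint ceiling] from the three joint rotations.

    Per-axis piecewise-linear curves, maximum over axes; the shoulder's
    two-input (antero-posterior x elevation) table is evaluated bilinearly.
    """
    graphs = graphs if graphs is not None else load_angle_graphs()
    key = base_joint(joint)
    if key not in graphs:
        raise KeyError(f"no angle graph configured for joint {joint!r}")
    spec = graphs[key]
    axes = {"Rx": np.asarray(rx, dtype=float), "Ry": np.asarray(ry, dtype=float),
            "Rz": np.asarray(rz, dtype=float)}
    scores = []
    for axis_name, bp in spec.items():
        if axis_name == "table2d":
            scores.append(_table2d_score(bp, axes))
        else:
            scores.append(_piecewise(axes[axis_name], bp))
    return np.maximum.reduce(scores)


def _table2d_score(spec: dict, axes: dict) -> np.ndarray:
    """Bilinear lookup on the grid generated from the two band curves."""
    xb = np.asarray(spec["x_bands"], dtype=float)
    yb = np.asarray(spec["y_bands"], dtype=float)
    grid = np.maximum(xb[:, 1][:, None], yb[:, 1][None, :])
    x = np.clip(axes[spec["x_axis"]], xb[0, 0], xb[-1, 0])
    y = np.clip(axes[spec["y_axis"]], yb[0, 0], yb[-1, 0])
    ix = np.clip(np.searchsorted(xb[:, 0], x) - 1, 0, len(xb) - 2)
    iy = np.clip(np.searchsorted(yb[:, 0], y) - 1, 0, len(yb) - 2)
    tx = (x - xb[ix, 0]) / (xb[ix + 1, 0] - xb[ix, 0])
    ty = (y - yb[iy, 0]) / (yb[iy + 1, 0] - yb[iy, 0])
    v00 = grid[ix, iy]
    v10 = grid[ix + 1, iy]
    v01 = grid[ix, iy + 1]
    v11 = grid[ix + 1, iy + 1]
    return (v00 * (1 - tx) * (1 - ty) + v10 * tx * (1 - ty)
            + v01 * (1 - tx) * ty + v11 * tx * ty)


def angular_acceleration_score(joint: str, accel_modulus,
                               thresholds: ThresholdTable) -> np.ndarray:
    """Score in [1, 1.5]: 1 below the slow threshold, 1.5 at/above the max."""
    row = thresholds.angular[base_joint(joint)]
    lo, hi = row["accel_slow"], row["accel_max"]
    x = np.asarray(accel_modulus, dtype=float)
    return 1.0 + 0.5 * np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def force_score(joint: str, force_modulus, thresholds: ThresholdTable,
                sex: str, height: float, preparation: int = 1,
                percentile: str | None = None) -> np.ndarray:
    """Score in [1, 2] from the internal force modulus (kgf)."""
    lo, hi = thresholds.stress_bounds("force", joint, sex, height, preparation, percentile)
    x = np.asarray(force_modulus, dtype=float)
    return 1.0 + np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def torque_score(joint: str, torque_modulus, thresholds: ThresholdTable,
                 sex: str, height: float, preparation: int = 1,
                 percentile: str | None = None) -> np.ndarray:
    """Score in [1, 2.5] from the internal torque modulus (kg·m)."""
    lo, hi = thresholds.stress_bounds("torque", joint, sex, height, preparation, percentile)
    x = np.asarray(torque_modulus, dtype=float)
    return 1.0 + 1.5 * np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def grip_score(grasp, thresholds: ThresholdTable | None = None) -> np.ndarray:
    """Grip-quality score (wrist joints only) from the grasp code 0–9."""
    thresholds = thresholds or load_thresholds()
    codes = np.atleast_1d(np.asarray(grasp, dtype=int))
    if np.any((codes < 0) | (codes > 9)):
        raise ValueError("grasp codes must be 0..9")
    table = np.array([thresholds.grip[c] for c in range(10)])
    out = table[codes]
    return out if np.ndim(grasp) else float(out[0])


def factors_per_posture(angle, accel, force, torque, grip=1.0) -> np.ndarray:
    """Product of the five factor scores minus one (>= 0)."""
    return (np.asarray(angle, dtype=float) * accel * force * torque * grip) - 1.0


def risk_per_posture(factors, joint: str, thresholds: ThresholdTable) -> np.ndarray:
    """Percentage of the joint's maximum achievable factor product."""
    return 100.0 * np.asarray(factors, dtype=float) / thresholds.max_factors_per_posture(joint)


# ---------------------------------------------------------------------------
# cycle aggregation

DEFAULT_REPETITIVENESS = ((0.0, 1.0), (100.0, 2.0))


def repetitiveness_factor(risk_pct, anchors=DEFAULT_REPETITIVENESS) -> np.ndarray:
    """Nondecreasing weight >= 1 penalising high-risk postures."""
    pts = np.asarray(anchors, dtype=float)
    return np.interp(np.asarray(risk_pct, dtype=float), pts[:, 0], pts[:, 1])


def recovery_factor(nonrecovery_hours: int, rate: float = 0.2,
                    ceiling: float = 2.6) -> float:
    """1 at no unrecovered hours, rising linearly and capped at 2.6."""
    return float(min(1.0 + rate * nonrecovery_hours, ceiling))


DEFAULT_DURATION_ANCHORS = ((0.0, 0.5), (8.0, 1.1), (16.0, 2.0))


def duration_factor(repetitive_hours: float,
                    anchors=DEFAULT_DURATION_ANCHORS) -> float:
    """Piecewise-linear in repetitive hours per workday; 8 h -> 1.1."""
    pts = np.asarray(anchors, dtype=float)
    return float(np.interp(repetitive_hours, pts[:, 0], pts[:, 1]))


def additional_factor(proportion: float) -> float:
    """1 + 0.18 x proportion of the cycle with additional risk conditions."""
    return 1.0 + 0.18 * proportion


def general_factors(ctx: WorkstationContext) -> float:
    """Product of recovery, micro-pauses, duration and additional factors."""
    return (recovery_factor(ctx.nonrecovery_hours)
            * ctx.micropauses_factor
            * duration_factor(ctx.repetitive_hours)
            * additional_factor(ctx.additional_proportion))


def risk_per_minute(factors, repetitiveness, ctx: WorkstationContext,
                    thresholds: ThresholdTable, joint: str,
                    frame_rate: float, cycle_time: float) -> float:
    """Aggregate per-frame factors into the joint's per-minute risk (%).

    Sum of (factors x repetitiveness weight) over the cycle, scaled to one
    minute (60 / cycle_time), normalised by the maximum factor product a
    minute of postures can reach, and multiplied by the general factors.
    """
    if cycle_time <= 0:
        raise ValueError("cycle_time must be > 0")
    factors = np.asarray(factors, dtype=float)
    weighted = float((factors * repetitiveness).sum()) * (60.0 / cycle_time)
    max_per_minute = thresholds.max_factors_per_posture(joint) * frame_rate * 60.0
    return 100.0 * weighted / max_per_minute * general_factors(ctx)


@dataclass(frozen=True)
class RiskLevel:
    level: float
    valuation: str
    interpretation: str
    color: str


def risk_level(risk_pct: float) -> RiskLevel:
    """Continuous 0–5+ level with its valuation band and colour."""
    r = float(risk_pct)
    lo_r, lo_l = 0.0, 0.0
    for hi_r, hi_l, valuation, interpretation, color in RISK_BANDS:
        if r <= hi_r:
            if math.isinf(hi_r):
                level = 5.0 + (r - 70.0) / 30.0
            else:
                level = lo_l + (r - lo_r) / (hi_r - lo_r) * (hi_l - lo_l)
            return RiskLevel(level, valuation, interpretation, color)
        lo_r, lo_l = hi_r, hi_l
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# end-to-end assessment

@dataclass
class RiskProfile:
    """Scored output of one capture: per-joint series and cycle totals."""

    joints: tuple
    frame_rate: float
    risk_per_posture: dict = field(repr=False)   # joint -> (n,) %
    factors: dict = field(repr=False)            # joint -> (n,)
    risk_per_minute: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        from .calibration import round_half_up
        rows = []
        for joint in self.joints:
            lvl = self.levels[joint]
            rows.append({
                "joint": joint,
                "risk_per_minute_pct": round_half_up(self.risk_per_minute[joint], 1),
                "risk_level": round_half_up(lvl.level, 2),
                "valuation": lvl.valuation,
                "interpretation": lvl.interpretation,
                "color": lvl.color,
            })
        return pd.DataFrame(rows)


def assess(model: HumanModel, series: CaptureSeries,
           actions: list[ExternalAction] | None = None,
           supports: list[SupportDeclaration] | None = None,
           ctx: WorkstationContext | None = None,
           thresholds: ThresholdTable | None = None,
           graphs: dict | None = None,
           loads: JointLoadSeries | None = None,
           repetitiveness_anchors=DEFAULT_REPETITIVENESS) -> RiskProfile:
    """Run the whole pipeline: kinetics, factor scores, risk aggregation."""
    ctx = ctx or WorkstationContext()
    thresholds = thresholds or load_thresholds()
    graphs = graphs if graphs is not None else load_angle_graphs()

    start = ctx.frame_start or 0
    end = ctx.frame_end if ctx.frame_end is not None else series.n_frames - 1
    window = series.select(start, end)
    cycle_time = ctx.cycle_time if ctx.cycle_time is not None else window.duration

    if loads is None:
        loads = run_inverse_dynamics(model, window, actions=_shift(actions, start),
                                     supports=_shift(supports, start))
    fk = forward_kinematics(model, window)
    deriv = differentiate(window, fk)
    _, _, grasp = resolve_actions(window, fk, _shift(actions, start))

    profile = RiskProfile(SCORED_JOINTS, window.frame_rate, {}, {})
    for joint in SCORED_JOINTS:
        ang = window.joint_angles(joint)
        s_angle = angle_score(joint, ang[:, 0], ang[:, 1], ang[:, 2], graphs)
        j = window.joint_index(joint)
        acc_mod = np.linalg.norm(deriv.ang_acc[:, j], axis=1)
        s_accel = angular_acceleration_score(joint, acc_mod, thresholds)
        s_force = force_score(joint, loads.force_modulus(joint), thresholds,
                              model.sex, model.height, ctx.preparation)
        s_torque = torque_score(joint, loads.torque_modulus(joint), thresholds,
                                model.sex, model.height, ctx.preparation)
        if base_joint(joint) == "wrist":
            side = 0 if joint.endswith("_r") else 1
            s_grip = grip_score(grasp[:, side], thresholds)
        else:
            s_grip = 1.0
        fac = factors_per_posture(s_angle, s_accel, s_force, s_torque, s_grip)
        rpp = risk_per_posture(fac, joint, thresholds)
        rep = repetitiveness_factor(rpp, repetitiveness_anchors)
        rpm = risk_per_minute(fac, rep, ctx, thresholds, joint,
                              window.frame_rate, cycle_time)
        profile.factors[joint] = fac
        profile.risk_per_posture[joint] = rpp
        profile.risk_per_minute[joint] = rpm
        profile.levels[joint] = risk_level(rpm)
    return profile


def _shift(items, start: int):
    """Re-base action/support frame ranges onto the selected window."""
    if not items or start == 0:
        return items
    out = []
    for it in items:
        s = max(it.frame_start - start, 0)
        e = it.frame_end - start
        if e < 0:
            continue
        out.append(type(it)(**{**it.__dict__, "frame_start": s, "frame_end": e}))
    return out


def plot_risk_per_posture(profile: RiskProfile, ax=None):
    """Per-frame risk traces for every scored joint (matplotlib)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    t = None
    for joint in profile.joints:
        rpp = profile.risk_per_posture[joint]
        if t is None:
            t = np.arange(len(rpp))
        ax.plot(t, rpp, label=joint, lw=1)
    ax.set_xlabel("frame")
    ax.set_ylabel("risk per posture (%)")
    ax.set_ylim(bottom=0)
    ax.legend(fontsize=7, ncol=2)
    return ax
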