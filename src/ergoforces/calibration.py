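"""Derivation of the scoring threshold tables from capture sets.

The maximum force/torque thresholds are the 99th percentile of the pooled
per-frame moduli recorded while subjects sweep every joint through wide
arcs carrying a declared 8 kgf load in each hand; the minima are the loads
of a static standing capture with empty hands.  Bilateral joints are
averaged left/right, percentile columns are reduced to P05/P95-over-P50
coefficients (2 decimals, half-up), and the static minima measured on the
P50 model are transported to the other percentiles with those same
coefficients.  Angular-acceleration thresholds come from the speed
thresholds through the 0.2-s stop rule.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .anthropometry import PERCENTILES, neutral_model
from .kinematics import differentiate
from .kinetics import ExternalAction, run_inverse_dynamics

STOP_TIME = 0.2  # s: assumed deceleration time from a peak angular speed

BILATERAL = ("shoulder", "elbow", "wrist", "knee")
CALIBRATION_JOINTS = ("lumbar", "cervical") + tuple(
    f"{b}_{s}" for b in BILATERAL for s in ("r", "l"))


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def max_stress(values) -> float:
    """99th percentile (linear interpolation) of pooled per-frame moduli."""
    return float(np.percentile(np.asarray(values, dtype=float), 99))


def speed_to_acceleration(speed: float, stop_time: float = STOP_TIME) -> float:
    """Angular-speed threshold (deg/s) -> acceleration threshold (deg/s^2)."""
    return speed / stop_time


def derive_threshold_table(maxima: dict, minima: dict,
                           decimals: int = 2) -> dict:
    """Reduce per-percentile maxima and P50 static minima to threshold rows.

    ``maxima``: {joint_or_side: {percentile: value}} per-capture 99th
    percentiles; ``minima``: {joint_or_side: value} static P50 loads.
    Returns {joint: {"min", "max", "coef_p05", "coef_p95"}} with bilateral
    sides averaged and coefficients rounded half-up.  Minima for other
    percentiles follow from min x coef.
    """
    table = {}
    for joint in ("lumbar", "cervical") + BILATERAL:
        if joint in BILATERAL:
            sides = (f"{joint}_r", f"{joint}_l")
        else:
            sides = (joint,)
        per_pct = {}
        for pct in PERCENTILES:
            vals = []
            for s in sides:
                if s not in maxima or pct not in maxima[s]:
                    raise ValueError(f"missing {pct} maxima for {s}")
                vals.append(maxima[s][pct])
            per_pct[pct] = float(np.mean(vals))
        vmin = float(np.mean([minima[s] for s in sides]))
        table[joint] = {
            "min": round_half_up(vmin, decimals),
            "max": round_half_up(per_pct["P50"], decimals),
            "coef_p05": round_half_up(per_pct["P05"] / per_pct["P50"], 2),
            "coef_p95": round_half_up(per_pct["P95"] / per_pct["P50"], 2),
        }
    return table


def simulate_calibration_protocol(sex: str = "male", seed: int = 0,
                                  duration: float = 6.0,
                                  frame_rate: float = 60.0) -> dict:
    """Exercise the calibration arithmetic end-to-end on synthetic captures.

    Generates a wide-arc sweep per model percentile with the declared
    (0, −8, 0) kgf load in each hand, plus a static standing capture, runs
    the kinetics pipeline, and reduces the results with
    :func:`derive_threshold_table`.  Returns ``{"force": ..., "torque": ...,
    "angular": ...}`` in the same shape as the packaged thresholds file.
    """
    from .synthetic import generate_synthetic_capture

    force_max: dict = {j: {} for j in CALIBRATION_JOINTS}
    torque_max: dict = {j: {} for j in CALIBRATION_JOINTS}
    speed_max: dict = {}
    series, _ = generate_synthetic_capture("wide_arcs", duration=duration,
                                           frame_rate=frame_rate, seed=seed)
    load = [ExternalAction(0, series.n_frames - 1, "both", force=(0.0, -16.0, 0.0))]

    for pct in PERCENTILES:
        model = neutral_model(sex, pct)
        loads = run_inverse_dynamics(model, series, actions=load)
        for joint in CALIBRATION_JOINTS:
            force_max[joint][pct] = max_stress(loads.force_modulus(joint))
            torque_max[joint][pct] = max_stress(loads.torque_modulus(joint))

    deriv = differentiate(series)
    for joint in CALIBRATION_JOINTS:
        j = series.joint_index(joint)
        speed_max[joint] = max_stress(np.linalg.norm(deriv.ang_vel[:, j], axis=1))

    static, _ = generate_synthetic_capture("static_stand", duration=2.0,
                                           frame_rate=frame_rate, seed=seed)
    model50 = neutral_model(sex, "P50")
    static_loads = run_inverse_dynamics(model50, static)
    force_min = {j: float(np.mean(static_loads.force_modulus(j)))
                 for j in CALIBRATION_JOINTS}
    torque_min = {j: float(np.mean(static_loads.torque_modulus(j)))
                  for j in CALIBRATION_JOINTS}

    angular = {}
    for joint in ("lumbar", "cervical") + BILATERAL:
        sides = (f"{joint}_r", f"{joint}_l") if joint in BILATERAL else (joint,)
        vmax = float(np.mean([speed_max[s] for s in sides]))
        angular[joint] = {
            "speed_max": round_half_up(vmax, 0),
            "accel_max": round_half_up(speed_to_acceleration(vmax), 0),
        }

    return {
        "force": derive_threshold_table(force_max, force_min),
        "torque": derive_threshold_table(torque_max, torque_min),
        "angular": angular,
    }
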