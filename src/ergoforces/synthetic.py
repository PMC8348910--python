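"""Synthetic capture generation: smooth repetitive work-cycle trajectories.

The generator emulates a short manufacturing cycle recorded at a fixed
frame rate, producing C2-continuous joint-angle trajectories (quintic
smoothstep transitions, sinusoidal oscillation) so the double numerical
differentiation downstream stays well behaved.  Scenarios:

``static_stand``
    neutral standing posture, no motion, no actions.
``wide_arcs``
    every scored joint sweeps wide arcs in all rotation axes — the motion
    pattern used to calibrate the maximum-stress thresholds.
``lift_place``
    trunk flexion + bilateral reach lifting a 3.5-kgf part (both hands,
    hook grasp) and placing it at working height.
``screw_task``
    arms held forward while the wrist oscillates driving a suspended
    screwdriver; a 0.2 kg·m reaction torque acts on the hand.

Amplitudes receive a small seeded jitter so repeated cycles differ the way
human repetitions do; the same seed always reproduces the same capture.
"""

from __future__ import annotations

import numpy as np

from .anthropometry import JOINTS
from .kinematics import CaptureSeries
from .kinetics import ExternalAction

SCENARIOS = ("static_stand", "wide_arcs", "lift_place", "screw_task")

_DEFAULT_DURATION = {
    "static_stand": 2.0,
    "wide_arcs": 8.0,
    "lift_place": 6.0,
    "screw_task": 6.0,
}

#: wide-arc sweep amplitudes (deg) per joint and axis, within working ROM
_ARC_AMPLITUDE = {
    "lumbar": (40.0, 25.0, 20.0),
    "cervical": (35.0, 35.0, 25.0),
    "shoulder_r": (110.0, 40.0, 80.0),
    "shoulder_l": (110.0, 40.0, 80.0),
    "elbow_r": (110.0, 60.0, 0.0),
    "elbow_l": (110.0, 60.0, 0.0),
    "wrist_r": (45.0, 60.0, 25.0),
    "wrist_l": (45.0, 60.0, 25.0),
    "knee_r": (80.0, 0.0, 0.0),
    "knee_l": (80.0, 0.0, 0.0),
    "hip_r": (60.0, 15.0, 20.0),
    "hip_l": (60.0, 15.0, 20.0),
}


def smoothstep(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: C2 ramp from 0 to 1 on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u ** 2)


def _pulse(t: np.ndarray, start: float, rise: float, hold: float,
           fall: float | None = None) -> np.ndarray:
    """C2 bump: ramp up over ``rise`` s, hold, ramp back down."""
    fall = rise if fall is None else fall
    up = smoothstep((t - start) / rise)
    down = smoothstep((t - start - rise - hold) / fall)
    return up - down


def generate_synthetic_capture(scenario: str, duration: float | None = None,
                               frame_rate: float = 60.0, seed: int = 0,
                               ) -> tuple[CaptureSeries, list[ExternalAction]]:
    """Deterministic scenario capture plus its external-action table."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    duration = duration if duration is not None else _DEFAULT_DURATION[scenario]
    n = max(int(round(duration * frame_rate)), 3)
    t = np.arange(n) / frame_rate
    rng = np.random.default_rng(seed)
    angles = np.zeros((n, len(JOINTS), 3))
    actions: list[ExternalAction] = []
    jidx = {j: i for i, j in enumerate(JOINTS)}

    if scenario == "static_stand":
        pass

    elif scenario == "wide_arcs":
        # each joint oscillates with its own phase; envelope ramps C2 at both ends
        envelope = smoothstep(t / 0.8) * (1.0 - smoothstep((t - (duration - 0.8)) / 0.8))
        for joint, amps in _ARC_AMPLITUDE.items():
            f = 0.5 + 0.25 * rng.random()          # Hz, work-paced sweeps
            phase = 2 * np.pi * rng.random()
            jitter = 1.0 + 0.05 * rng.standard_normal(3)
            for ax in range(3):
                amp = amps[ax] * jitter[ax]
                angles[:, jidx[joint], ax] = (
                    amp * envelope * np.sin(2 * np.pi * f * t + phase + ax * np.pi / 3))

    elif scenario == "lift_place":
        # reach down (trunk + knees), lift over [0.25, 0.65] of the cycle, place
        bend = _pulse(t, 0.3, 1.0, 1.0)
        carry = _pulse(t, 0.25 * duration, 0.8, 0.45 * duration - 0.8)
        jit = 1.0 + 0.04 * rng.standard_normal(4)
        angles[:, jidx["lumbar"], 0] = 45.0 * jit[0] * bend
        angles[:, jidx["knee_r"], 0] = 25.0 * jit[1] * bend
        angles[:, jidx["knee_l"], 0] = 25.0 * jit[1] * bend
        for side in ("r", "l"):
            angles[:, jidx[f"shoulder_{side}"], 0] = 55.0 * jit[2] * carry
            angles[:, jidx[f"elbow_{side}"], 0] = 40.0 * jit[3] * carry
        lift_start = int(0.25 * duration * frame_rate)
        lift_end = min(int(0.70 * duration * frame_rate), n - 1)
        actions.append(ExternalAction(lift_start, lift_end, "both",
                                      force=(0.0, -3.5, 0.0), grasp=4))

    elif scenario == "screw_task":
        hold = _pulse(t, 0.3, 0.8, duration - 2.2)
        jit = 1.0 + 0.04 * rng.standard_normal(2)
        for side in ("r", "l"):
            angles[:, jidx[f"shoulder_{side}"], 0] = 60.0 * jit[0] * hold
            angles[:, jidx[f"elbow_{side}"], 0] = 30.0 * jit[1] * hold
        # driving hand oscillates about the forearm axis
        spin = hold * 25.0 * np.sin(2 * np.pi * 2.0 * t)
        angles[:, jidx["wrist_r"], 1] = spin
        s0, s1 = int(0.2 * n), int(0.8 * n)
        actions.append(ExternalAction(s0, s1, "right",
                                      torque=(0.0, 0.0, -0.2), grasp=1))

    series = CaptureSeries(frame_rate, JOINTS, angles)
    return series, actions
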