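"""File formats: capture CSV, BVH subset, action/support tables, config.

The canonical capture format is a plain CSV with one row per frame and
columns ``<joint>_Rx, <joint>_Ry, <joint>_Rz`` in degrees; the first line
is a ``#meta frame_rate=<Hz>`` comment.  A read-only subset of BVH is also
supported for data coming from other capture pipelines: the hierarchy is
parsed for joint names and rotation channels, joints are renamed through a
mapping table, and unmapped joints are ignored with a warning.
"""

from __future__ import annotations

import logging
import re
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anthropometry import JOINTS
from .kinematics import CaptureSeries
from .kinetics import ExternalAction, SupportDeclaration

logger = logging.getLogger(__name__)

_AXES = ("Rx", "Ry", "Rz")


# ---------------------------------------------------------------------------
# capture CSV

def write_capture(series: CaptureSeries, path) -> None:
    cols = {}
    for j, joint in enumerate(series.joints):
        for a, axis in enumerate(_AXES):
            cols[f"{joint}_{axis}"] = series.angles[:, j, a]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"#meta frame_rate={series.frame_rate:g}\n")
        df.to_csv(fh, index=False)


def read_capture(path, dialect: str = "csv", frame_rate: float | None = None,
                 joint_map: dict | None = None,
                 axis_map: tuple = ("Rx", "Ry", "Rz"),
                 require: tuple = JOINTS) -> CaptureSeries:
    """Load a capture series; ``dialect`` is ``csv`` or ``bvh``.

    ``axis_map`` remaps foreign axis conventions (a permutation of
    Rx/Ry/Rz, optionally sign-prefixed like ``-Rz``).  Missing required
    joints raise a ``ValueError`` naming the joint.
    """
    if dialect == "csv":
        series = _read_capture_csv(path, frame_rate)
    elif dialect == "bvh":
        series = _read_bvh(path, joint_map or {})
    else:
        raise ValueError(f"unknown capture dialect {dialect!r}")
    series = _remap_axes(series, axis_map)
    missing = [j for j in require if j not in series.joints]
    if dialect == "csv" and missing:
        raise ValueError(f"capture misses joint column(s): {', '.join(missing)}")
    if missing:  # BVH: fill unmapped joints with the neutral rotation
        logger.warning("joints %s absent from BVH; assuming neutral", missing)
        n = series.n_frames
        angles = np.zeros((n, len(require), 3))
        for j, joint in enumerate(require):
            if joint in series.joints:
                angles[:, j] = series.joint_angles(joint)
        series = CaptureSeries(series.frame_rate, require, angles)
    return series


def _read_capture_csv(path, frame_rate) -> CaptureSeries:
    meta_rate = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#meta"):
            m = re.search(r"frame_rate=([0-9.]+)", first)
            if m:
                meta_rate = float(m.group(1))
            body = fh.read()
        else:
            body = first + fh.read()
    rate = frame_rate or meta_rate
    if rate is None:
        raise ValueError(f"{path}: no frame rate in #meta line and none supplied")
    try:
        df = pd.read_csv(StringIO(body))
    except Exception as exc:
        raise ValueError(f"{path}: malformed capture CSV ({exc})") from exc

    joints = []
    for col in df.columns:
        if col.endswith("_Rx"):
            joints.append(col[:-3])
    for joint in joints:
        for axis in _AXES:
            if f"{joint}_{axis}" not in df.columns:
                raise ValueError(f"{path}: joint {joint!r} misses column {joint}_{axis}")
    n = len(df)
    angles = np.zeros((n, len(joints), 3))
    for j, joint in enumerate(joints):
        for a, axis in enumerate(_AXES):
            vals = pd.to_numeric(df[f"{joint}_{axis}"], errors="coerce")
            if vals.isna().any():
                line = int(vals.index[vals.isna()][0]) + 3  # +header +meta, 1-based
                raise ValueError(f"{path}: non-numeric value in {joint}_{axis} near line {line}")
            angles[:, j, a] = vals.to_numpy()
    return CaptureSeries(rate, tuple(joints), angles)


def _remap_axes(series: CaptureSeries, axis_map) -> CaptureSeries:
    if tuple(axis_map) == _AXES:
        return series
    angles = np.zeros_like(series.angles)
    for a, spec in enumerate(axis_map):
        sign = -1.0 if spec.startswith("-") else 1.0
        src = _AXES.index(spec.lstrip("+-"))
        angles[:, :, a] = sign * series.angles[:, :, src]
    return CaptureSeries(series.frame_rate, series.joints, angles)


# ---------------------------------------------------------------------------
# BVH subset (read-only)

def _read_bvh(path, joint_map: dict) -> CaptureSeries:
    text = Path(path).read_text()
    if "HIERARCHY" not in text or "MOTION" not in text:
        raise ValueError(f"{path}: not a BVH file")
    hierarchy, motion = text.split("MOTION", 1)

    channels = []  # (joint_name, channel_name) in file order
    current = None
    for line in hierarchy.splitlines():
        line = line.strip()
        if line.startswith(("ROOT", "JOINT")):
            current = line.split(None, 1)[1].strip()
        elif line.startswith("End"):
            current = None
        elif line.startswith("CHANNELS") and current is not None:
            parts = line.split()
            for ch in parts[2:]:
                channels.append((current, ch))

    frame_time = 1.0 / 60.0
    rows = []
    for line in motion.splitlines():
        line = line.strip()
        if not line or line.startswith("Frames:"):
            continue
        if line.startswith("Frame Time:"):
            frame_time = float(line.split(":")[1])
            continue
        rows.append([float(v) for v in line.split()])
    data = np.asarray(rows, dtype=float)
    if data.shape[0] and data.shape[1] != len(channels):
        raise ValueError(f"{path}: motion rows have {data.shape[1]} values, "
                         f"hierarchy declares {len(channels)} channels")

    known = set(JOINTS)
    mapped: dict[str, np.ndarray] = {}
    ignored = set()
    axis_of = {"Xrotation": 0, "Yrotation": 1, "Zrotation": 2}
    for k, (bvh_joint, ch) in enumerate(channels):
        if ch not in axis_of:
            continue
        joint = joint_map.get(bvh_joint, bvh_joint if bvh_joint in known else None)
        if joint is None:
            ignored.add(bvh_joint)
            continue
        mapped.setdefault(joint, np.zeros((data.shape[0], 3)))
        mapped[joint][:, axis_of[ch]] = data[:, k]
    if ignored:
        logger.warning("ignoring unmapped BVH joints: %s", sorted(ignored))
    if not mapped:
        raise ValueError(f"{path}: no BVH joint could be mapped onto the model")

    joints = tuple(mapped)
    angles = np.stack([mapped[j] for j in joints], axis=1)
    return CaptureSeries(1.0 / frame_time, joints, angles)


# ---------------------------------------------------------------------------
# action / support tables

_ACTION_COLS = ["frame_start", "frame_end", "hand",
                "Fx", "Fy", "Fz", "Tx", "Ty", "Tz", "grasp"]


def write_actions(actions: list[ExternalAction], path) -> None:
    rows = [{
        "frame_start": a.frame_start, "frame_end": a.frame_end, "hand": a.hand,
        "Fx": a.force[0], "Fy": a.force[1], "Fz": a.force[2],
        "Tx": a.torque[0], "Ty": a.torque[1], "Tz": a.torque[2],
        "grasp": a.grasp,
    } for a in actions]
    pd.DataFrame(rows, columns=_ACTION_COLS).to_csv(path, index=False)


def read_actions(path) -> list[ExternalAction]:
    df = pd.read_csv(path)
    missing = [c for c in _ACTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: action table misses column(s) {missing}")
    return [
        ExternalAction(
            int(r.frame_start), int(r.frame_end), str(r.hand),
            (float(r.Fx), float(r.Fy), float(r.Fz)),
            (float(r.Tx), float(r.Ty), float(r.Tz)),
            int(r.grasp))
        for r in df.itertuples()
    ]


def write_supports(declarations: list[SupportDeclaration], path) -> None:
    pd.DataFrame(
        [{"frame_start": d.frame_start, "frame_end": d.frame_end, "kind": d.kind}
         for d in declarations],
        columns=["frame_start", "frame_end", "kind"]).to_csv(path, index=False)


def read_supports(path) -> list[SupportDeclaration]:
    df = pd.read_csv(path)
    return [SupportDeclaration(int(r.frame_start), int(r.frame_end), str(r.kind))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# configuration

def load_config(path) -> dict:
    """YAML/JSON config: anthropometry, context, threshold/graph overrides."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
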