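"""Risk maps and time-weighted combination of workstation risks.

A risk map is a table with one row per workstation (or captured variant of
one workstation) holding the per-joint RiskPerMinute percentages.  Several
captured variants combine into one workstation row — and several
workstations into a job-rotation row — by the same weighted arithmetic
mean, with weights given by the share of time (or of occurrences) each
situation represents.  The order of tasks is deliberately ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import round_half_up
from .risk import RiskProfile, risk_level

#: canonical column order of a risk map
JOINT_ORDER = (
    "lumbar", "cervical",
    "shoulder_r", "elbow_r", "wrist_r", "knee_r",
    "shoulder_l", "elbow_l", "wrist_l", "knee_l",
)


@dataclass
class RiskMapRow:
    """One labelled row of per-joint RiskPerMinute values (%)."""

    label: str
    values: dict = field(repr=False)   # joint -> %
    weight: float = 1.0

    def __post_init__(self):
        if not 0 <= self.weight <= 1:
            raise ValueError("weight must lie in [0, 1]")
        bad = [j for j, v in self.values.items() if v < 0]
        if bad:
            raise ValueError(f"negative risk values for {bad}")

    @classmethod
    def from_profile(cls, profile: RiskProfile, label: str,
                     weight: float = 1.0) -> "RiskMapRow":
        return cls(label, dict(profile.risk_per_minute), weight)


def combine_rows(rows: list[RiskMapRow], weights=None,
                 label: str = "combined") -> RiskMapRow:
    """Weighted per-joint mean of several rows.

    Weights default to each row's own ``weight``; they are renormalised
    (with a warning) when they do not sum to 1 within 1e-6.  All rows must
    cover the same joint set.
    """
    if not rows:
        raise ValueError("need at least one row")
    joints = set(rows[0].values)
    for row in rows[1:]:
        if set(row.values) != joints:
            raise ValueError(
                f"row {row.label!r} covers joints {sorted(row.values)}, "
                f"expected {sorted(joints)}")
    w = np.asarray([r.weight for r in rows] if weights is None else weights, dtype=float)
    if len(w) != len(rows):
        raise ValueError("one weight per row required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if abs(total - 1.0) > 1e-6:
        warnings.warn(f"weights sum to {total:.4f}; renormalising", stacklevel=2)
    w = w / total
    combined = {
        j: float(sum(wk * r.values[j] for wk, r in zip(w, rows)))
        for j in rows[0].values
    }
    return RiskMapRow(label, combined, 1.0)


def build_risk_map(rows: list[RiskMapRow], decimals: int = 1) -> pd.DataFrame:
    """Risk-map table: one row per workstation with banded levels.

    Values are reported half-up to ``decimals``; each joint cell carries a
    companion ``<joint>_band`` column with the valuation of its risk band.
    """
    records = []
    for row in rows:
        joints = [j for j in JOINT_ORDER if j in row.values]
        joints += [j for j in row.values if j not in JOINT_ORDER]
        rec: dict = {"label": row.label, "weight": row.weight}
        for j in joints:
            rec[j] = round_half_up(row.values[j], decimals)
            rec[f"{j}_band"] = risk_level(row.values[j]).valuation
        records.append(rec)
    return pd.DataFrame(records)


def read_risk_map(path) -> list[RiskMapRow]:
    """Load rows from CSV with columns label, weight, then one per joint."""
    df = pd.read_csv(path)
    rows = []
    for _, rec in df.iterrows():
        values = {c: float(rec[c]) for c in df.columns
                  if c not in ("label", "weight") and not c.endswith("_band")}
        weight = float(rec.get("weight", 1.0))
        if weight > 1.0:  # percentage notation
            weight /= 100.0
        rows.append(RiskMapRow(str(rec["label"]), values, weight))
    return rows
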