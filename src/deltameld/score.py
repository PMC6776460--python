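"""Composite MELD + ΔMELD₃₀ prioritization scores by linear-predictor equating.

Given a MELD-only dropout model with coefficient ``b_M`` and a joint model
with MELD coefficient ``b'_M`` and jump coefficient ``b_J`` (optionally a
MELD × jump interaction ``b_I``), setting the two linear predictors equal,

    b_M · MELD_new  =  b'_M · MELD + (b_J + b_I · MELD) · I(ΔMELD₃₀ ≥ 10),

yields the equivalent score ``MELD_new = (b'_M/b_M) · MELD +
(b_J + b_I·MELD)/b_M · I(jump)``.  Without an interaction this is a flat
bonus — the "+2 points" rule; with a negative interaction the bonus shrinks
as MELD rises, giving a per-MELD points table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MELD_CAP

__all__ = ["EquatingInput", "PointsTable", "equate_flat",
           "equate_interaction", "apply_score"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class EquatingInput:
    """Log-hazard-ratio inputs to the equating step."""

    beta_meld_only: float
    beta_meld_joint: float
    beta_jump: float
    beta_interaction: float | None = None

    def __post_init__(self):
        if self.beta_meld_only <= 0:
            raise ValueError("beta_meld_only must be positive")


@dataclass(frozen=True)
class PointsTable:
    """MELD-dependent bonus points for a jump, as disjoint integer ranges."""

    rows: tuple  # ((meld_lo, meld_hi, added_points), ...)

    def __post_init__(self):
        covered = []
        for lo, hi, pts in self.rows:
            if pts < 0 or pts != int(pts):
                raise ValueError("added points must be non-negative integers")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != covered or len(set(covered)) != len(covered):
            raise ValueError("ranges must be disjoint and ascending")

    def points(self, meld: int) -> int:
        for lo, hi, pts in self.rows:
            if lo <= meld <= hi:
                return pts
        return 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f"{lo}" if lo == hi else f"{lo}-{hi}", pts)
             for lo, hi, pts in self.rows],
            columns=["meld_range", "added_points"])


def equate_flat(inp: EquatingInput):
    """Flat equating: returns ``(slope, add_points_real, add_points_int)``.

    Slope and real-valued bonus are reported to two decimals; the integer
    bonus uses round-half-up.
    """
    if inp.beta_interaction is not None:
        raise ValueError("flat equating requires no interaction term; "
                         "use equate_interaction")
    slope = round(inp.beta_meld_joint / inp.beta_meld_only, 2)
    add_real = round(inp.beta_jump / inp.beta_meld_only, 2)
    return slope, add_real, _round_half_up(add_real)


def equate_interaction(inp: EquatingInput, meld_range=range(16, 41)) -> PointsTable:
    """MELD-dependent equating: bonus points per MELD level, merged to ranges.

    Restricted to MELD ≥ 16 by default, since a 10-point rise cannot land
    below 16.  Negative computed bonuses are clamped to zero — deterioration
    never lowers priority.
    """
    if inp.beta_interaction is None:
        raise ValueError("equate_interaction requires beta_interaction; "
                         "use equate_flat")
    melds = sorted(int(m) for m in meld_range)
    if not melds or melds[0] < 16 or melds[-1] > MELD_CAP:
        raise ValueError("meld_range must be a subset of [16, 40]")
    pts = []
    for m in melds:
        raw = (inp.beta_jump + inp.beta_interaction * m) / inp.beta_meld_only
        pts.append(max(0, _round_half_up(max(0.0, raw))))
    rows = []
    lo = melds[0]
    for i in range(1, len(melds) + 1):
        if i == len(melds) or pts[i] != pts[i - 1] or melds[i] != melds[i - 1] + 1:
            rows.append((lo, melds[i - 1], pts[i - 1]))
            if i < len(melds):
                lo = melds[i]
    return PointsTable(tuple(rows))


def apply_score(feature_rows: pd.DataFrame, points) -> pd.DataFrame:
    """Attach the composite score ``meld_new`` to feature rows.

    ``points`` is a flat integer bonus or a :class:`PointsTable`.  The bonus
    applies only to rows with an active ΔMELD₃₀ ≥ 10 jump; the result is
    capped at 40 and never falls below the current capped MELD.
    """
    meld = feature_rows["meld_capped"].to_numpy(int)
    if meld.min() < 6 or meld.max() > MELD_CAP:
        raise ValueError("capped MELD outside [6, 40]")
    jump = feature_rows["ind_ge10"].to_numpy(int)
    if isinstance(points, PointsTable):
        bonus = np.array([points.points(m) for m in meld])
    else:
        bonus = np.full(len(meld), int(points))
    if (bonus < 0).any():
        raise ValueError("bonus points must be non-negative")
    out = feature_rows.copy()
    out["meld_new"] = np.minimum(meld + bonus * jump, MELD_CAP)
    return out
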