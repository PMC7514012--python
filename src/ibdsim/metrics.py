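"""Evaluation statistics: healthy-interval occupancy, pro-/anti-inflammatory
cytokine ratios, and steady-state fold changes.

The *healthy interval* of a compartment is the band centred on the
healthy steady-state level whose half-width is half the patient–healthy
gap:

    lower = healthy − |patient − healthy| / 2
    upper = healthy + |patient − healthy| / 2

Time-in-band over the analysis window (default weeks 14–50, excluding
the initial-condition transient) is the treatment-quality statistic: a
trajectory that stays inside the band the whole window scores 100%.

Ratios of pro- to anti-inflammatory factors (e.g. TNF-α/IL-10, Th1/Th2)
are reported as minima and maxima over the window and as percent change
relative to the healthy steady-state ratio, because the immune system
oscillates naturally under cyclic dosing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ImmuneState
from .simulate import Trajectory

__all__ = [
    "HealthyInterval",
    "OccupancyReport",
    "RatioReport",
    "healthy_interval",
    "intervals_from_states",
    "occupancy",
    "ratio_report",
    "fold_change",
    "DEFAULT_WINDOW",
    "DEFAULT_RATIO_PAIRS",
    "PRO_INFLAMMATORY",
    "ANTI_INFLAMMATORY",
    "IMMUNE_CELLS",
]

#: analysis window (weeks); the first 13 weeks carry the initial transient
DEFAULT_WINDOW = (14.0, 50.0)

#: group membership is configuration; the defaults cover the factors the
#: four-case analysis discusses
PRO_INFLAMMATORY = ("I_alpha", "I_12", "I_gamma", "I_2")
ANTI_INFLAMMATORY = ("I_10", "I_4")
IMMUNE_CELLS = ("M1", "M2", "Th1", "Th2", "Th17", "Treg")

#: default (pro, anti) ratio pairs: each blocked/administered cytokine against
#: each anti-inflammatory factor, plus the helper/regulatory cell balances
DEFAULT_RATIO_PAIRS = (
    ("I_alpha", "I_10"),
    ("I_alpha", "I_4"),
    ("I_12", "I_10"),
    ("I_12", "I_4"),
    ("Th1", "Th2"),
    ("Th1", "Treg"),
)

#: relative tolerance of closed-interval membership; makes the zero-width
#: interval (patient already at the healthy level) score 100%, not 0%
MEMBERSHIP_RTOL = 1e-9


@dataclass(frozen=True)
class HealthyInterval:
    """Healthy band of one compartment (Eq. above)."""

    compartment: str
    healthy_level: float
    patient_level: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("interval bounds inverted")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Closed-interval membership with a tiny absolute tolerance scaled
        by the healthy level (handles the zero-width degenerate case)."""
        tol = MEMBERSHIP_RTOL * abs(self.healthy_level)
        v = np.asarray(values, dtype=float)
        return (v >= self.lower - tol) & (v <= self.upper + tol)


def healthy_interval(patient_level: float, healthy_level: float,
                     compartment: str = "") -> HealthyInterval:
    """Band centred on the healthy level, half-width |patient − healthy|/2."""
    if patient_level < 0.0 or healthy_level < 0.0:
        raise ValueError("levels must be >= 0")
    half = abs(patient_level - healthy_level) / 2.0
    return HealthyInterval(
        compartment=compartment,
        healthy_level=float(healthy_level),
        patient_level=float(patient_level),
        lower=float(healthy_level - half),
        upper=float(healthy_level + half),
    )


def intervals_from_states(patient_ss: ImmuneState, healthy_ss: ImmuneState,
                          compartments: Optional[Iterable[str]] = None,
                          ) -> dict[str, HealthyInterval]:
    """Per-compartment healthy intervals from two steady states.

    Drug compartments (zero in both references) are skipped by default.
    """
    if compartments is None:
        compartments = [n for n in healthy_ss.names
                        if not n.startswith("D_") and n in patient_ss]
    return {
        n: healthy_interval(patient_ss[n], healthy_ss[n], n) for n in compartments
    }


@dataclass(frozen=True)
class OccupancyReport:
    """Percent of analysis-window time spent inside the healthy interval."""

    occupancy: Mapping[str, float]     # compartment -> percent in [0, 100]
    window: tuple[float, float]
    mode: str = ""
    case: str = ""

    def __post_init__(self):
        for name, pct in self.occupancy.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"occupancy of {name!r} outside [0, 100]: {pct}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compartment": list(self.occupancy),
                "occupancy_pct": list(self.occupancy.values()),
                "window_start": self.window[0],
                "window_end": self.window[1],
                "therapy": self.mode,
                "case": self.case,
            }
        )


def occupancy(traj: Trajectory,
              intervals: Mapping[str, HealthyInterval],
              window: tuple[float, float] = DEFAULT_WINDOW,
              *,
              mode: str = "",
              case: str = "") -> OccupancyReport:
    """Interval occupancy by uniform-grid counting on the trajectory grid.

    occupancy = 100 x (grid points inside the closed band) / (points in
    window).  The window must lie within the trajectory span.
    """
    t0, t1 = float(window[0]), float(window[1])
    lo, hi = traj.span
    if not (t0 < t1):
        raise ValueError("window must satisfy t0 < t1")
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise ValueError(f"window [{t0}, {t1}] outside trajectory span [{lo}, {hi}]")
    mask = traj.window_mask(t0, t1)
    out = {}
    for name, iv in intervals.items():
        inside = iv.contains(traj.column(name)[mask])
        out[name] = 100.0 * float(np.mean(inside))
    return OccupancyReport(occupancy=out, window=(t0, t1), mode=mode, case=case)


@dataclass(frozen=True)
class RatioPairSummary:
    pro: str
    anti: str
    healthy_ratio: float
    ratio_min: float
    ratio_max: float
    pct_change_min: float
    pct_change_max: float
    flagged: bool = False      # anti compartment reached 0 somewhere in window

    def __post_init__(self):
        if not self.flagged and self.ratio_min > self.ratio_max:
            raise ValueError("ratio min exceeds max")


@dataclass(frozen=True)
class RatioReport:
    """Min/max of pro/anti ratios over the window and percent change
    relative to the healthy steady-state ratio."""

    pairs: tuple[RatioPairSummary, ...]
    window: tuple[float, float]
    mode: str = ""
    case: str = ""

    def pair(self, pro: str, anti: str) -> RatioPairSummary:
        for p in self.pairs:
            if (p.pro, p.anti) == (pro, anti):
                return p
        raise KeyError((pro, anti))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pro": p.pro,
                "anti": p.anti,
                "healthy_ratio": p.healthy_ratio,
                "ratio_min": p.ratio_min,
                "ratio_max": p.ratio_max,
                "pct_change_min": p.pct_change_min,
                "pct_change_max": p.pct_change_max,
                "flagged": p.flagged,
                "therapy": self.mode,
                "case": self.case,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(rows)


def ratio_report(traj: Trajectory,
                 healthy_ss: ImmuneState,
                 pairs: Sequence[tuple[str, str]] = DEFAULT_RATIO_PAIRS,
                 window: tuple[float, float] = DEFAULT_WINDOW,
                 *,
                 mode: str = "",
                 case: str = "") -> RatioReport:
    """Ratio summaries for each configured (pro, anti) pair.

    ratio(t) = pro(t)/anti(t); percent change = 100 x (ratio −
    healthy_ratio)/healthy_ratio.  Grid points where the anti compartment
    is zero are excluded and the pair is flagged (a reported gap, never
    an infinity).
    """
    t0, t1 = float(window[0]), float(window[1])
    lo, hi = traj.span
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise ValueError(f"window [{t0}, {t1}] outside trajectory span [{lo}, {hi}]")
    mask = traj.window_mask(t0, t1)
    summaries = []
    for pro, anti in pairs:
        h_ratio = healthy_ss[pro] / healthy_ss[anti]
        p = traj.column(pro)[mask]
        a = traj.column(anti)[mask]
        ok = a > 0.0
        flagged = not bool(np.all(ok))
        if not np.any(ok):
            summaries.append(RatioPairSummary(pro, anti, h_ratio,
                                              np.nan, np.nan, np.nan, np.nan, True))
            continue
        r = p[ok] / a[ok]
        pct = 100.0 * (r - h_ratio) / h_ratio
        summaries.append(RatioPairSummary(
            pro, anti, float(h_ratio),
            float(r.min()), float(r.max()),
            float(pct.min()), float(pct.max()),
            flagged,
        ))
    return RatioReport(tuple(summaries), (t0, t1), mode=mode, case=case)


def fold_change(case_ss: ImmuneState, healthy_ss: ImmuneState,
                groups: Optional[Mapping[str, Sequence[str]]] = None,
                ) -> pd.DataFrame:
    """Component-wise case/healthy steady-state ratios, grouped as
    pro-inflammatory / anti-inflammatory / immune cells."""
    if groups is None:
        groups = {
            "pro_inflammatory": PRO_INFLAMMATORY,
            "anti_inflammatory": ANTI_INFLAMMATORY,
            "immune_cells": IMMUNE_CELLS,
        }
    rows = []
    for group, names in groups.items():
        for n in names:
            h = healthy_ss[n]
            if h <= 0.0:
                raise ValueError(f"healthy level of {n!r} is zero; fold change undefined")
            rows.append({"compartment": n, "group": group,
                         "fold_change": case_ss[n] / h})
    return pd.DataFrame(rows)
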