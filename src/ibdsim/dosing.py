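"""Infusion forcing function v_M(t) and the infliximab-style schedule.

A dose schedule is a list of non-overlapping infusion windows; during a
window the drug enters its compartment at a constant rate (conc/week),
outside all windows the rate is zero.  Window membership uses the
half-open convention [start, start + duration), so the integral of the
forcing function is exactly rate·duration per window and boundaries are
never double-counted.

The infliximab regimen gives induction doses at weeks 0, 2, 4 and 8,
then maintenance doses every 8 weeks.  Infusion rate and duration are
configuration, not constants: the clinical sources behind the regimen do
not pin a concentration scale, so the shipped values are nominal (see
:func:`ibdsim.scenarios.drug_nominals`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DoseWindow",
    "DoseSchedule",
    "infliximab_schedule",
    "infusion_rate",
    "INDUCTION_TIMES",
    "MAINTENANCE_INTERVAL",
]

#: induction infusions (weeks)
INDUCTION_TIMES = (0.0, 2.0, 4.0, 8.0)
#: maintenance inter-dose interval (weeks)
MAINTENANCE_INTERVAL = 8.0


@dataclass(frozen=True)
class DoseWindow:
    """One infusion: constant ``rate`` over [start, start + duration)."""

    start: float
    duration: float
    rate: float

    def __post_init__(self):
        if self.start < 0.0:
            raise ValueError("window start must be >= 0")
        if not self.duration > 0.0:
            raise ValueError("window duration must be > 0")
        if self.rate < 0.0:
            raise ValueError("window rate must be >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered list of non-overlapping infusion windows."""

    windows: tuple[DoseWindow, ...]

    def __post_init__(self):
        ws = tuple(sorted(self.windows, key=lambda w: w.start))
        object.__setattr__(self, "windows", ws)
        for a, b in zip(ws, ws[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"infusion windows overlap: [{a.start}, {a.end}) and "
                    f"[{b.start}, {b.end})"
                )

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def rate_at(self, t: float) -> float:
        """Infusion rate at time ``t`` (half-open window membership)."""
        if t < 0.0:
            raise ValueError("t must be >= 0")
        for w in self.windows:
            if w.start <= t < w.end:
                return w.rate
            if t < w.start:
                break
        return 0.0

    def start_times(self) -> tuple[float, ...]:
        return tuple(w.start for w in self.windows)

    def breakpoints(self, horizon: float) -> np.ndarray:
        """Window boundaries within [0, horizon], for integrator restarts."""
        pts = {0.0, float(horizon)}
        for w in self.windows:
            for t in (w.start, w.end):
                if 0.0 < t < horizon:
                    pts.add(float(t))
        return np.array(sorted(pts))

    def total_dose(self) -> float:
        """Integral of v_M over all windows: Σ rate·duration."""
        return float(sum(w.rate * w.duration for w in self.windows))

    def to_dicts(self) -> list[dict]:
        return [
            {"start": w.start, "duration": w.duration, "rate": w.rate}
            for w in self.windows
        ]

    @classmethod
    def from_dicts(cls, rows: Iterable[dict]) -> "DoseSchedule":
        return cls(tuple(DoseWindow(**row) for row in rows))

    @classmethod
    def empty(cls) -> "DoseSchedule":
        return cls(())


def infliximab_schedule(horizon: float, rate: float, duration: float) -> DoseSchedule:
    """Infliximab-style schedule up to ``horizon`` weeks.

    Infusions start at weeks 0, 2, 4 and 8 (induction), then every
    8 weeks (maintenance); every start time <= horizon is included.

    Parameters
    ----------
    horizon : float
        Treatment horizon in weeks (> 0).
    rate : float
        Infusion rate during each window (conc/week).
    duration : float
        Window length in weeks; must be smaller than the smallest
        inter-dose gap (2 weeks) so windows cannot overlap.
    """
    if not horizon > 0.0:
        raise ValueError("horizon must be > 0")
    gaps = [b - a for a, b in zip(INDUCTION_TIMES, INDUCTION_TIMES[1:])]
    min_gap = min(gaps + [MAINTENANCE_INTERVAL])
    if duration >= min_gap:
        raise ValueError(
            f"infusion duration {duration} >= smallest inter-dose gap {min_gap}; "
            "windows would overlap"
        )
    starts = [t for t in INDUCTION_TIMES if t <= horizon]
    t = INDUCTION_TIMES[-1] + MAINTENANCE_INTERVAL
    while t <= horizon:
        starts.append(t)
        t += MAINTENANCE_INTERVAL
    return DoseSchedule(tuple(DoseWindow(s, duration, rate) for s in starts))


def infusion_rate(t: float, schedule: DoseSchedule) -> float:
    """The forcing function v_M(t): window rate inside a window, else 0."""
    return schedule.rate_at(t)
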