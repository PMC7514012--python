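"""Optional plotting helpers (stacked occupancy bars, trajectory panels)."""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .metrics import HealthyInterval, OccupancyReport
from .simulate import Trajectory

__all__ = ["plot_occupancy", "plot_compartment"]


def plot_occupancy(reports: Iterable[OccupancyReport], ax=None):
    """Stacked occupancy bars, one bar per report (case/therapy cell)."""
    import matplotlib.pyplot as plt

    reports = list(reports)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(reports) + 2, 4))
    compartments = sorted({c for r in reports for c in r.occupancy})
    x = np.arange(len(reports))
    bottom = np.zeros(len(reports))
    for comp in compartments:
        vals = np.array([r.occupancy.get(comp, 0.0) for r in reports])
        ax.bar(x, vals, bottom=bottom, label=comp)
        bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels([f"{r.case}\n{r.mode}" for r in reports])
    ax.set_ylabel("occupancy of healthy interval (%)")
    ax.legend(fontsize="small", ncol=2)
    return ax


def plot_compartment(traj: Trajectory, name: str,
                     interval: Optional[HealthyInterval] = None, ax=None):
    """Time series of one compartment with healthy/patient levels and band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(traj.times, traj.column(name), lw=1.2, label=name)
    if interval is not None:
        ax.axhline(interval.healthy_level, ls=":", color="green", label="healthy level")
        ax.axhline(interval.patient_level, ls=":", color="red", label="patient level")
        ax.axhspan(interval.lower, interval.upper, color="orange", alpha=0.15,
                   label="healthy interval")
    ax.set_xlabel("time (weeks)")
    ax.set_ylabel("concentration (g/cm$^3$)")
    ax.legend(fontsize="small")
    return ax
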