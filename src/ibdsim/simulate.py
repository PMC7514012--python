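"""Trajectory integration and drug-free steady states.

Treatment runs integrate the full network with a stiff-capable solver
(LSODA) restarted at every infusion-window boundary, because the forcing
function v_M(t) is piecewise constant and must not be smoothed across a
discontinuity.  Output is sampled on a uniform grid (default step 0.01
week) — the same grid the occupancy metric counts on.

Steady states (used as both the patient baseline and the healthy
reference) are found by a long burn-in integration followed by a
Newton-type root solve on the drug-free right-hand side, and are
accepted only when the residual max-norm is at most 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .dosing import DoseSchedule
from .model import ImmuneModel, ImmuneState, TherapyMode

__all__ = [
    "Trajectory",
    "IntegrationError",
    "NegativeConcentrationError",
    "SteadyStateError",
    "run",
    "steady_state",
]

DEFAULT_STEP = 0.01     # output grid step, weeks
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
_EPS = 1e-9             # time-comparison fuzz, weeks


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last successful time and state."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(f"{message} (last successful t={last_time:.6g})")
        self.last_time = last_time
        self.last_state = last_state


class NegativeConcentrationError(RuntimeError):
    """A compartment fell materially below zero (beyond -10x the absolute
    solver tolerance); tiny round-off negatives are clipped instead."""


class SteadyStateError(RuntimeError):
    """Steady-state search failed to converge.  Try a different seed state
    or a longer burn-in."""


@dataclass(frozen=True)
class Trajectory:
    """Time grid, state matrix (time x compartment) and run metadata."""

    times: np.ndarray
    states: np.ndarray
    compartments: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or s.ndim != 2 or s.shape[0] != t.size:
            raise ValueError("states must be (n_times, n_compartments)")
        if s.shape[1] != len(self.compartments):
            raise ValueError("state columns must match compartment names")
        if not np.all(np.diff(t) > 0.0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("trajectory values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.compartments.index(name)]

    def state_at(self, t: float) -> ImmuneState:
        i = int(np.argmin(np.abs(self.times - t)))
        return ImmuneState(self.compartments, np.clip(self.states[i], 0.0, None))

    @property
    def final_state(self) -> ImmuneState:
        return ImmuneState(self.compartments, np.clip(self.states[-1], 0.0, None))

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.times >= t0 - _EPS) & (self.times <= t1 + _EPS)

    def to_frame(self, long: bool = True) -> pd.DataFrame:
        wide = pd.DataFrame(self.states, columns=list(self.compartments))
        wide.insert(0, "time", self.times)
        if not long:
            return wide
        return wide.melt(id_vars="time", var_name="compartment", value_name="value")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: Optional[dict] = None) -> "Trajectory":
        """Rebuild from the long CSV format (time, compartment, value)."""
        wide = df.pivot(index="time", columns="compartment", values="value")
        order = df["compartment"].drop_duplicates().tolist()
        wide = wide[order].sort_index()
        return cls(wide.index.to_numpy(), wide.to_numpy(), tuple(order),
                   metadata or {})


def _uniform_grid(horizon: float, step: float) -> np.ndarray:
    n = int(round(horizon / step))
    if n < 1:
        raise ValueError("horizon must cover at least one output step")
    return np.linspace(0.0, horizon, n + 1)


def run(model: ImmuneModel,
        mode: TherapyMode = TherapyMode.NONE,
        schedule: Optional[DoseSchedule] = None,
        init: Optional[ImmuneState] = None,
        horizon: float = 50.0,
        *,
        step: float = DEFAULT_STEP,
        rtol: float = DEFAULT_RTOL,
        atol: float = DEFAULT_ATOL,
        metadata: Optional[dict] = None) -> Trajectory:
    """Integrate the full system over [0, horizon] weeks.

    The initial state must be non-negative and cover every model
    compartment (drug compartments default to 0 when ``init`` is built
    from a mapping).  Dose-window boundaries are mandatory integrator
    breakpoints.  The result is deterministic given (model, schedule,
    init, tolerances).
    """
    if not horizon > 0.0:
        raise ValueError("horizon must be > 0")
    mode = TherapyMode(mode)
    if schedule is None:
        schedule = DoseSchedule.empty()
    if init is None:
        init = model.uniform_state(1.0)
    y0 = np.array([init[n] if n in init else 0.0 for n in model.compartments])
    if np.any(y0 < 0.0):
        raise ValueError("initial state must be non-negative")

    times = _uniform_grid(horizon, step)
    seg_edges = schedule.breakpoints(horizon) if mode is not TherapyMode.NONE \
        else np.array([0.0, horizon])
    out = np.empty((times.size, model.n))
    out[0] = y0
    stats = {"nfev": 0, "njev": 0, "nlu": 0, "segments": int(len(seg_edges) - 1)}

    y = y0
    for t0, t1 in zip(seg_edges[:-1], seg_edges[1:]):
        vM = schedule.rate_at(0.5 * (t0 + t1)) if mode is not TherapyMode.NONE else 0.0
        fun = (lambda t, yy, _vM=vM: model.rhs_full(t, yy, mode, lambda _t: _vM))
        sel = np.nonzero((times > t0 + _EPS) & (times <= t1 + _EPS))[0]
        t_eval = times[sel]
        if t_eval.size == 0 or abs(t_eval[-1] - t1) > _EPS:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(fun, (t0, t1), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(sol.message, float(sol.t[-1]) if sol.t.size else t0,
                                   sol.y[:, -1] if sol.t.size else y)
        out[sel] = sol.y[:, :sel.size].T
        y = sol.y[:, -1]
        for k in ("nfev", "njev", "nlu"):
            stats[k] += int(getattr(sol, k) or 0)

    floor = -10.0 * atol
    if out.min() < floor:
        i, j = np.unravel_index(np.argmin(out), out.shape)
        raise NegativeConcentrationError(
            f"compartment {model.compartments[j]!r} reached {out[i, j]:.3e} "
            f"at t={times[i]:.4g} (below {floor:.1e})"
        )
    np.clip(out, 0.0, None, out=out)

    meta = {
        "mode": mode.value,
        "horizon": float(horizon),
        "step": float(step),
        "rtol": float(rtol),
        "atol": float(atol),
        "schedule": schedule.to_dicts(),
        "config_hash": model.config_hash(),
        "solver": stats,
    }
    if metadata:
        meta.update(metadata)
    return Trajectory(times, out, model.compartments, meta)


def steady_state(model: ImmuneModel,
                 *,
                 seed: Optional[ImmuneState] = None,
                 burn_in: float = 500.0,
                 tol: float = 1e-10) -> ImmuneState:
    """Drug-free steady state reachable from the seed (default: unit state).

    Drug compartments are pinned at zero.  Returns a non-negative state
    at which the max-norm of the full right-hand side is <= ``tol``.
    Only the steady state reachable from the given seed is reported;
    multiple steady states are not searched for.
    """
    ns = model.n_species

    def residual(ys: np.ndarray) -> np.ndarray:
        y = np.concatenate([ys, np.zeros(3)])
        return model.rhs_full(0.0, y)[:ns]

    def polish(ys: np.ndarray) -> Optional[np.ndarray]:
        sol = root(residual, ys, method="hybr", options={"xtol": 1e-13})
        x = sol.x
        if (sol.success and np.max(np.abs(residual(x))) <= tol
                and np.min(x) >= -1e-9):
            return np.clip(x, 0.0, None)
        return None

    if seed is not None:
        x = polish(np.array([seed[n] for n in model.species]))
        if x is not None:
            return ImmuneState(model.compartments, np.concatenate([x, np.zeros(3)]))

    start = np.ones(ns) if seed is None else np.array([seed[n] for n in model.species])
    sol = solve_ivp(lambda t, ys: residual(ys), (0.0, burn_in), start,
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise SteadyStateError(f"burn-in integration failed: {sol.message}")
    x = polish(sol.y[:, -1])
    if x is None:
        raise SteadyStateError(
            "root solve did not reach the residual tolerance; "
            "try a different seed state or a longer burn-in"
        )
    return ImmuneState(model.compartments, np.concatenate([x, np.zeros(3)]))
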