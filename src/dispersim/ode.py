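"""Coupled thermal + growth + dispersal dynamics of the metacommunity.

State: three vessel temperatures plus nine population densities (three
strains x three vessels).  Per strain s and vessel v,

    dn_{s,v}/dt = r_s(T_v(t), t) n_{s,v} + d (n_{s,up(v)} - n_{s,v})

where up(v) is the upstream vessel in the cyclic flow 25 -> 37 -> 42 -> 25
and d is the per-minute replacement fraction, i.e. circulation speed
divided by the vessel volume.  (The transport coefficient multiplying a
density must be a rate, so the volumetric circulation speed is divided by
the 30-ml vessel volume, consistent with the mass-fraction speed in the
thermal model.)  Temperatures follow the lumped-capacitance balance of
:mod:`dispersim.thermal`.

Scenarios
---------
``full``            heat advection and cell migration (the real system)
``thermal_only``    medium carries heat but no cells
``migration_only``  cells migrate; temperatures pinned at their initial values

Lag-phase discontinuities (r jumps from 0 to r_growth when a strain's lag
completes in a vessel) are located with integrator event detection and the
integration restarts there, so the adaptive Runge-Kutta never steps across
an undetected jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import RunConfig, UPSTREAM_INDEX
from .growth import build_profiles
from .thermal import temperature_derivative

__all__ = ["Trajectory", "simulate", "metacommunity_derivative",
           "immigration_rate", "SCENARIOS"]

SCENARIOS = ("full", "thermal_only", "migration_only")

_UP = np.array(UPSTREAM_INDEX)


def _growth_pieces(config: RunConfig, speed: float):
    """Per-strain penalized rate/lag callables at this circulation speed."""
    profiles = build_profiles(config.growth_table)
    pen = config.penalty
    pieces = []
    for s in config.strains:
        prof = profiles[s]
        factor = pen.rate_factor(s, speed)
        shift = pen.lag_shift_min(s, speed)
        pieces.append((prof, factor, shift))
    return pieces


@dataclass
class Trajectory:
    """Simulated metacommunity trajectory on a regular output grid."""

    times_min: np.ndarray        # (nt,)
    temperatures: np.ndarray     # (nt, 3) per vessel
    densities: np.ndarray        # (nt, 3 strains, 3 vessels), cells/ul
    growth_rates: np.ndarray     # (nt, 3, 3) realized r at grid points, 1/min
    speed_ul_s: float
    scenario: str
    config: RunConfig = field(repr=False)

    def __post_init__(self):
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("output grid must be strictly increasing")
        if not np.all(np.isfinite(self.densities)):
            raise ValueError("non-finite densities in trajectory")

    @property
    def migration_coefficient_per_min(self) -> float:
        if self.scenario == "thermal_only":
            return 0.0
        return self.speed_ul_s / self.config.vessel_volume_ul * 60.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times_min):
            for vi, vessel in enumerate(self.config.vessels):
                for si, strain in enumerate(self.config.strains):
                    rows.append((float(t), vessel, strain,
                                 float(self.densities[i, si, vi]),
                                 float(self.temperatures[i, vi]),
                                 self.speed_ul_s, self.scenario))
        return pd.DataFrame(rows, columns=[
            "time_min", "vessel", "strain", "cells_per_ul",
            "temperature_C", "speed_ul_s", "scenario"])


def _derivative_core(state, t_min, config, speed_ul_s, scenario, pieces,
                     active) -> np.ndarray:
    """RHS with a fixed lag-activity mask (smooth within a segment)."""
    T = state[:3]
    n = state[3:12].reshape(3, 3)
    if scenario == "migration_only":
        dT = np.zeros(3)
    else:
        dT = temperature_derivative(T, t_min, speed_ul_s, config.thermal,
                                    config.vessel_volume_ul)
    dn = np.empty((3, 3))
    for si, (prof, factor, shift) in enumerate(pieces):
        rate = np.maximum(prof.rate(T) * factor, 0.0)
        dn[si] = np.where(active[si], rate, 0.0) * n[si]
    if scenario != "thermal_only" and speed_ul_s > 0:
        d = speed_ul_s / config.vessel_volume_ul * 60.0
        dn += d * (n[:, _UP] - n)
    return np.concatenate([dT, dn.ravel()])


def metacommunity_derivative(state, t_min: float, config: RunConfig,
                             speed_ul_s: float, scenario: str = "full",
                             pieces=None) -> np.ndarray:
    """Time derivative of [T (3), n (9 strain-major)] in per-minute units.

    The lag condition is evaluated at the given time and temperatures
    (wall-clock rule): a strain grows in a vessel once t exceeds its
    penalized lag at the vessel's current temperature.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    state = np.asarray(state, dtype=float)
    if np.any(state[3:12] < -1e-9):
        raise ValueError("negative density in state")
    if pieces is None:
        pieces = _growth_pieces(config, speed_ul_s)
    active = np.empty((3, 3), dtype=bool)
    for si, (prof, factor, shift) in enumerate(pieces):
        active[si] = t_min > prof.lag(state[:3]) + shift
    return _derivative_core(state, t_min, config, speed_ul_s, scenario,
                            pieces, active)


def _lag_events(config: RunConfig, pieces, scenario):
    """One event per (strain, vessel): lag completion t = t0(T_v(t))."""
    events = []
    for si, (prof, factor, shift) in enumerate(pieces):
        for vi in range(3):
            def g(t, y, *args, _prof=prof, _shift=shift, _vi=vi):
                return t - (float(_prof.lag(y[_vi])) + _shift)
            g.terminal = True
            g.direction = 0
            events.append(g)
    return events


def simulate(speed_ul_s: float, config: Optional[RunConfig] = None,
             scenario: str = "full", duration_min: Optional[float] = None,
             output_every_min: float = 30.0,
             rtol: float = 1e-10, atol: float = 1e-8,
             max_step_min: float = 5.0) -> Trajectory:
    """Integrate the metacommunity ODE at one circulation speed.

    Initial conditions: 120 cells/ul of every strain in every vessel and
    medium pre-equilibrated at (25, 35.5, 40) degC.  The integrator is an
    adaptive explicit Runge-Kutta (RK45) restarted at every lag-completion
    event; output is interpolated onto the requested regular grid.
    """
    if config is None:
        config = RunConfig()
    if speed_ul_s < 0:
        raise ValueError("circulation speed must be non-negative")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if duration_min is None:
        duration_min = config.duration_min

    pieces = _growth_pieces(config, speed_ul_s)
    y0 = np.concatenate([
        np.asarray(config.thermal.initial_temperatures, dtype=float),
        np.full(9, config.initial_density_cells_per_ul, dtype=float)])
    if config.lag_mode == "progress":
        y0 = np.concatenate([y0, np.zeros(9)])

    if config.lag_mode == "progress":
        events = _progress_events(pieces)
    else:
        events = _lag_events(config, pieces, scenario)

    # The realized rate jumps when a lag completes, so the lag-activity
    # mask is frozen per integration segment: inside a segment the RHS is
    # smooth, the events locate mask changes exactly, and the integration
    # restarts there with a recomputed mask.
    def active_mask(t, y):
        if config.lag_mode == "progress":
            return (y[12:21].reshape(3, 3) >= 1.0)
        mask = np.empty((3, 3), dtype=bool)
        for si, (prof, factor, shift) in enumerate(pieces):
            mask[si] = t > prof.lag(y[:3]) + shift
        return mask

    def rhs_frozen(t, y, mask):
        if config.lag_mode == "progress":
            return _derivative_progress(y, t, config, speed_ul_s, scenario,
                                        pieces, mask)
        return _derivative_core(y, t, config, speed_ul_s, scenario, pieces,
                                mask)

    t_eval = np.arange(0.0, duration_min + 0.5 * output_every_min,
                       output_every_min)
    t_cur, y_cur = 0.0, y0
    segments = []
    for _ in range(64):  # at most 9 lag crossings can occur
        if config.lag_mode == "progress":
            # snap lag progress that just reached 1 so the mask flips even
            # when interpolation left it a rounding error short
            P = y_cur[12:21]
            P[np.abs(P - 1.0) <= 1e-9] = 1.0
        mask = active_mask(t_cur, y_cur)
        # drop events sitting exactly at their crossing (they just fired);
        # the mask already reflects them
        seg_events = [g for g in events if abs(g(t_cur, y_cur)) > 1e-9]
        sol = solve_ivp(rhs_frozen, (t_cur, duration_min), y_cur,
                        args=(mask,), method="RK45",
                        rtol=rtol, atol=atol, max_step=max_step_min,
                        events=seg_events or None, dense_output=True)
        if not sol.success and sol.status != 1:
            raise RuntimeError(f"integration failed at speed {speed_ul_s}: "
                               f"{sol.message}")
        segments.append(sol)
        if sol.status != 1:
            break
        t_cur = sol.t[-1] + 1e-9
        y_cur = sol.y[:, -1]
    else:
        raise RuntimeError("too many integrator restarts")

    # sample the piecewise dense solutions on the output grid
    out = np.empty((len(t_eval), len(y0)))
    for i, t in enumerate(t_eval):
        for sol in segments:
            if sol.t[0] - 1e-9 <= t <= sol.t[-1] + 1e-9:
                out[i] = sol.sol(min(max(t, sol.t[0]), sol.t[-1]))
                break
        else:  # t falls in the 1e-9 gap between segments
            sol = min(segments, key=lambda s: abs(s.t[-1] - t))
            out[i] = sol.y[:, -1]

    temps = out[:, :3]
    dens = np.maximum(out[:, 3:12], 0.0).reshape(len(t_eval), 3, 3)
    if scenario == "migration_only":
        temps = np.tile(np.asarray(config.thermal.initial_temperatures),
                        (len(t_eval), 1))

    rates = _realized_rates(t_eval, temps, out, config, pieces, speed_ul_s)
    return Trajectory(t_eval, temps, dens, rates, float(speed_ul_s),
                      scenario, config)


def _realized_rates(t_eval, temps, out, config, pieces, speed):
    rates = np.empty((len(t_eval), 3, 3))
    for i, t in enumerate(t_eval):
        for si, (prof, factor, shift) in enumerate(pieces):
            rate = np.maximum(prof.rate(temps[i]) * factor, 0.0)
            lag = prof.lag(temps[i]) + shift
            if config.lag_mode == "progress":
                active = out[i, 12 + 3 * si: 15 + 3 * si] >= 1.0
            else:
                active = t > lag
            rates[i, si] = np.where(active, rate, 0.0)
    return rates


# ---- accumulated-lag-progress variant --------------------------------------

def _derivative_progress(state, t_min, config, speed, scenario, pieces,
                         active):
    """Variant where lag completion integrates dt/t0(T(t)) to 1."""
    T = state[:3]
    n = state[3:12].reshape(3, 3)
    if scenario == "migration_only":
        dT = np.zeros(3)
    else:
        dT = temperature_derivative(T, t_min, speed, config.thermal,
                                    config.vessel_volume_ul)
    dn = np.empty((3, 3))
    dP = np.empty((3, 3))
    for si, (prof, factor, shift) in enumerate(pieces):
        rate = np.maximum(prof.rate(T) * factor, 0.0)
        lag = np.maximum(prof.lag(T) + shift, 1e-6)
        dP[si] = 1.0 / lag
        dn[si] = np.where(active[si], rate, 0.0) * n[si]
    if scenario != "thermal_only" and speed > 0:
        d = speed / config.vessel_volume_ul * 60.0
        dn += d * (n[:, _UP] - n)
    return np.concatenate([dT, dn.ravel(), dP.ravel()])


def _progress_events(pieces):
    events = []
    for si in range(len(pieces)):
        for vi in range(3):
            def g(t, y, *args, _i=12 + 3 * si + vi):
                return y[_i] - 1.0
            g.terminal = True
            g.direction = 1
            events.append(g)
    return events


def immigration_rate(traj: Trajectory, interval_min: float = 10.0) -> np.ndarray:
    """Immigration term I_{s,v}(t) = d (n_up - n_v) on the interval grid.

    Returns an array (nt_sub, 3 strains, 3 vessels) in cells/ul per minute,
    where nt_sub covers the trajectory grid points that fall on multiples
    of ``interval_min``.
    """
    times = traj.times_min
    on_grid = np.isclose(times % interval_min, 0.0) | np.isclose(
        times % interval_min, interval_min)
    if not on_grid.any():
        raise ValueError("trajectory has no points on the interval grid")
    d = traj.migration_coefficient_per_min
    n = traj.densities[on_grid]
    return d * (n[:, :, _UP] - n)
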