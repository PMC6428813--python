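"""Lumped-capacitance thermal model of the circulation loop.

Each vessel exchanges heat with its thermomixer and with the medium pumped
in from the upstream vessel; medium in transit relaxes toward ambient
temperature in the connecting tubing.  The energy balance per vessel, with
m the medium mass, Cp its heat capacity and T(t) its (well-mixed)
temperature, reads

    m Cp dT = h A (T_mixer - T) dt + m Cp M_frac (T_in - T) dt

where M_frac = circulation speed / vessel volume is the fraction of vessel
contents replaced per unit time, and T_in is the tubing outlet temperature
of the upstream vessel.  Internally time is in seconds; public interfaces
use minutes.  Temperatures are degC (only differences appear).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import ThermalParams, UPSTREAM_INDEX, VESSELS

__all__ = [
    "mass_fraction_rate",
    "tubing_outlet_temperature",
    "temperature_derivative",
    "simulate_temperatures",
    "mean_temperature_difference",
    "TemperatureTrajectory",
]


def mass_fraction_rate(circulation_speed_ul_s: float,
                       vessel_volume_ul: float) -> float:
    """Fraction of vessel contents replaced per second (M_frac, 1/s)."""
    if vessel_volume_ul <= 0:
        raise ValueError("vessel volume must be positive")
    if circulation_speed_ul_s < 0:
        raise ValueError("circulation speed must be non-negative")
    return circulation_speed_ul_s / vessel_volume_ul


def tubing_outlet_temperature(T_upstream, circulation_speed_ul_s: float,
                              params: ThermalParams):
    """Temperature of medium arriving after transit through one tubing segment.

    The medium relaxes exponentially toward ambient over the tubing
    residence time:

        T_in = T_amb + (T_up - T_amb) * exp(-h_t A_t / (mdot Cp))

    with mdot the mass flow rate.  Slow flow means long residence and full
    equilibration with the room; fast flow delivers the medium unchanged.
    """
    if circulation_speed_ul_s <= 0:
        raise ValueError("tubing outlet temperature undefined at zero flow")
    mdot = (circulation_speed_ul_s * 1e-9  # ul/s -> m3/s
            * params.medium_density_kg_per_m3)
    expo = params.h_tubing * params.area_tubing_m2 / (
        mdot * params.heat_capacity_j_per_kg_k)
    T_up = np.asarray(T_upstream, dtype=float)
    return params.ambient_temperature + (
        T_up - params.ambient_temperature) * np.exp(-expo)


def temperature_derivative(T, t_min: float, circulation_speed_ul_s: float,
                           params: ThermalParams, vessel_volume_ul: float,
                           upstream=UPSTREAM_INDEX) -> np.ndarray:
    """dT/dt in degC per minute for the three vessels.

    ``T`` is the vector of vessel temperatures ordered (V25, V37, V42);
    ``upstream`` gives the index of each vessel's upstream neighbour under
    the cyclic flow 25 -> 37 -> 42 -> 25.
    """
    T = np.asarray(T, dtype=float)
    dT_s = params.mixer_rate_per_s * (np.asarray(params.set_temperatures) - T)
    if circulation_speed_ul_s > 0:
        M = mass_fraction_rate(circulation_speed_ul_s, vessel_volume_ul)
        T_in = tubing_outlet_temperature(T[list(upstream)],
                                         circulation_speed_ul_s, params)
        dT_s = dT_s + M * (T_in - T)
    return 60.0 * dT_s


@dataclass(frozen=True)
class TemperatureTrajectory:
    """Vessel temperatures on a regular time grid (minutes, degC)."""

    times_min: np.ndarray          # (nt,)
    temperatures: np.ndarray       # (nt, 3) ordered as VESSELS

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times_min):
            for v, name in enumerate(VESSELS):
                rows.append((float(t), name, float(self.temperatures[i, v])))
        return pd.DataFrame(rows, columns=["time_min", "vessel", "temperature_C"])


def simulate_temperatures(circulation_speed_ul_s: float, params: ThermalParams,
                          vessel_volume_ul: float = 30000.0,
                          duration_min: float = 240.0,
                          output_every_min: float = 10.0,
                          rtol: float = 1e-10, atol: float = 1e-10
                          ) -> TemperatureTrajectory:
    """Integrate the three-vessel thermal ODE alone (no populations)."""
    t_eval = np.arange(0.0, duration_min + 0.5 * output_every_min,
                       output_every_min)
    sol = solve_ivp(
        lambda t, T: temperature_derivative(T, t, circulation_speed_ul_s,
                                            params, vessel_volume_ul),
        (0.0, duration_min), np.asarray(params.initial_temperatures, float),
        t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise RuntimeError(f"thermal integration failed: {sol.message}")
    return TemperatureTrajectory(sol.t, sol.y.T)


def mean_temperature_difference(traj, burn_in_min: float = 20.0) -> float:
    """Time-averaged mean pairwise |dT| among the vessels after burn-in.

    The first ~20 min are excluded because the vessels are still relaxing
    from their pre-incubation temperatures toward the set-points.
    Accepts a :class:`TemperatureTrajectory` or any object exposing
    ``times_min`` and ``temperatures`` (nt, 3).
    """
    times = np.asarray(traj.times_min, dtype=float)
    temps = np.asarray(traj.temperatures, dtype=float)
    if times[-1] < burn_in_min:
        raise ValueError("trajectory shorter than burn-in")
    mask = times >= burn_in_min
    T = temps[mask]
    pair_diffs = (np.abs(T[:, 0] - T[:, 1]) + np.abs(T[:, 0] - T[:, 2])
                  + np.abs(T[:, 1] - T[:, 2])) / 3.0
    return float(np.trapezoid(pair_diffs, times[mask])
                 / (times[mask][-1] - times[mask][0])) if mask.sum() > 1 \
        else float(pair_diffs[0])
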