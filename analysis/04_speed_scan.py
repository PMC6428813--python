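#!/usr/bin/env python
"""The main experiment: 100-speed scan of the full metacommunity model.

Simulates the coupled thermal/growth/dispersal dynamics at 100
logarithmically spaced circulation speeds (0.05-71.5 ul/s), classifies
every speed from its BC-within vs BC-across samples, and locates the
homogenization transition.  Writes results/scan_full.csv and
results/scan_full_summary.json.
"""

import json
from pathlib import Path

from dispersim.scan import log_speed_grid, ratio_at_transition, scan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

speeds = log_speed_grid(0.05, 71.5, 100)
report = scan(speeds, scenario="full", seed=1)
report.table.to_csv(OUT / "scan_full.csv", index=False)

tab = report.table
trans = tab[tab.label == "transition"]
summary = {
    "phases": report.label_phases(),
    "transition_zone_ul_s": [float(trans.speed_ul_s.min()),
                             float(trans.speed_ul_s.max())],
    "first_homogeneous_speed_ul_s": report.first_homogeneous_speed,
    "growth_over_immigration_at_transition": ratio_at_transition(report),
    "bc_within_range_pct": [float(tab.bc_within_mean.min()),
                            float(tab.bc_within_mean.max())],
    "mean_delta_T_range_C": [float(tab.mean_delta_T.max()),
                             float(tab.mean_delta_T.min())],
}
(OUT / "scan_full_summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
print(f"\nThe metacommunity is heterogeneous at low circulation speeds, "
      f"passes through a transition zone at "
      f"{summary['transition_zone_ul_s'][0]:.2f}-"
      f"{summary['transition_zone_ul_s'][1]:.2f} ul/s, and is homogeneous "
      f"from {summary['first_homogeneous_speed_ul_s']:.2f} ul/s on.  At "
      "that transition the average growth term still exceeds the average "
      f"immigration magnitude "
      f"{summary['growth_over_immigration_at_transition']:.2f}-fold, while "
      "the temperature gradient (selection) is barely weakened: dispersal "
      "homogenizes via immigration, not via weakened selection.")
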