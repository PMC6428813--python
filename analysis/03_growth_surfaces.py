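#!/usr/bin/env python
"""Interpolated growth profiles and parameter-recovery check.

Evaluates each strain's pchip-interpolated exponential rate and lag over
a dense temperature grid (the growth "surface" driving selection in the
metacommunity) and verifies that the lag+exponential fitter recovers
known parameters from noisy replicate-like series.  Writes
results/growth_surfaces.csv and results/fit_recovery.csv.
"""

import numpy as np
import pandas as pd
from pathlib import Path

from dispersim import default_growth_table, fit_growth_parameters
from dispersim.growth import build_profiles, closed_form_population
from dispersim.synthetic import lognormal_factors

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

profiles = build_profiles(default_growth_table())
T = np.linspace(25.0, 42.0, 171)
rows = []
for strain, prof in profiles.items():
    for temp, rate, lag in zip(T, prof.rate(T), prof.lag(T)):
        rows.append({"strain": strain, "temperature_C": temp,
                     "r_growth_per_min": rate, "t0_min": lag})
surf = pd.DataFrame(rows)
surf.to_csv(OUT / "growth_surfaces.csv", index=False)

peaks = surf.loc[surf.groupby("strain")["r_growth_per_min"].idxmax()]
print("Interpolated growth maxima:")
print(peaks.round(4).to_string(index=False))

# parameter recovery under 4.1% replicate noise
t = np.arange(0, 241, 30.0)
truth = {"t0": 60.0, "r": 0.02}
clean = closed_form_population(120, truth["t0"], truth["r"], t)
rng = np.random.default_rng(42)
recs = []
for i in range(200):
    noisy = clean * lognormal_factors(0.041, clean.shape, rng)
    t0_hat, r_hat, _ = fit_growth_parameters(t, noisy, 120)
    recs.append({"replicate": i, "t0_hat": t0_hat, "r_hat": r_hat})
rec = pd.DataFrame(recs)
rec.to_csv(OUT / "fit_recovery.csv", index=False)
err = np.abs(rec.r_hat - truth["r"]) / truth["r"]
print(f"\nFit recovery under 4.1% noise (200 series): median |r error| = "
      f"{100 * err.median():.1f}% of the true rate; median t0 estimate "
      f"{rec.t0_hat.median():.1f} min (truth {truth['t0']:.0f} min).")
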