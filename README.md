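# dispersim

Does dispersal homogenize a metacommunity by *immigration* — physically
moving individuals between habitats — or indirectly, by transporting so
much material that the environmental differences (and hence selection)
disappear? `dispersim` implements a fully synthetic, simulation-based
version of a three-vessel bacterial metacommunity experiment designed to
answer that question, for microbial ecologists who want a controlled
system where dispersal and selection are coupled and separately
switchable.

The system: three 30-ml vessels at nominal 25, 37 and 42 °C, connected in
a closed loop by peristaltic tubing, each inoculated with the same three
soil strains (B42, E310, E111) at 120 cells µl⁻¹. Temperature creates
variable selection (each strain's lag t₀ and exponential rate r depend
on temperature); circulation at speed *s* creates dispersal. Per strain
and vessel the model integrates

    dn_v/dt = r(T_v(t), t) · n_v + d · (n_up(v) − n_v),      d = s / V

coupled to a lumped-capacitance heat balance per vessel
(m Cp dT/dt = hA(T_set − T) + m Cp·M_frac·(T_in − T), with tubing heat
loss toward ambient). Growth profiles are shape-preserving pchip
interpolations of per-strain anchor tables, with a dispersal-stress
penalty on (r, t₀) growing with circulation speed.

Homogeneity is scored with the quantitative Bray–Curtis kernel on
absolute densities, D = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ): **BC within** (similarity
among the three vessels of one run) against **BC across** (similarity of
each vessel to its zero-dispersal counterpart), 21 paired samples per
speed (63 with three replicates). A linear mixed-effects model with a
block-permutation fallback classifies every speed on a 100-point log grid
as heterogeneous / transition / homogeneous. The package also contains
the flow-cytometry side of the workflow: spillover deconvolution of gate
counts into absolute per-strain densities via the linear system
`observed_b = repr_b + Σ S_a/b · repr_a`, and synthetic generators for
every input (anchor tables, gate counts with 3.75 % instrument noise and
blank background, 4.1 %-CV replicate trajectories).

## Worked example

```python
import dispersim as ds
from dispersim.scan import log_speed_grid, scan, ratio_at_transition

report = scan(log_speed_grid(0.05, 71.5, 100), scenario="full", seed=1)
print(report.label_phases())
print(round(report.first_homogeneous_speed, 2))
print(round(ratio_at_transition(report), 2))
```

prints

```
['heterogeneous', 'transition', 'homogeneous']
6.83
2.63
```

meaning: with the default configuration the metacommunity is
significantly heterogeneous at low circulation speeds, passes through a
transition zone (3.3–6.3 µl s⁻¹, Bonferroni-corrected mixed-model tests
of BC-within vs BC-across), and is homogeneous from 6.83 µl s⁻¹ upward —
a speed at which the average growth term still exceeds the average
immigration magnitude 2.63-fold and the temperature gradient is barely
weakened. Dispersal homogenizes this metacommunity through immigration,
well before it weakens selection; the `migration_only` scenario (cells
move, temperatures pinned) homogenizes at the same speed, while
`thermal_only` (heat moves, cells don't) never does over the
experimental range.

The numbered drivers under `analysis/` run each stage as a narrative
(deconvolution accuracy, thermal envelopes, growth surfaces, the main
scan, the scenario decoupling, the generality variants) and write tidy
tables under `results/`. `docs/methods.md` documents the model,
parameter choices and limitations.

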