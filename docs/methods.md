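# Methods

`dispersim` models a closed circulation loop of three 30-ml incubation
vessels held by thermomixers at nominal 25, 37 and 42 °C and connected by
peristaltic tubing in the cycle 25 → 37 → 42 → 25. Each vessel holds the
same three-strain bacterial community (B42, a weak grower with a short lag;
E310, fastest at 40 °C with a ~60 min lag; E111, sharply peaked at 37 °C
with a ~120 min lag), inoculated at 120 cells µl⁻¹ per strain and followed
for 4 h. Temperature imposes *variable selection* (the strains grow
differently in each vessel); medium circulation imposes *dispersal*, which
simultaneously transports cells (immigration) and heat (weakening the
temperature gradient and hence selection). The package asks at which
circulation speed dispersal homogenizes the metacommunity, and through
which of the two coupled mechanisms.

## Thermal model

Each vessel is a lumped capacitance: well mixed, a single temperature
T(t). The energy balance per vessel is

    m Cp dT/dt = h_mixer A_mixer (T_set − T) + m Cp M_frac (T_in − T)

with `M_frac = speed / vessel volume` the fraction of vessel contents
replaced per unit time, and T_in the temperature of medium arriving from
the upstream vessel after exponential relaxation toward ambient in the
tubing, `T_in = T_amb + (T_up − T_amb) exp(−h_tub A_tub / (ṁ Cp))` (ṁ is
the mass flow rate). Heat-transfer rates are measured constants
(342.6975 and 82.3414 W m⁻² K⁻¹ for mixer and tubing). The contact areas
are not measured quantities: `A_mixer = 6.1 × 10⁻⁴ m²` is set so the
zero-flow relaxation time constant is ~10 min — vessels reach their
set-points (within 0.5 °C) in about 20 min, which is why every
time-averaged summary discards a 20-min burn-in; `A_tub = 3.14 × 10⁻³ m²`
corresponds to ~0.5 m of 2-mm-bore tubing per segment. Temperatures are
°C throughout (only differences enter), internal time is seconds, public
interfaces use minutes. Starting temperatures are the measured pre-run
values (25, 35.5, 40 °C).

Consequences worth knowing: at slow flow the tubing delivers medium at
ambient temperature (full equilibration), so weak circulation slightly
*cools* the warm vessels; the mean pairwise temperature difference among
vessels decreases monotonically with circulation speed (from 11.3 °C to
4.2 °C over the default scan); at extreme flow all vessels converge.

## Growth model

Populations follow lag + exponential growth:
n(t) = n₀ for t ≤ t₀, n(t) = n₀·exp(r·(t − t₀)) for t > t₀. Both r and t₀
depend on strain and temperature through shape-preserving piecewise cubic
Hermite (pchip) interpolation of per-strain anchor tables at 25, 28, 34,
37, 40, 42 °C; pchip passes exactly through the anchors and cannot invent
extrema between them. Outside the anchor span the profiles are clamped to
the boundary values (vessel temperatures cannot leave 25–42 °C anyway).

No numeric anchor table is published, so the default table is a
*qualitative emulation* of the described strains: the anchor grid is too
coarse to realize B42's two reported maxima (31 and 36.5 °C) as two
separate anchor-grid maxima — its default profile has a single maximum at
34 °C between them — while E310's maximum at 40 °C and E111's sharp
maximum at 37 °C are realized exactly, as is the lag ordering
B42 (20 min) < E310 (60) < E111 (120). Absolute rates (0.002–0.016 min⁻¹,
doubling times ~45–350 min) give 1.3–15-fold growth over the 4-h window.
Quantities that depend on the exact fitted profiles (the transition speed,
the growth-over-immigration ratio at transition) are therefore reproduced
in order of magnitude, not digit by digit.

Parameter fitting minimizes the sum of squared errors on the density
scale: candidate lags on the observation grid, conditional rate by
bounded 1-D search, then continuous refinement of the lag between
neighbouring grid points. Non-increasing series are reported as r = 0
with the lag spanning the series, flagged.

**Dispersal-stress penalty.** Circulating cells grow slower and lag
longer. The maximal per-strain penalties are known (−32 %/+7.2 min for
B42, −40.5 %/+31 min for E310, −9 %/+53.3 min for E111, reached at
71.5 µl s⁻¹) but the speed dependence is only described as non-linear, so
the default shape is saturating, `φ(s) = (1−e^(−s/κ))/(1−e^(−s_max/κ))`,
with κ = 10 µl s⁻¹ — approximately the geometric mean of the four
experimental circulation speeds (1.75, 5, 12, 71.5 → 9.3), i.e. the scale
at which stress is assumed to saturate. The generality variants instead
use a non-specific linear penalty on the exponential rate only.

**Lag under changing temperature.** The default rule is wall-clock: a
strain grows in a vessel once t exceeds t₀ at the vessel's *current*
temperature. An alternative "lag progress" rule (integrate dt/t₀(T(t))
until it reaches 1) is available behind `RunConfig.lag_mode`; at constant
temperature the two coincide exactly. The wall-clock rule is the default
because it evaluates r(T(t), t) directly from the interpolated surfaces
with no auxiliary state.

## Metacommunity ODE

Per strain s and vessel v:

    dn_{s,v}/dt = r_s(T_v(t), t) · n_{s,v} + d · (n_{s,up(v)} − n_{s,v})

The transport coefficient multiplying a density must be a rate, so the
volumetric circulation speed (µl s⁻¹) is divided by the 30-ml vessel
volume, exactly parallel to `M_frac` in the thermal model: at 5 µl s⁻¹ a
vessel exchanges 1 % of its contents per minute. Cells in transit through
the tubing are not a separate compartment (no delay term). The second
term is the immigration I_{s,v}(t).

Scenario switches: `thermal_only` zeroes cell migration (heat still
advected), `migration_only` pins temperatures at their initial values
(cells still migrate). These separate the two candidate homogenization
mechanisms.

**Numerics.** Adaptive RK45 (`scipy.solve_ivp`), rtol 1e-10, atol 1e-8,
max step 5 min — the system is 12-dimensional and non-stiff (all rates
≪ 1 min⁻¹), so tight tolerances are essentially free and let the
zero-dispersal limit track the closed-form growth law to better than 1e-8
relative. The realized growth rate jumps discontinuously when a lag
completes; the integrator therefore runs with one event per
(strain, vessel) located at t = t₀(T_v(t)), freezes the lag-activity mask
within each segment (the RHS is smooth there), and restarts at each
crossing. Without this, Runge–Kutta stages straddling the jump contaminate
the step and the error floor sits near 1e-7. Explicit RK preserves the
linear invariant of the transport graph, so with growth off the total
cell count per strain is conserved to round-off over the full run.

## Homogeneity metrics

All community comparisons use the quantitative Bray–Curtis kernel on raw
absolute densities, D(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), reported as
similarity 100·(1−D) %. Absolute densities matter: communities
(100,100,100) and (200,200,200) are 100 % similar on relative abundances
but D = 33.33 % on absolute ones — proportional growth is invisible to
relative-abundance comparisons. Both kernels are exposed
(`bray_curtis_dissimilarity`, `bray_curtis_similarity_relative`).

Per circulation speed: **BC within** compares the three vessel pairs of
one run at matched time points; **BC across** compares each vessel with
the same-nominal-temperature vessel of the zero-dispersal reference run
(undefined at zero dispersal). Comparisons start at 60 min — earlier the
populations still sit at the inoculum and every comparison is trivially
high — and run every 30 min to 240 min: 7 × 3 = 21 samples per metric per
trajectory, or 63 over three replicates in experimental mode.

Process strength proxies, all over a 20-min burn-in:
*CV of growth rates* — per strain, the realized rate r(T_v(t), t) is
time-averaged per vessel and the sample CV across the three vessels taken
(selection strength); *growth-over-immigration ratio* — the growth term
r·n and the immigration magnitude |I| are averaged over strains, vessels
and 10-min time points, and the ratio of the time averages taken.
Absolute |I| is used because signed net immigration around a closed cycle
sums to ~0, which would degenerate the ratio; the "growth term" is r·n
(cells µl⁻¹ min⁻¹), commensurate with I. *Mean temperature difference* —
time-averaged mean pairwise |ΔT|.

## Classifying speeds and locating the transition

Per speed, a linear mixed-effects model `value ~ metric` with a random
intercept per time point (statsmodels MixedLM) tests BC-within against
BC-across; two-sided Wald p-values are Bonferroni-corrected by the number
of speeds in the scan (100 by default). Significantly positive effect →
*homogeneous*; significantly negative → *heterogeneous*; otherwise
*transition*. A seed-fixed block-permutation test (metric labels shuffled
within time-point blocks, 4000 permutations) is bundled as an independent
engine; it is the automatic fallback when the mixed model degenerates
(e.g. zero residual variance at the scan extremes) and serves as a
cross-check oracle in the test suite. The contract is the *label*: exact
mixed-model coefficients depend on the fitting engine and are not
reproduced. The transition point is reported as the smallest grid speed
labeled homogeneous with every larger grid speed also homogeneous;
non-monotone label sequences are reported verbatim.

With the default configuration the 100-speed scan yields a heterogeneous
phase up to 3.3 µl s⁻¹, a transition zone of 3.3–6.3 µl s⁻¹ and a
homogeneous phase from 6.8 µl s⁻¹ on; at that point the growth term still
exceeds the immigration magnitude ~2.6-fold, the mean temperature
difference has barely moved, B42's growth-rate CV has declined moderately
and E310's is essentially unchanged — homogenization happens *before*
selection weakens, through immigration. The `migration_only` scenario
homogenizes at the same grid speed as the full model; `thermal_only`
never homogenizes over the experimental range (≤ 5.72 µl s⁻¹). Both
generality variants reproduce the same three-phase structure with
growth-over-immigration > 1 at their transitions.

## Synthetic data

The generators supply every pipeline input: anchor tables from shape
descriptors (Gaussian bumps on a baseline, evaluated at the anchors),
gate-count tables from the forward spillover model, and replicate
trajectories. Noise is multiplicative lognormal with unit mean — counts
are positive and errors scale with magnitude — at the instrument's 3.75 %
CV for gate counts and the observed 4.1 % between-replicate CV for
densities. Blank background (10–20 events µl⁻¹, drawn uniformly) is
spread evenly across gates and subtracted before deconvolution, as with
a sterile-medium control.

What the generators do *not* emulate: per-event scatter data (only
gate-level counts), gate drift within a sampling time point, mutualistic
strain interactions (the anchor rates are taken as including them),
carrying capacity or stationary phase (the window is lag + early
exponential only), and demographic stochasticity. Passing tests show the
pipeline machinery is correct under the stated noise model, not that the
default growth table matches any particular real strain panel.

## Spillover deconvolution

Observed gate counts are modeled as
`observed_b = repr_b + Σ_{a≠b} S_a/b · repr_a` with S_a/b the spillover
ratio of strain a into gate b (expressed relative to a's own
representative population; e.g. 1.3 % of events in a neighbour gate
against 76.9 % in the own gate gives S = 0.0169). The 3×3 system is
solved by direct linear inversion — exact and symmetric, rather than
iterative substitution — with ratios below 0.0025 omitted (configurable
threshold; omitting such a term moves recovered densities by < 0.5 % at
realistic magnitudes). Condition numbers above 1e8 are rejected; negative
solutions (possible under noise) are clamped to zero and flagged.
Absolute density = representative count / (capture fraction × volume).
Spillover is time-indexed (gates drift as cells grow); lookup uses the
nearest tabulated time, never interpolation. Under 3.75 % instrument
noise recovery is unbiased (< 1 % mean relative error); the recovered CV
is close to the injected CV at an even 1:1:1 mixture but is amplified for
a gate that receives a large share of foreign events in strongly uneven
mixtures — inherent to linear unmixing, not a defect. Mean absolute
relative error across mixing tests is ~3–4 %; no accuracy-percentage
equivalence to any other method is claimed.

## Problem sizes

Defaults are the study conditions: 100-speed log grid (0.05–71.5 µl s⁻¹;
0.05–200 for generality variants), 240-min runs output every 10 min for
metrics (30 min for the comparison grid), 21/63 BC samples per metric per
speed, 500-draw Monte-Carlo checks for deconvolution bias and 100–200
series for fit recovery. A full scan takes ~20 s on one core; the entire
test suite under a minute.

## Known limitations

* Default growth anchors and capture fractions (other than B42's 0.769)
  are synthetic emulations; quantities downstream of them are
  order-of-magnitude reproductions.
* The penalty's speed dependence (κ) is an assumption; only its endpoints
  are constrained.
* The well-mixed (lumped) vessel assumption ignores spatial structure;
  tubing transit time is ignored for both heat (beyond the steady-state
  loss factor) and cells.
* The mixed-model engine differs from an lme4 fit in REML details;
  only labels, not coefficients, should be compared across engines.
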