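"""Synthetic-data generators: every input the pipeline needs, with the
study's noise characteristics, so all downstream stages are testable
without the deposited flow-cytometry files.

Three generators:

* growth anchor tables - per-strain (rate, lag) at the anchor temperatures,
  synthesized from qualitative shape descriptors (peak locations/heights,
  lag durations) because no numeric rate table is published;
* gate-count tables - the forward model of the spillover observation
  system (representative counts + spillover + blank background, perturbed
  by the instrument's 3.75% CV), used to exercise the deconvolution;
* trajectory perturbation - multiplicative lognormal noise with the 4.1%
  between-replicate CV, emulating independent replicate experiments.

Noise is multiplicative (lognormal, mean 1) because counts are positive
and measurement error scales with magnitude.  Blank background events are
spread evenly across gates and are meant to be subtracted before
deconvolution, mirroring the sterile-medium correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (DEFAULT_ANCHOR_TEMPERATURES, STRAINS, NoiseModel)
from .cytometry import SpilloverMatrix
from .ode import Trajectory

__all__ = [
    "GrowthProfileSpec",
    "default_growth_specs",
    "generate_growth_anchor_table",
    "generate_gate_count_table",
    "perturb_trajectory",
    "default_spillover_matrix",
    "lognormal_factors",
]


def lognormal_factors(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative noise factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class GrowthProfileSpec:
    """Qualitative description of one strain's temperature response.

    ``peaks``: (temperature degC, added peak rate 1/min) of each growth
    maximum; ``baseline_rate``: rate far from any peak; ``peak_width``:
    Gaussian width (degC) of the peaks; ``lags``: lag duration per anchor
    (a scalar applies to all anchors).  The anchor-table generator
    evaluates baseline + sum of Gaussian bumps at the anchor temperatures,
    so each realized anchor-grid maximum lands on the anchor nearest a
    requested peak (up to grid resolution).
    """

    strain_id: str
    anchor_temperatures: tuple[float, ...] = DEFAULT_ANCHOR_TEMPERATURES
    peaks: tuple[tuple[float, float], ...] = ()
    baseline_rate: float = 0.002
    peak_width: float = 3.0
    lags: float | tuple[float, ...] = 60.0
    jitter_cv: float = 0.0

    def __post_init__(self):
        T = np.asarray(self.anchor_temperatures, dtype=float)
        if len(T) != len(np.unique(T)):
            raise ValueError("duplicate anchor temperatures")
        if np.any(np.diff(T) <= 0):
            raise ValueError("anchor temperatures must be strictly increasing")
        if self.baseline_rate < 0 or any(a < 0 for _, a in self.peaks):
            raise ValueError("rates must be non-negative")
        lags = np.atleast_1d(np.asarray(self.lags, dtype=float))
        if np.any(lags < 0):
            raise ValueError("lags must be non-negative")

    def rates_at_anchors(self) -> np.ndarray:
        T = np.asarray(self.anchor_temperatures, dtype=float)
        r = np.full_like(T, self.baseline_rate)
        for Tp, amp in self.peaks:
            r = r + amp * np.exp(-((T - Tp) ** 2) / (2.0 * self.peak_width ** 2))
        return r

    def lags_at_anchors(self) -> np.ndarray:
        lags = np.atleast_1d(np.asarray(self.lags, dtype=float))
        if lags.size == 1:
            return np.full(len(self.anchor_temperatures), float(lags[0]))
        if lags.size != len(self.anchor_temperatures):
            raise ValueError("lags must be scalar or one per anchor")
        return lags


def default_growth_specs() -> list[GrowthProfileSpec]:
    """Shape descriptors matching the three reference strains: B42 weak
    grower, short lag, maxima near 31 and 36.5 degC; E310 global maximum at
    40 degC, ~60 min lag; E111 sharpest maximum at 37 degC, ~120 min lag."""
    return [
        GrowthProfileSpec("B42", peaks=((31.0, 0.0065), (36.5, 0.0060)),
                          baseline_rate=0.002, peak_width=2.5, lags=20.0),
        GrowthProfileSpec("E310", peaks=((40.0, 0.011),),
                          baseline_rate=0.004, peak_width=4.0, lags=60.0),
        GrowthProfileSpec("E111", peaks=((37.0, 0.014),),
                          baseline_rate=0.002, peak_width=2.0, lags=120.0),
    ]


def generate_growth_anchor_table(specs, seed: int = 0) -> pd.DataFrame:
    """Anchor table (strain, temperature_C, r_growth_per_min, t0_min).

    Deterministic given the seed; the seed only matters when a spec
    requests anchor jitter (``jitter_cv > 0``).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one growth spec")
    anchors0 = tuple(specs[0].anchor_temperatures)
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        if tuple(spec.anchor_temperatures) != anchors0:
            raise ValueError("anchor temperatures must be shared across strains")
        rates = spec.rates_at_anchors()
        lags = spec.lags_at_anchors()
        if spec.jitter_cv > 0:
            rates = rates * lognormal_factors(spec.jitter_cv, rates.shape, rng)
            lags = lags * lognormal_factors(spec.jitter_cv, lags.shape, rng)
        for T, r, t0 in zip(spec.anchor_temperatures, rates, lags):
            rows.append((spec.strain_id, float(T), float(r), float(t0)))
    return pd.DataFrame(rows, columns=["strain", "temperature_C",
                                       "r_growth_per_min", "t0_min"])


def default_spillover_matrix(time_min: float = 0.0) -> SpilloverMatrix:
    """Spillover ratios and capture fractions of the reference strain panel
    at the start of incubation.  B42's spillover into the E111 gate sits
    below the omission threshold at all times.  Capture fractions other
    than B42's 0.769 are synthetic defaults in the same range."""
    return SpilloverMatrix(
        strains=STRAINS,
        ratios={
            ("B42", "E310"): 0.0169,
            ("B42", "E111"): 0.002,
            ("E310", "B42"): 0.135,
            ("E310", "E111"): 0.007,
            ("E111", "B42"): 0.127,
            ("E111", "E310"): 0.064,
        },
        capture_fractions={"B42": 0.769, "E310": 0.83, "E111": 0.80},
        time_min=time_min)


def generate_gate_count_table(true_densities, spillover: SpilloverMatrix,
                              noise: NoiseModel | None = None,
                              sample_volume_ul: float = 20.0,
                              capture_fractions=None,
                              seed: int = 0, sample_id: str = "S1",
                              omit_threshold: float = 0.0
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Forward model of the gate observation system.

    ``true_densities``: per-strain cells/ul ordered as ``spillover.strains``
    (or a mapping).  Representative counts are density x volume x capture
    fraction; observed gate counts add spillover from the other strains
    and a uniform blank background, then instrument noise.

    Returns (table, blank) where ``table`` is tidy
    (sample_id, gate, events, volume_ul) and ``blank`` maps gate ->
    background events (the sterile-control measurement to subtract before
    deconvolution).
    """
    strains = spillover.strains
    if isinstance(true_densities, dict):
        dens = np.array([true_densities[s] for s in strains], dtype=float)
    else:
        dens = np.asarray(true_densities, dtype=float)
    if np.any(dens < 0):
        raise ValueError("densities must be non-negative")
    if noise is None:
        noise = NoiseModel.none()
    capture = (np.asarray(capture_fractions, dtype=float)
               if capture_fractions is not None
               else spillover.capture_vector())
    rng = np.random.default_rng(seed)

    representative = dens * sample_volume_ul * capture
    M = spillover.mixing_matrix(omit_threshold)
    observed = M @ representative

    lo, hi = noise.blank_rate_range
    blank_rate = rng.uniform(lo, hi) if hi > lo else lo
    blank_per_gate = blank_rate * sample_volume_ul / len(strains)
    counts = (observed + blank_per_gate) * lognormal_factors(
        noise.instrument_cv, observed.shape, rng)

    table = pd.DataFrame({
        "sample_id": sample_id, "gate": list(strains),
        "events": counts, "volume_ul": sample_volume_ul})
    blank = pd.Series(blank_per_gate, index=list(strains), name="events")
    return table, blank


def perturb_trajectory(traj: Trajectory, noise: NoiseModel,
                       n_replicates: int, seed: int = 0) -> list[Trajectory]:
    """Replicate-like copies of a trajectory with multiplicative lognormal
    density noise of the configured replicate CV; temperatures untouched."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        factors = lognormal_factors(noise.replicate_cv,
                                    traj.densities.shape, rng)
        out.append(Trajectory(
            times_min=traj.times_min.copy(),
            temperatures=traj.temperatures.copy(),
            densities=traj.densities * factors,
            growth_rates=traj.growth_rates.copy(),
            speed_ul_s=traj.speed_ul_s, scenario=traj.scenario,
            config=traj.config))
    return out
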