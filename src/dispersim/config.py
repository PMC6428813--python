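"""Run configuration for the three-vessel metacommunity pipeline.

All tunable quantities live here, as data, so that a run is fully described
by a single :class:`RunConfig` that can be round-tripped through YAML.

The defaults describe the reference system: three 30-ml vessels held by
thermomixers at nominal 25, 37 and 42 degC, connected in a closed loop
(25 -> 37 -> 42 -> 25) by peristaltic tubing, inoculated with three
soil isolates (B42, E310, E111) at 120 cells/ul each, and monitored for
4 h.  Growth anchors are a qualitative emulation of the strains' measured
temperature response (see ``docs/methods.md``): B42 grows weakly with a
short lag, E310 peaks at 40 degC with a ~60 min lag, and E111 has the
sharpest maximum (37 degC) and the longest lag (~120 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

STRAINS = ("B42", "E310", "E111")
VESSELS = ("V25", "V37", "V42")

#: cyclic flow order 25 -> 37 -> 42 -> 25: upstream vessel index for each vessel
UPSTREAM_INDEX = (2, 0, 1)

#: anchor temperatures (degC) of the no-dispersal growth assays
DEFAULT_ANCHOR_TEMPERATURES = (25.0, 28.0, 34.0, 37.0, 40.0, 42.0)


@dataclass(frozen=True)
class ThermalParams:
    """Lumped-capacitance heat-transfer parameters.

    ``h_mixer``/``h_tubing`` are the measured heat-transfer rates between
    thermomixer and vessel medium and between tubing and ambient air
    (W m-2 K-1).  ``area_mixer_m2`` sets the vessel relaxation time
    constant tau = m*Cp/(h*A); the default gives tau ~ 10 min so a vessel
    reaches its set-point (within 0.5 degC) in about 20 min of incubation.
    ``area_tubing_m2`` corresponds to ~0.5 m of 2-mm-bore tubing per
    segment.  Temperatures are degC throughout; only differences enter the
    equations.
    """

    h_mixer: float = 342.6975
    h_tubing: float = 82.3414
    area_mixer_m2: float = 6.1e-4
    area_tubing_m2: float = 3.14e-3
    medium_mass_kg: float = 0.030
    heat_capacity_j_per_kg_k: float = 4184.0
    medium_density_kg_per_m3: float = 1000.0
    set_temperatures: tuple[float, float, float] = (25.0, 37.0, 42.0)
    ambient_temperature: float = 25.0
    initial_temperatures: tuple[float, float, float] = (25.0, 35.5, 40.0)

    def __post_init__(self) -> None:
        for name in ("h_mixer", "h_tubing", "area_mixer_m2", "area_tubing_m2",
                     "medium_mass_kg", "heat_capacity_j_per_kg_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mixer_rate_per_s(self) -> float:
        """h*A/(m*Cp): relaxation rate toward the set-point, 1/s."""
        return (self.h_mixer * self.area_mixer_m2
                / (self.medium_mass_kg * self.heat_capacity_j_per_kg_k))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement / replicate noise for the synthetic data generators.

    instrument_cv: CV of gate counts across repeated instrument reads
        (0.0375 = the flow cytometer's measured 3.75%).
    replicate_cv: CV of densities across independent replicate experiments
        (0.041 = the 4.1% observed across biological replicates).
    blank_rate_range: background events per ul in sterile medium; drawn
        uniformly per sample and spread evenly across gates.
    """

    instrument_cv: float = 0.0375
    replicate_cv: float = 0.041
    blank_rate_range: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        if self.instrument_cv < 0 or self.replicate_cv < 0:
            raise ValueError("CVs must be non-negative")
        lo, hi = self.blank_rate_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid blank_rate_range")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(instrument_cv=0.0, replicate_cv=0.0, blank_rate_range=(0.0, 0.0))


@dataclass(frozen=True)
class PenaltyModel:
    """Dispersal-stress penalty on the growth parameters.

    Circulating the medium stresses the cells: the exponential rate drops
    and the lag lengthens, more so at faster circulation.  ``dr_max`` is
    the maximal fractional change of r_growth per strain (negative),
    ``dt0_max_min`` the maximal lag extension in minutes, both reached at
    ``speed_max_ul_s``.  ``shape``:

    * ``"saturating"`` - multiplier (1-exp(-s/kappa))/(1-exp(-s_max/kappa)),
      strain-specific maxima (the default model);
    * ``"linear_uniform"`` - a non-specific penalty on the exponential
      rate only, growing linearly with speed up to ``uniform_dr_max``
      (used by the generality simulations).
    """

    dr_max: dict[str, float] = field(default_factory=lambda: {
        "B42": -0.32, "E310": -0.405, "E111": -0.09})
    dt0_max_min: dict[str, float] = field(default_factory=lambda: {
        "B42": 7.2, "E310": 31.0, "E111": 53.3})
    shape: str = "saturating"
    kappa_ul_s: float = 10.0
    speed_max_ul_s: float = 71.5
    uniform_dr_max: float = -0.3

    def __post_init__(self) -> None:
        if self.shape not in ("saturating", "linear_uniform"):
            raise ValueError(f"unknown penalty shape {self.shape!r}")
        if self.kappa_ul_s <= 0 or self.speed_max_ul_s <= 0:
            raise ValueError("kappa and speed_max must be positive")

    def multiplier(self, speed_ul_s: float) -> float:
        """Fraction of the maximal penalty realized at this speed, in [0, 1]."""
        s = max(float(speed_ul_s), 0.0)
        if self.shape == "saturating":
            denom = 1.0 - np.exp(-self.speed_max_ul_s / self.kappa_ul_s)
            return min((1.0 - np.exp(-s / self.kappa_ul_s)) / denom, 1.0)
        return min(s / self.speed_max_ul_s, 1.0)

    def rate_factor(self, strain: str, speed_ul_s: float) -> float:
        """Multiplicative factor on r_growth (<= 1, >= 0)."""
        phi = self.multiplier(speed_ul_s)
        if self.shape == "linear_uniform":
            return max(1.0 + self.uniform_dr_max * phi, 0.0)
        return max(1.0 + self.dr_max[strain] * phi, 0.0)

    def lag_shift_min(self, strain: str, speed_ul_s: float) -> float:
        """Additive shift on t0 in minutes (>= 0)."""
        if self.shape == "linear_uniform":
            return 0.0
        return self.dt0_max_min[strain] * self.multiplier(speed_ul_s)

    @classmethod
    def none(cls) -> "PenaltyModel":
        return cls(dr_max={s: 0.0 for s in STRAINS},
                   dt0_max_min={s: 0.0 for s in STRAINS})


def default_growth_table() -> pd.DataFrame:
    """Default growth anchors (strain, temperature_C, r_growth_per_min, t0_min).

    Synthesized to match the qualitative temperature responses of the three
    strains: B42 lowest rates overall with maxima between 28 and 37 degC and
    a short lag; E310 global maximum at 40 degC, ~60 min lag; E111 sharpest
    maximum at 37 degC, ~120 min lag.  Lag ordering B42 < E310 < E111.
    """
    rows = []
    anchors = DEFAULT_ANCHOR_TEMPERATURES
    rates = {
        "B42":  (0.0021, 0.0052, 0.0088, 0.0082, 0.0034, 0.0024),
        "E310": (0.0040, 0.0041, 0.0076, 0.0123, 0.0150, 0.0137),
        "E111": (0.0020, 0.0022, 0.0065, 0.0160, 0.0065, 0.0023),
    }
    lags = {"B42": 20.0, "E310": 60.0, "E111": 120.0}
    for strain in STRAINS:
        for T, r in zip(anchors, rates[strain]):
            rows.append((strain, T, r, lags[strain]))
    return pd.DataFrame(rows, columns=["strain", "temperature_C",
                                       "r_growth_per_min", "t0_min"])


def generality_growth_table(variant: str) -> pd.DataFrame:
    """Growth anchors for the two generality simulations.

    Both variants make the strains' temperature responses more similar to
    each other than the reference profiles.  ``sim2``: single global maxima
    (B42 at 35.5 degC and highest overall, then E310 at 40 degC, then E111
    at 37 degC).  ``sim3``: B42 grows fastest over 25-37 degC; E310 exceeds
    E111 at every temperature with a local maximum at 37.5 degC.
    """
    if variant == "sim2":
        anchors = (25.0, 28.0, 31.0, 34.0, 35.5, 37.0, 40.0, 42.0)
        rates = {
            "B42":  (0.0060, 0.0080, 0.0110, 0.0140, 0.0160, 0.0140, 0.0090, 0.0070),
            "E310": (0.0050, 0.0060, 0.0070, 0.0090, 0.0100, 0.0110, 0.0130, 0.0110),
            "E111": (0.0030, 0.0040, 0.0050, 0.0070, 0.0080, 0.0100, 0.0060, 0.0040),
        }
    elif variant == "sim3":
        anchors = (25.0, 28.0, 31.0, 34.0, 37.5, 40.0, 42.0)
        rates = {
            "B42":  (0.0100, 0.0110, 0.0120, 0.0120, 0.0100, 0.0060, 0.0040),
            "E310": (0.0060, 0.0070, 0.0080, 0.0090, 0.0110, 0.0090, 0.0080),
            "E111": (0.0040, 0.0050, 0.0060, 0.0070, 0.0080, 0.0050, 0.0030),
        }
    else:
        raise ValueError(f"unknown generality variant {variant!r}")
    lags = {"B42": 20.0, "E310": 60.0, "E111": 120.0}
    rows = [(s, T, r, lags[s]) for s in STRAINS
            for T, r in zip(anchors, rates[s])]
    return pd.DataFrame(rows, columns=["strain", "temperature_C",
                                       "r_growth_per_min", "t0_min"])


@dataclass
class RunConfig:
    """Everything needed to reproduce one scan of the metacommunity."""

    strains: tuple[str, ...] = STRAINS
    vessels: tuple[str, ...] = VESSELS
    vessel_volume_ul: float = 30000.0
    initial_density_cells_per_ul: float = 120.0
    duration_min: float = 240.0
    thermal: ThermalParams = field(default_factory=ThermalParams)
    penalty: PenaltyModel = field(default_factory=PenaltyModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    growth_table: pd.DataFrame = field(default_factory=default_growth_table)
    #: lag completion rule: "wall_clock" compares t against t0 at the current
    #: temperature; "progress" integrates dt/t0(T(t)) until it reaches 1.
    lag_mode: str = "wall_clock"
    speed_min_ul_s: float = 0.05
    speed_max_ul_s: float = 71.5
    n_speeds: int = 100
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.lag_mode not in ("wall_clock", "progress"):
            raise ValueError(f"unknown lag_mode {self.lag_mode!r}")
        if self.vessel_volume_ul <= 0:
            raise ValueError("vessel_volume_ul must be positive")

    # ---- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["thermal"] = asdict(self.thermal)
        d["penalty"] = asdict(self.penalty)
        d["noise"] = asdict(self.noise)
        d["growth_table"] = self.growth_table.to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["thermal"] = ThermalParams(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in d["thermal"].items()})
        pen = dict(d["penalty"])
        d["penalty"] = PenaltyModel(**pen)
        noi = dict(d["noise"])
        noi["blank_rate_range"] = tuple(noi["blank_rate_range"])
        d["noise"] = NoiseModel(**noi)
        d["growth_table"] = pd.DataFrame(d["growth_table"])
        for key in ("strains", "vessels"):
            d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(**overrides) -> RunConfig:
    return RunConfig(**overrides)


def generality_config(variant: str) -> RunConfig:
    """Config for a generality simulation: ~3x lower vessel heat buffering,
    speed range extended to 200 ul/s, more-similar growth profiles, and a
    non-specific linear penalty on the exponential rate only."""
    base = ThermalParams()
    thermal = ThermalParams(h_mixer=base.h_mixer / 3.0)
    penalty = PenaltyModel(shape="linear_uniform", speed_max_ul_s=200.0)
    return RunConfig(thermal=thermal, penalty=penalty,
                     growth_table=generality_growth_table(variant),
                     speed_max_ul_s=200.0)
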