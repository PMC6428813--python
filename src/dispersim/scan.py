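"""Circulation-speed scan and transition-point location.

Simulates the metacommunity over a logarithmic grid of circulation speeds
(denser at low speeds, where the homogenization transition sits),
classifies every speed as heterogeneous / transition / homogeneous from
its BC-within vs BC-across samples, and reports the first-homogeneous
speed: the smallest grid speed labeled homogeneous with every larger grid
speed also homogeneous.

Two kinds of follow-up experiments reuse the same machinery:

* scenario comparison - ``thermal_only`` (heat moves, cells do not) and
  ``migration_only`` (cells move, temperatures pinned), to separate the
  roles of weakening selection and immigration;
* generality simulations - ~3x lower vessel heat buffering, speeds up to
  200 ul/s, more-similar growth profiles and a linear non-specific
  penalty, to check that the homogenization-by-immigration result does not
  hinge on the reference parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig, generality_config
from .metrics import bc_across, bc_within, process_summary
from .ode import Trajectory, simulate
from .stats import SpeedClassification, classify_speed
from .synthetic import perturb_trajectory

__all__ = ["log_speed_grid", "scan", "generality_experiment", "ScanReport"]


def log_speed_grid(min_speed: float, max_speed: float, n: int = 100
                   ) -> np.ndarray:
    """n geometrically spaced speeds from min to max inclusive (ul/s)."""
    if min_speed <= 0:
        raise ValueError("min_speed must be positive (zero dispersal is the "
                         "separate reference run)")
    if max_speed <= min_speed:
        raise ValueError("max_speed must exceed min_speed")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return np.geomspace(min_speed, max_speed, n)


@dataclass
class ScanReport:
    """Per-speed classification and process summaries for one scenario."""

    scenario: str
    speeds: np.ndarray
    table: pd.DataFrame                    # one row per speed
    first_homogeneous_speed: Optional[float]
    classifications: list[SpeedClassification] = field(repr=False)
    samples: pd.DataFrame = field(repr=False, default=None)

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    def label_phases(self) -> list[str]:
        """Collapsed run-length label sequence, e.g. [het, trans, hom]."""
        phases = []
        for lab in self.labels:
            if not phases or phases[-1] != lab:
                phases.append(lab)
        return phases


def _first_homogeneous(speeds, labels) -> Optional[float]:
    homog = np.array([lab == "homogeneous" for lab in labels])
    if not homog.any():
        return None
    # smallest speed from which everything larger is homogeneous
    idx = len(homog)
    for i in range(len(homog) - 1, -1, -1):
        if homog[i]:
            idx = i
        else:
            break
    return float(speeds[idx]) if idx < len(homog) else None


def scan(speeds, config: Optional[RunConfig] = None, scenario: str = "full",
         replicates: int = 0, seed: int = 0, engine: str = "auto",
         output_every_min: float = 10.0, keep_samples: bool = False
         ) -> ScanReport:
    """Simulate + classify every speed on the grid.

    ``replicates=0`` runs in model mode (21 BC samples per metric and
    speed); ``replicates>=2`` adds lognormal replicate noise to each
    trajectory, emulating independent replicate experiments (3 replicates
    give the 63-sample experimental design).  Failures at individual
    speeds are recorded and do not abort the scan.
    """
    if config is None:
        config = RunConfig()
    speeds = np.asarray(speeds, dtype=float)
    reference = simulate(0.0, config, scenario=scenario,
                         output_every_min=output_every_min)
    if replicates:
        ref_for_bc = perturb_trajectory(reference, config.noise, replicates,
                                        seed=seed)
    else:
        ref_for_bc = reference

    rows, classifications, all_samples = [], [], []
    for k, speed in enumerate(speeds):
        try:
            traj = simulate(float(speed), config, scenario=scenario,
                            output_every_min=output_every_min)
            run = (perturb_trajectory(traj, config.noise, replicates,
                                      seed=seed + 1000 + k)
                   if replicates else traj)
            within = bc_within(run)
            across = bc_across(run, ref_for_bc)
            cls = classify_speed(within, across, alpha=config.alpha,
                                 n_tests=len(speeds), engine=engine,
                                 seed=seed + k)
            summ = process_summary(traj)
        except Exception as exc:  # keep scanning; report the failure
            warnings.warn(f"speed {speed:.4g} ul/s failed: {exc}")
            rows.append({"speed_ul_s": float(speed), "label": "failed",
                         "error": str(exc)})
            continue
        if keep_samples:
            all_samples.append(pd.concat([within, across], ignore_index=True))
        classifications.append(cls)
        row = {
            "speed_ul_s": float(speed),
            "label": cls.label,
            "effect": cls.effect,
            "statistic": cls.statistic,
            "p_corrected": cls.p_corrected,
            "engine": cls.engine,
            "bc_within_mean": float(within["value_pct"].mean()),
            "bc_across_mean": float(across["value_pct"].mean()),
            "n_within": cls.n_within,
            "n_across": cls.n_across,
            "growth_over_immigration": summ.growth_over_immigration,
            "mean_delta_T": summ.mean_delta_T,
        }
        for strain, cv in summ.cv_growth.items():
            row[f"cv_growth_{strain}"] = cv
        rows.append(row)

    table = pd.DataFrame(rows)
    ok = table[table["label"] != "failed"]
    first = _first_homogeneous(ok["speed_ul_s"].to_numpy(),
                               list(ok["label"]))
    samples = (pd.concat(all_samples, ignore_index=True)
               if all_samples else None)
    return ScanReport(scenario, speeds, table, first, classifications, samples)


def generality_experiment(variant: str, n_speeds: int = 100, seed: int = 0,
                          engine: str = "auto") -> ScanReport:
    """Run one generality simulation ("sim2" or "sim3") end to end.

    Uses the variant config (h_mixer/3, linear uniform penalty, altered
    growth profiles) over a log grid from 0.05 to 200 ul/s.
    """
    config = generality_config(variant)
    speeds = log_speed_grid(config.speed_min_ul_s, config.speed_max_ul_s,
                            n_speeds)
    return scan(speeds, config, scenario="full", seed=seed, engine=engine)


def ratio_at_transition(report: ScanReport) -> Optional[float]:
    """Growth-over-immigration ratio at the first homogeneous speed."""
    if report.first_homogeneous_speed is None:
        return None
    tab = report.table
    row = tab[np.isclose(tab["speed_ul_s"], report.first_homogeneous_speed)]
    return float(row["growth_over_immigration"].iloc[0])
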