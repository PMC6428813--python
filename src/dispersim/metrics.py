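"""Homogeneity and process-strength metrics.

Community comparisons use the quantitative Bray-Curtis kernel on raw
absolute densities (cells/ul), without any transformation: with absolute
abundances the metric is sensitive to overall population growth, which a
relative-abundance comparison hides.  Two community-similarity summaries
are computed per circulation speed:

* **BC within** - pairwise similarity among the three vessels of one run
  at matched time points: how alike the communities inside the
  metacommunity are.
* **BC across** - similarity of each vessel to the same-nominal-temperature
  vessel of the zero-dispersal run at matched time points: how much the
  communities changed relative to no dispersal.

Comparisons start after the first hour (before that all communities still
sit near the inoculum and are trivially similar) and run every 30 min to
240 min: 7 time points x 3 pairs = 21 samples per trajectory, or 63 over
three replicate trajectories.

Process-strength summaries: the coefficient of variation of each strain's
realized growth rate across vessels (a proxy for the strength of variable
selection), the growth-over-immigration ratio (how fast populations grow
relative to how fast immigrants replace them), and the mean temperature
difference among vessels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ode import Trajectory, immigration_rate
from .thermal import mean_temperature_difference

__all__ = [
    "bray_curtis_dissimilarity",
    "bray_curtis_similarity_relative",
    "bc_within",
    "bc_across",
    "cv_growth_rates",
    "growth_over_immigration",
    "ProcessSummary",
    "process_summary",
    "COMPARISON_TIMES",
]

#: time points (min) entering the BC comparisons
COMPARISON_TIMES = (60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0)

_PAIRS = ((0, 1), (0, 2), (1, 2))


def bray_curtis_dissimilarity(x, y) -> float:
    """Quantitative Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    total = float(np.sum(x + y))
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero communities")
    return float(np.sum(np.abs(x - y)) / total)


def bray_curtis_similarity_relative(x, y) -> float:
    """100 x (1 - D) after normalizing each community to relative abundances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = float(np.sum(x)), float(np.sum(y))
    if sx == 0 or sy == 0:
        raise ValueError("relative abundances undefined for an empty community")
    return 100.0 * (1.0 - bray_curtis_dissimilarity(x / sx, y / sy))


def _similarity_pct(x, y) -> float:
    return 100.0 * (1.0 - bray_curtis_dissimilarity(x, y))


def _check_grid(traj: Trajectory) -> dict[float, int]:
    index = {}
    for t in COMPARISON_TIMES:
        hits = np.flatnonzero(np.isclose(traj.times_min, t))
        if len(hits) == 0:
            raise ValueError(f"trajectory missing comparison time {t} min")
        index[t] = int(hits[0])
    return index


def _as_replicates(traj) -> list[Trajectory]:
    return list(traj) if isinstance(traj, (list, tuple)) else [traj]


def bc_within(traj) -> pd.DataFrame:
    """BC-within samples: 3 vessel pairs x 7 time points per trajectory.

    ``traj`` may be a single :class:`Trajectory` (21 samples, model mode)
    or a list of replicate trajectories (63 samples over 3 replicates,
    experimental mode).  Returns a tidy frame
    (metric, time_min, pair, replicate, value_pct, speed_ul_s).
    """
    rows = []
    for rep, tr in enumerate(_as_replicates(traj)):
        idx = _check_grid(tr)
        for t, i in idx.items():
            for a, b in _PAIRS:
                val = _similarity_pct(tr.densities[i, :, a],
                                      tr.densities[i, :, b])
                rows.append(("within", t, f"{tr.config.vessels[a]}-"
                             f"{tr.config.vessels[b]}", rep, val,
                             tr.speed_ul_s))
    return pd.DataFrame(rows, columns=["metric", "time_min", "pair",
                                       "replicate", "value_pct", "speed_ul_s"])


def bc_across(traj, zero_dispersal_traj) -> pd.DataFrame:
    """BC-across samples: each vessel vs the same-temperature vessel of the
    zero-dispersal reference, 3 vessels x 7 time points per trajectory.

    Undefined at zero circulation speed (the run would be compared with
    itself).  In replicate mode the i-th replicate run is compared with the
    i-th replicate of the reference.
    """
    runs = _as_replicates(traj)
    refs = _as_replicates(zero_dispersal_traj)
    if any(tr.speed_ul_s == 0 for tr in runs):
        raise ValueError("BC across is undefined at zero dispersal")
    if len(refs) == 1:
        refs = refs * len(runs)
    if len(refs) != len(runs):
        raise ValueError("replicate counts of run and reference differ")
    rows = []
    for rep, (tr, ref) in enumerate(zip(runs, refs)):
        idx = _check_grid(tr)
        ridx = _check_grid(ref)
        if tr.config.vessels != ref.config.vessels:
            raise ValueError("vessel labels differ between run and reference")
        for t in COMPARISON_TIMES:
            i, j = idx[t], ridx[t]
            for v, vessel in enumerate(tr.config.vessels):
                val = _similarity_pct(tr.densities[i, :, v],
                                      ref.densities[j, :, v])
                rows.append(("across", t, vessel, rep, val, tr.speed_ul_s))
    return pd.DataFrame(rows, columns=["metric", "time_min", "pair",
                                       "replicate", "value_pct", "speed_ul_s"])


def cv_growth_rates(traj: Trajectory, burn_in_min: float = 20.0
                    ) -> dict[str, float]:
    """Per-strain CV of time-averaged realized growth rates across vessels.

    For each strain, the realized rate r(T_v(t), t) is averaged over
    t >= burn_in per vessel; the CV (sample sd / mean) of the three vessel
    averages quantifies how differently the strain grows along the
    temperature gradient.  A strain with zero mean rate gets NaN.
    """
    mask = traj.times_min >= burn_in_min
    if not mask.any():
        raise ValueError("trajectory shorter than burn-in")
    out = {}
    for si, strain in enumerate(traj.config.strains):
        per_vessel = traj.growth_rates[mask, si, :].mean(axis=0)
        m = per_vessel.mean()
        out[strain] = float(per_vessel.std(ddof=1) / m) if m > 0 else float("nan")
    return out


def growth_over_immigration(traj: Trajectory, interval_min: float = 10.0
                            ) -> float:
    """Time-averaged growth term over time-averaged immigration magnitude.

    At each interval point the growth term r*n and the immigration
    magnitude |I| = d |n_up - n_v| are averaged over strains and vessels;
    the ratio of their time averages is returned.  Infinite (numpy inf)
    when there is no immigration at all (zero speed).
    """
    times = traj.times_min
    on_grid = np.isclose(times % interval_min, 0.0) | np.isclose(
        times % interval_min, interval_min)
    if not on_grid.any():
        raise ValueError("trajectory has no points on the interval grid")
    growth_term = (traj.growth_rates[on_grid] * traj.densities[on_grid]).mean(
        axis=(1, 2))
    I = immigration_rate(traj, interval_min)
    imm_term = np.abs(I).mean(axis=(1, 2))
    denom = float(imm_term.mean())
    if denom == 0:
        return float("inf")
    return float(growth_term.mean() / denom)


@dataclass(frozen=True)
class ProcessSummary:
    """Selection/immigration strength summaries at one circulation speed."""

    speed_ul_s: float
    cv_growth: dict[str, float]
    growth_over_immigration: float
    mean_delta_T: float


def process_summary(traj: Trajectory, burn_in_min: float = 20.0,
                    interval_min: float = 10.0) -> ProcessSummary:
    return ProcessSummary(
        speed_ul_s=traj.speed_ul_s,
        cv_growth=cv_growth_rates(traj, burn_in_min),
        growth_over_immigration=growth_over_immigration(traj, interval_min),
        mean_delta_T=mean_temperature_difference(traj, burn_in_min))
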