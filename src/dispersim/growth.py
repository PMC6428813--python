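"""Temperature- and strain-dependent growth law: lag + exponential.

Over the 4-h window each strain grows as

    n(t) = n0                          for t <= t0
    n(t) = n0 * exp(r_growth (t - t0)) for t >  t0

with both the lag length t0 and the exponential rate r_growth depending on
strain and temperature.  Rates and lags measured at a handful of anchor
temperatures are interpolated with a shape-preserving piecewise cubic
Hermite polynomial (pchip), which passes exactly through the anchors and
introduces no spurious extrema between them.  Outside the anchor range the
profile is clamped to the boundary values (vessel temperatures stay within
the anchor span by construction).

A dispersal-stress penalty (see :class:`dispersim.config.PenaltyModel`)
lowers r_growth and lengthens t0 as circulation speed increases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

from .config import PenaltyModel

__all__ = [
    "StrainGrowthProfile",
    "build_profiles",
    "closed_form_population",
    "growth_rate_at",
    "fit_growth_parameters",
]


class _ClampedPchip:
    """Pchip through the anchors, constant beyond the anchor range."""

    def __init__(self, x, y):
        self._lo, self._hi = float(x[0]), float(x[-1])
        self._f = PchipInterpolator(x, y, extrapolate=False)
        self._ylo, self._yhi = float(y[0]), float(y[-1])

    def __call__(self, x):
        xc = np.clip(np.asarray(x, dtype=float), self._lo, self._hi)
        return self._f(xc)


@dataclass(frozen=True)
class StrainGrowthProfile:
    """Interpolated r_growth(T) and t0(T) for one strain."""

    strain_id: str
    anchor_temperatures: np.ndarray
    anchor_rates: np.ndarray
    anchor_lags: np.ndarray
    _rate: _ClampedPchip
    _lag: _ClampedPchip

    @classmethod
    def from_anchors(cls, strain_id, temperatures, rates, lags):
        T = np.asarray(temperatures, dtype=float)
        r = np.asarray(rates, dtype=float)
        t0 = np.asarray(lags, dtype=float)
        if len(T) < 2 or np.any(np.diff(T) <= 0):
            raise ValueError("anchor temperatures must be strictly increasing")
        if np.any(r < 0) or np.any(t0 < 0):
            raise ValueError("rates and lags must be non-negative")
        return cls(strain_id, T, r, t0, _ClampedPchip(T, r), _ClampedPchip(T, t0))

    def rate(self, T):
        """Interpolated exponential rate at temperature T, 1/min."""
        return self._rate(T)

    def lag(self, T):
        """Interpolated lag duration at temperature T, min."""
        return self._lag(T)


def build_profiles(growth_table: pd.DataFrame) -> dict[str, StrainGrowthProfile]:
    """Profiles per strain from a tidy anchor table
    (strain, temperature_C, r_growth_per_min, t0_min)."""
    profiles = {}
    for strain, grp in growth_table.groupby("strain", sort=False):
        grp = grp.sort_values("temperature_C")
        if grp["temperature_C"].duplicated().any():
            raise ValueError(f"duplicate anchor temperatures for {strain}")
        profiles[strain] = StrainGrowthProfile.from_anchors(
            strain, grp["temperature_C"].to_numpy(),
            grp["r_growth_per_min"].to_numpy(), grp["t0_min"].to_numpy())
    return profiles


def closed_form_population(n0: float, t0: float, r: float, t) -> np.ndarray:
    """Lag + exponential population density at time(s) t (minutes)."""
    if n0 < 0:
        raise ValueError("initial density must be non-negative")
    t = np.asarray(t, dtype=float)
    return np.where(t <= t0, n0, n0 * np.exp(r * np.maximum(t - t0, 0.0)))


def growth_rate_at(profile: StrainGrowthProfile, T, t: float,
                   penalty: PenaltyModel | None = None,
                   speed_ul_s: float = 0.0):
    """Realized growth rate r(T, t): zero during lag, penalized r_growth after.

    The lag test is wall-clock against the (penalized) lag length at the
    current temperature.
    """
    if penalty is None:
        penalty = PenaltyModel.none()
    rate = profile.rate(T) * penalty.rate_factor(profile.strain_id, speed_ul_s)
    lag = profile.lag(T) + penalty.lag_shift_min(profile.strain_id, speed_ul_s)
    return np.where(t > lag, np.maximum(rate, 0.0), 0.0)


def _sse(times, densities, n0, t0, r):
    return float(np.sum((closed_form_population(n0, t0, r, times) - densities) ** 2))


def _best_rate_given_lag(times, densities, n0, t0):
    """r minimizing SSE for fixed t0, by 1-D bounded search.

    On the density scale the problem is nonlinear in r; a log-linear fit of
    the post-lag points seeds a bounded refinement.
    """
    post = times > t0
    if post.sum() == 0:
        return 0.0
    dt = times[post] - t0
    with np.errstate(divide="ignore"):
        logs = np.log(np.maximum(densities[post] / n0, 1e-300))
    r0 = max(float(np.sum(dt * logs) / np.sum(dt * dt)), 0.0)
    hi = max(4.0 * r0, 0.1)
    res = minimize_scalar(lambda r: _sse(times, densities, n0, t0, max(r, 0.0)),
                          bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-12})
    return max(float(res.x), 0.0)


def fit_growth_parameters(times, densities, n0: float) -> tuple[float, float, bool]:
    """Least-squares fit of (t0, r_growth) to an observed density series.

    Minimizes the sum of squared errors of the lag+exponential model on the
    density scale: a coarse search over candidate lags on the observation
    grid is refined continuously with a bounded scalar optimization per
    inter-sample interval.

    Returns (t0_min, r_growth_per_min, flagged); ``flagged`` is True for a
    non-increasing series, which is reported as r=0 with t0 spanning the
    whole series.
    """
    times = np.asarray(times, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if len(times) < 4:
        raise ValueError("need at least 4 time points")
    if np.any(densities <= 0):
        raise ValueError("densities must be positive")
    if densities[-1] <= densities[0]:
        return float(times[-1] - times[0]), 0.0, True

    span = float(times[-1] - times[0])

    def objective(t0):
        t0 = float(np.clip(t0, 0.0, span + times[0]))
        r = _best_rate_given_lag(times, densities, n0, t0)
        return _sse(times, densities, n0, t0, r), r

    # coarse pass: lag candidates on the observation grid
    best = None
    for t0 in times:
        sse, r = objective(t0)
        if best is None or sse < best[0]:
            best = (sse, float(t0), r)
    # continuous refinement around the best grid candidate
    i = int(np.searchsorted(times, best[1]))
    lo = times[max(i - 1, 0)]
    hi = times[min(i + 1, len(times) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda t0: objective(t0)[0], bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-10})
        sse, r = objective(float(res.x))
        if sse < best[0]:
            best = (sse, float(res.x), r)
    return best[1], best[2], False
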