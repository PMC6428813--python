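"""Statistical classification of a circulation speed.

A speed is *homogeneous* when BC-within is significantly higher than
BC-across (the vessels resemble each other more than they resemble their
no-dispersal counterparts), *heterogeneous* when significantly lower, and
*transition* when the two metrics are statistically indistinguishable.

The primary engine is a linear mixed-effects model (value ~ metric with a
random intercept per time point) whose Wald test on the metric effect
yields the p-value; p-values are Bonferroni-corrected for the number of
speeds scanned.  A seed-fixed block-permutation test (metric labels
shuffled within time-point blocks) is bundled as an independent engine; it
is also the automatic fallback when the mixed model cannot be fit, e.g.
when residual variance degenerates at the extremes of the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["SpeedClassification", "classify_speed", "permutation_pvalue"]

LABELS = ("heterogeneous", "transition", "homogeneous")


@dataclass(frozen=True)
class SpeedClassification:
    speed_ul_s: float
    effect: float                 # mean(within) - mean(across), % points
    statistic: float              # z of the mixed model, or the permutation
    p_value: float                # raw two-sided p            # statistic
    p_corrected: float            # Bonferroni-corrected
    label: str
    n_within: int
    n_across: int
    engine: str                   # "mixedlm" or "permutation"
    degenerate: bool = False


def _block_permutation(values: np.ndarray, is_within: np.ndarray,
                       blocks: np.ndarray, n_permutations: int,
                       rng: np.random.Generator) -> tuple[float, float]:
    """Two-sided p for mean(within)-mean(across), permuting within blocks."""
    def stat(labels):
        return values[labels].mean() - values[~labels].mean()

    observed = stat(is_within)
    unique_blocks = np.unique(blocks)
    block_idx = [np.flatnonzero(blocks == b) for b in unique_blocks]
    count = 0
    labels = is_within.copy()
    for _ in range(n_permutations):
        for idx in block_idx:
            labels[idx] = rng.permutation(labels[idx])
        if abs(stat(labels)) >= abs(observed) - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return observed, p


def permutation_pvalue(within: pd.DataFrame, across: pd.DataFrame,
                       n_permutations: int = 4000,
                       seed: int = 0) -> tuple[float, float]:
    """Block-permutation test of BC-within vs BC-across.

    Returns (effect, two-sided p).  Metric labels are shuffled only among
    samples from the same time point, preserving the time structure.
    """
    values = np.concatenate([within["value_pct"].to_numpy(float),
                             across["value_pct"].to_numpy(float)])
    is_within = np.concatenate([np.ones(len(within), bool),
                                np.zeros(len(across), bool)])
    blocks = np.concatenate([within["time_min"].to_numpy(float),
                             across["time_min"].to_numpy(float)])
    rng = np.random.default_rng(seed)
    return _block_permutation(values, is_within, blocks, n_permutations, rng)


def _mixedlm(within: pd.DataFrame, across: pd.DataFrame):
    df = pd.concat([within, across], ignore_index=True)[
        ["metric", "time_min", "value_pct"]]
    df["metric"] = pd.Categorical(df["metric"],
                                  categories=["across", "within"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value_pct ~ metric", df, groups=df["time_min"])
        fit = model.fit(reml=True)
    coef = float(fit.params["metric[T.within]"])
    z = float(fit.tvalues["metric[T.within]"])
    p = float(fit.pvalues["metric[T.within]"])
    if not (np.isfinite(z) and np.isfinite(p)):
        raise ValueError("mixed model produced non-finite statistics")
    return coef, z, p


def classify_speed(within: pd.DataFrame, across: pd.DataFrame,
                   alpha: float = 0.05, n_tests: int = 1,
                   engine: str = "auto", seed: int = 0,
                   n_permutations: int = 4000) -> SpeedClassification:
    """Label one circulation speed from its BC-within / BC-across samples.

    ``within`` and ``across`` are tidy sample frames as produced by
    :func:`dispersim.metrics.bc_within` / ``bc_across``.  ``n_tests`` is
    the Bonferroni family size (the number of speeds in the scan).
    ``engine``: "mixedlm", "permutation", or "auto" (mixed model with
    permutation fallback).
    """
    if len(within) == 0 or len(across) == 0:
        raise ValueError("need samples for both metrics")
    speed = float(within["speed_ul_s"].iloc[0]) if "speed_ul_s" in within else float("nan")
    values = np.concatenate([within["value_pct"].to_numpy(float),
                             across["value_pct"].to_numpy(float)])
    effect = float(within["value_pct"].mean() - across["value_pct"].mean())

    if np.ptp(values) < 1e-12:
        return SpeedClassification(speed, 0.0, 0.0, 1.0, 1.0, "transition",
                                   len(within), len(across), "degenerate",
                                   degenerate=True)

    used = engine
    if engine in ("auto", "mixedlm"):
        try:
            coef, z, p = _mixedlm(within, across)
            effect_stat, statistic, p_value = coef, z, p
            used = "mixedlm"
        except Exception:
            if engine == "mixedlm":
                raise
            used = "permutation"
    if used == "permutation":
        effect_stat, p_value = permutation_pvalue(within, across,
                                                  n_permutations, seed)
        statistic = effect_stat

    p_corr = min(1.0, p_value * max(n_tests, 1))
    if p_corr < alpha:
        label = "homogeneous" if effect_stat > 0 else "heterogeneous"
    else:
        label = "transition"
    return SpeedClassification(speed, effect, float(statistic),
                               float(p_value), float(p_corr), label,
                               len(within), len(across), used)
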