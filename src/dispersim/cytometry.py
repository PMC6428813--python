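"""Gate-count spillover deconvolution for stain-free flow cytometry.

Each strain owns a non-overlapping "representative" gate in the forward/
side-scatter plane.  In a mixed culture, the events observed in a gate are
the owning strain's representative population plus spillover from the other
strains.  With spillover ratios S_a/b (events of strain ``a`` landing in the
gate of strain ``b``, expressed relative to ``a``'s own representative
population) the observation model is linear:

    observed_b = repr_b + sum_{a != b} S_a/b * repr_a

Solving this small linear system per sample recovers the representative
populations; dividing by the capture fraction (share of a pure culture's
total events inside its own gate) and the sampled volume converts them to
absolute densities in cells/ul.

Spillover ratios below a small threshold (default 0.0025) are treated as
zero, i.e. the corresponding term is omitted from the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateGateError",
    "SpilloverMatrix",
    "SpilloverSeries",
    "compute_spillover_ratio",
    "deconvolve_gate_counts",
    "to_total_density",
    "blank_correct",
    "OMIT_THRESHOLD",
]

#: spillover ratios below this are omitted from the linear system
OMIT_THRESHOLD = 0.0025

#: condition numbers above this flag the system as ill-conditioned
CONDITION_LIMIT = 1e8


class DegenerateGateError(ValueError):
    """Raised when a gate holds no events and a ratio is undefined."""


def compute_spillover_ratio(events_in_other_gate: float,
                            events_in_own_gate: float) -> float:
    """Spillover ratio of a strain into another strain's gate.

    Both arguments may be raw counts or percentages of total events; only
    their ratio matters.  E.g. a pure culture with 76.9% of its events in
    its own gate and 1.3% in a neighbour's has a spillover ratio of
    1.3/76.9 = 0.0169 into that neighbour.
    """
    if events_in_own_gate <= 0:
        raise DegenerateGateError("own-gate events must be positive")
    if events_in_other_gate < 0:
        raise ValueError("event counts must be non-negative")
    return events_in_other_gate / events_in_own_gate


@dataclass(frozen=True)
class SpilloverMatrix:
    """Pairwise spillover ratios and capture fractions for a strain panel.

    ``ratios`` maps ordered pairs (source_strain, target_gate) to S_a/b;
    missing pairs are zero.  ``capture_fractions`` maps each strain to the
    share of its pure-culture events inside its own gate.  ``time_min``
    optionally records the sampling time the ratios were drawn at (gates
    drift as cells grow, so spillover is tabulated per time point).
    """

    strains: tuple[str, ...]
    ratios: dict[tuple[str, str], float]
    capture_fractions: dict[str, float] = field(default_factory=dict)
    time_min: float | None = None

    def __post_init__(self) -> None:
        for (a, b), s in self.ratios.items():
            if a == b:
                raise ValueError("diagonal spillover entries are implicit")
            if not 0.0 <= s < 1.0:
                raise ValueError(f"spillover S_{a}/{b}={s} outside [0, 1)")
        for s, c in self.capture_fractions.items():
            if not 0.0 < c <= 1.0:
                raise ValueError(f"capture fraction of {s} outside (0, 1]")

    def mixing_matrix(self, omit_threshold: float = OMIT_THRESHOLD) -> np.ndarray:
        """Matrix M with observed = M @ representative.

        M[b, a] = S_a/b for a != b (zero when below ``omit_threshold``),
        and 1 on the diagonal.
        """
        n = len(self.strains)
        M = np.eye(n)
        idx = {s: i for i, s in enumerate(self.strains)}
        for (a, b), s in self.ratios.items():
            if s >= omit_threshold:
                M[idx[b], idx[a]] = s
        return M

    def capture_vector(self) -> np.ndarray:
        return np.array([self.capture_fractions.get(s, 1.0) for s in self.strains])


@dataclass(frozen=True)
class SpilloverSeries:
    """Time-indexed spillover matrices with nearest-time lookup."""

    matrices: tuple[SpilloverMatrix, ...]

    def at(self, time_min: float) -> SpilloverMatrix:
        times = np.array([m.time_min for m in self.matrices], dtype=float)
        if np.isnan(times).any():
            raise ValueError("all matrices in a series need a time_min")
        return self.matrices[int(np.argmin(np.abs(times - time_min)))]


def deconvolve_gate_counts(observed, spillover: SpilloverMatrix,
                           omit_threshold: float = OMIT_THRESHOLD):
    """Recover representative populations from observed gate counts.

    Parameters
    ----------
    observed : array-like, shape (n_strains,) or (n_samples, n_strains)
        Blank-corrected events per representative gate, ordered as
        ``spillover.strains``.
    spillover : SpilloverMatrix
    omit_threshold : float
        Ratios below this are dropped from the system.

    Returns
    -------
    representative : ndarray, same shape as ``observed``
        Solutions, with negative components clamped to zero.
    flags : dict with ``clamped`` (boolean mask of clamped entries) and
        ``condition_number`` of the mixing matrix.

    Raises
    ------
    np.linalg.LinAlgError if the mixing matrix is singular or its condition
    number exceeds ``CONDITION_LIMIT``.
    """
    obs = np.asarray(observed, dtype=float)
    M = spillover.mixing_matrix(omit_threshold)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            f"spillover system ill-conditioned (cond={cond:.3g})")
    sol = np.linalg.solve(M, obs.T).T
    clamped = sol < 0
    sol = np.where(clamped, 0.0, sol)
    return sol, {"clamped": clamped, "condition_number": cond}


def to_total_density(representative_counts, capture_fraction, volume_ul):
    """Convert representative gate counts to absolute density (cells/ul).

    density = representative / (capture_fraction * volume).
    """
    capture = np.asarray(capture_fraction, dtype=float)
    if np.any(capture <= 0):
        raise ValueError("capture fraction must be positive")
    if np.any(np.asarray(volume_ul, dtype=float) <= 0):
        raise ValueError("sample volume must be positive")
    return np.asarray(representative_counts, dtype=float) / (capture * volume_ul)


def blank_correct(counts, blank_counts):
    """Subtract sterile-medium background per gate, clamping at zero."""
    return np.maximum(np.asarray(counts, dtype=float)
                      - np.asarray(blank_counts, dtype=float), 0.0)


def densities_from_table(table: pd.DataFrame, spillover: SpilloverMatrix,
                         blank: pd.Series | None = None,
                         omit_threshold: float = OMIT_THRESHOLD) -> pd.DataFrame:
    """Full pipeline on a tidy gate-count table.

    ``table`` has columns (sample_id, gate, events, volume_ul); ``blank``
    optionally maps gate -> background events to subtract per sample.
    Returns a tidy frame (sample_id, strain, cells_per_ul).
    """
    out = []
    for sample_id, grp in table.groupby("sample_id", sort=False):
        counts = grp.set_index("gate")["events"].reindex(list(spillover.strains))
        if counts.isna().any():
            raise ValueError(f"sample {sample_id} missing gates")
        volume = float(grp["volume_ul"].iloc[0])
        vals = counts.to_numpy(dtype=float)
        if blank is not None:
            vals = blank_correct(vals, blank.reindex(list(spillover.strains)).to_numpy())
        repr_counts, _ = deconvolve_gate_counts(vals, spillover, omit_threshold)
        dens = to_total_density(repr_counts, spillover.capture_vector(), volume)
        for strain, d in zip(spillover.strains, dens):
            out.append((sample_id, strain, d))
    return pd.DataFrame(out, columns=["sample_id", "strain", "cells_per_ul"])
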