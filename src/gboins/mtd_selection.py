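"""Isotonic smoothing of per-dose toxicity means and final MTD selection.

Observed per-dose means are not guaranteed monotone in dose, so before
selecting the maximum tolerated dose they are replaced by their weighted
isotonic regression (pooled adjacent violators), with per-dose sample
sizes as weights.  The MTD is the dose whose smoothed mean is closest to
the target; ties below the target resolve to the highest tied dose, ties
above to the lowest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class IsotonicFit:
    raw_means: tuple[float, ...]
    weights: tuple[float, ...]
    fitted: tuple[float, ...]


def pava(means: Sequence[float], weights: Sequence[float]) -> IsotonicFit:
    """Weighted least-squares isotonic (non-decreasing) fit via PAVA."""
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if means.size == 0:
        raise ValueError("pava requires at least one dose with data")
    if means.shape != weights.shape:
        raise ValueError("means and weights must have the same length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive (exclude empty doses)")
    x = np.arange(means.size)
    fitted = IsotonicRegression(increasing=True).fit_transform(
        x, means, sample_weight=weights
    )
    return IsotonicFit(
        raw_means=tuple(means.tolist()),
        weights=tuple(weights.tolist()),
        fitted=tuple(float(v) for v in fitted),
    )


def select_mtd(state, phi0: float) -> int | None:
    """Choose the MTD from a completed trial's state; None if no dose qualifies.

    Only admissible doses with at least one treated patient enter the
    isotonic fit.  Among doses whose smoothed mean is closest to the
    target: all below the target -> highest dose; all above -> lowest; an
    equidistant straddle -> the lower dose (safety preference).
    """
    if state.terminated:
        return None
    eligible = [
        j
        for j, d in enumerate(state.doses)
        if state.admissible[j] and d.n >= 1
    ]
    if not eligible:
        return None
    fit = pava(
        [state.doses[j].mean for j in eligible],
        [state.doses[j].n for j in eligible],
    )
    dist = [abs(v - phi0) for v in fit.fitted]
    best = min(dist)
    tied = [k for k, d in enumerate(dist) if d <= best + _TIE_TOL]
    values = [fit.fitted[k] for k in tied]
    if all(v < phi0 for v in values):
        pick = tied[-1]
    else:
        # all-above ties and equidistant straddles both resolve low
        pick = tied[0]
    return eligible[pick]
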