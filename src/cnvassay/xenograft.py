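"""Xenograft growth metrics: caliper volume and confluence doubling time.

Tumor volume uses the spheroid caliper approximation
``V = 0.5236 * ((width + length) / 2) ** 3`` (0.5236 ≈ π/6, the sphere built
on the mean diameter).  Doubling time comes from the exponential phase of a
confluence curve: the longest contiguous pre-plateau window whose
log-confluence is linear in time (R² above a threshold) is fit as
``y = A * exp(B t)`` and the doubling time is ``ln 2 / B``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GrowthFit", "NoExponentialPhase", "xenograft_volume", "doubling_time"]

PLATEAU_CONFLUENCE = 95.0
MIN_WINDOW = 4


class NoExponentialPhase(ValueError):
    """Raised when no window of the curve grows exponentially."""


def xenograft_volume(width: float, length: float) -> float:
    """Caliper volume in mm³ from two perpendicular diameters in mm."""
    if width <= 0 or length <= 0:
        raise ValueError("width and length must be positive")
    return 0.5236 * ((width + length) / 2.0) ** 3


@dataclass(frozen=True)
class GrowthFit:
    """Exponential-phase fit of a confluence curve."""

    window: tuple[int, int]  # [start, end) indices into the curve
    A: float
    B: float  # per hour
    r_squared: float
    doubling_time_hours: float


def doubling_time(
    curve: pd.DataFrame,
    r2_min: float = 0.99,
    plateau: float = PLATEAU_CONFLUENCE,
    min_window: int = MIN_WINDOW,
) -> GrowthFit:
    """Doubling time from the longest exponential window of a growth curve.

    ``curve`` has columns ``t`` (hours, strictly increasing) and
    ``confluence`` (percent).  Only points below ``plateau`` are eligible,
    excluding the contact-inhibited top of the curve.  Among windows of at
    least ``min_window`` points whose ln(confluence)-vs-t least squares fit
    reaches R² >= ``r2_min`` with positive slope, the longest (earliest on
    ties) is kept.
    """
    t = curve["t"].to_numpy(float)
    y = curve["confluence"].to_numpy(float)
    if len(t) < 6:
        raise ValueError("need at least 6 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("confluence must be positive")

    eligible = y < plateau
    logy = np.log(y)
    best: tuple[int, int, object] | None = None
    n = len(t)
    for start in range(n):
        if not eligible[start]:
            continue
        stop = start
        while stop < n and eligible[stop]:
            stop += 1
        for end in range(stop, start + min_window - 1, -1):
            if best is not None and end - start <= best[1] - best[0]:
                break
            fit = stats.linregress(t[start:end], logy[start:end])
            r2 = fit.rvalue ** 2 if np.isfinite(fit.rvalue) else 0.0
            if fit.slope > 0 and r2 >= r2_min:
                best = (start, end, fit)
                break
    if best is None:
        raise NoExponentialPhase(
            f"no window of >= {min_window} pre-plateau points with R^2 >= {r2_min}"
        )
    start, end, fit = best
    B = float(fit.slope)
    return GrowthFit(
        window=(start, end),
        A=float(np.exp(fit.intercept)),
        B=B,
        r_squared=float(fit.rvalue ** 2),
        doubling_time_hours=float(np.log(2) / B),
    )
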