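"""Cubic smoothing-spline resampling of sampled log-ratio trajectories.

Sampled profiles are irregular (dense in the first hour, sparse later); all
downstream temporal logic (twofold-crossing timestamps, lag scanning) runs on a
dense minute-resolution grid. Smoothing uses scipy's penalized cubic smoothing
spline; with ``lam=None`` the penalty is chosen automatically by generalized
cross-validation, with ``lam=0`` the spline interpolates the samples exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = ["SmoothProfile", "smooth_and_resample"]


@dataclass
class SmoothProfile:
    source_id: str
    grid: np.ndarray  # minutes, uniform step covering [0, max(times)]
    values: np.ndarray  # smoothed log2 ratios on the grid
    lam: float | None  # penalty actually requested (None = GCV-automatic)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])


def smooth_and_resample(
    times,
    values,
    *,
    source_id: str = "",
    grid_step_min: float = 1.0,
    lam: float | None = None,
) -> SmoothProfile:
    """Fit a cubic smoothing spline to (times, values) and evaluate on a dense grid."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be 1-D and equally long")
    if len(t) < 4:
        raise ValueError("at least 4 timepoints are required for spline smoothing")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    spline = make_smoothing_spline(t, y, lam=lam)
    n = int(np.floor((t[-1] - t[0]) / grid_step_min)) + 1
    grid = t[0] + grid_step_min * np.arange(n)
    return SmoothProfile(source_id=source_id, grid=grid, values=spline(grid), lam=lam)
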