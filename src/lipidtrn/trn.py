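"""Time-lagged inference of transcriptional-regulator influences on modules.

Smoothed regulator (TR) and module-mean trajectories are first divided by their
maximum absolute value, so only the shape of the response matters. For a
candidate lag L (TR leading the module), the distance between TR profile f and
module profile g is the RMS difference between f(t) and g(t + L) over the
overlapping part of the dense grid; scoring against -g as well captures
repression, and the smaller of the two is the pair's distance at that lag. The
best lag is the argmin over a physiological window (15-90 min by default,
ties toward the smaller lag). An edge is emitted when a pair's best distance
falls below the fifth percentile of the pooled distance population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import SmoothProfile

__all__ = [
    "LagWindow",
    "InfluenceEdge",
    "normalize_profile",
    "lagged_distance",
    "best_lag",
    "infer_influences",
    "edges_to_frame",
]

MIN_OVERLAP_POINTS = 10


class DegenerateProfileError(ValueError):
    """An identically-zero profile cannot be max-normalized or scored."""


@dataclass(frozen=True)
class LagWindow:
    min_lag: float = 15.0  # minutes
    max_lag: float = 90.0

    def __post_init__(self) -> None:
        if not (0 < self.min_lag < self.max_lag):
            raise ValueError("need 0 < min_lag < max_lag")


@dataclass(frozen=True)
class InfluenceEdge:
    tr_id: str
    module_id: str
    lag: float  # minutes, TR leads module
    distance: float
    sign: str  # 'activation' | 'repression'


def normalize_profile(sp: SmoothProfile) -> SmoothProfile:
    """Divide by the maximum absolute value; output values lie in [-1, 1]."""
    scale = float(np.max(np.abs(sp.values)))
    if scale == 0:
        raise DegenerateProfileError(f"profile {sp.source_id!r} is identically zero")
    return SmoothProfile(sp.source_id, sp.grid, sp.values / scale, sp.lam)


def _lag_to_shift(lag: float, step: float) -> int:
    shift = int(round(lag / step))
    if abs(shift * step - lag) > 1e-9:
        raise ValueError(f"lag {lag} is not a multiple of the grid step {step}")
    return shift


def _check_aligned(tr: SmoothProfile, mod: SmoothProfile) -> None:
    if len(tr.grid) != len(mod.grid) or abs(tr.step - mod.step) > 1e-12:
        raise ValueError("TR and module profiles must share the same dense grid")


def lagged_distance(tr: SmoothProfile, mod: SmoothProfile, lag: float) -> tuple[float, str]:
    """RMS distance between tr(t) and mod(t + lag) over the overlap, best of +/- module."""
    _check_aligned(tr, mod)
    shift = _lag_to_shift(lag, tr.step)
    n = len(tr.grid) - shift
    if n < MIN_OVERLAP_POINTS:
        raise ValueError(f"overlap of {n} grid points is below {MIN_OVERLAP_POINTS}")
    f = tr.values[:n]
    g = mod.values[shift:]
    d_act = float(np.sqrt(np.mean((f - g) ** 2)))
    d_rep = float(np.sqrt(np.mean((f + g) ** 2)))
    if d_act <= d_rep:
        return d_act, "activation"
    return d_rep, "repression"


def _lag_grid(window: LagWindow, step: float, lag_step: float) -> np.ndarray:
    lags = np.arange(
        np.ceil(window.min_lag / lag_step) * lag_step,
        window.max_lag + 0.5 * lag_step,
        lag_step,
    )
    return lags[(lags >= window.min_lag) & (lags <= window.max_lag)]


def best_lag(
    tr: SmoothProfile,
    mod: SmoothProfile,
    window: LagWindow = LagWindow(),
    lag_step: float = 1.0,
) -> tuple[float, float, str]:
    """Argmin of lagged_distance over the window; ties go to the smallest lag."""
    best = None
    for lag in _lag_grid(window, tr.step, lag_step):
        d, sign = lagged_distance(tr, mod, float(lag))
        if best is None or d < best[1] - 1e-15:
            best = (float(lag), d, sign)
    if best is None:
        raise ValueError("empty lag window on this grid")
    return best


def _distance_matrix_at_lag(tr_mat: np.ndarray, mod_mat: np.ndarray, shift: int):
    """Pairwise activation/repression RMS distances for one integer grid shift."""
    n = tr_mat.shape[1] - shift
    f = tr_mat[:, :n]
    g = mod_mat[:, shift:]
    f2 = np.einsum("ij,ij->i", f, f)[:, None]
    g2 = np.einsum("ij,ij->i", g, g)[None, :]
    cross = f @ g.T
    d_act = np.sqrt(np.maximum(f2 + g2 - 2 * cross, 0.0) / n)
    d_rep = np.sqrt(np.maximum(f2 + g2 + 2 * cross, 0.0) / n)
    return d_act, d_rep


def infer_influences(
    tr_profiles: dict[str, SmoothProfile],
    module_profiles: dict[str, SmoothProfile],
    *,
    window: LagWindow = LagWindow(),
    lag_step: float = 1.0,
    percentile: float = 5.0,
    pool: str = "best",
) -> list[InfluenceEdge]:
    """Score every (TR, module) pair and threshold at the distance percentile.

    ``pool`` selects the population the percentile is taken over: ``'best'``
    (default) pools the per-pair best distances, ``'all'`` pools every
    (pair, lag) distance inside the window.
    """
    if pool not in ("best", "all"):
        raise ValueError("pool must be 'best' or 'all'")
    tr_ids, mod_ids = [], []
    tr_rows, mod_rows = [], []
    for tid in sorted(tr_profiles):
        try:
            tr_rows.append(normalize_profile(tr_profiles[tid]).values)
            tr_ids.append(tid)
        except DegenerateProfileError:
            warnings.warn(f"TR {tid!r} has an identically-zero profile; skipped")
    for mid in sorted(module_profiles):
        mod_rows.append(normalize_profile(module_profiles[mid]).values)
        mod_ids.append(mid)
    if not tr_ids or not mod_ids:
        if not tr_ids:
            warnings.warn("no scorable TR profiles; returning an empty edge list")
        return []

    any_tr = tr_profiles[tr_ids[0]]
    any_mod = module_profiles[mod_ids[0]]
    _check_aligned(any_tr, any_mod)
    step = any_tr.step
    tr_mat = np.asarray(tr_rows)
    mod_mat = np.asarray(mod_rows)

    lags = _lag_grid(window, step, lag_step)
    best_d = np.full((len(tr_ids), len(mod_ids)), np.inf)
    best_lag_arr = np.zeros_like(best_d)
    best_sign = np.zeros(best_d.shape, dtype=int)  # +1 activation, -1 repression
    pooled_all = []
    for lag in lags:
        shift = _lag_to_shift(float(lag), step)
        d_act, d_rep = _distance_matrix_at_lag(tr_mat, mod_mat, shift)
        sign = np.where(d_act <= d_rep, 1, -1)
        d = np.minimum(d_act, d_rep)
        if pool == "all":
            pooled_all.append(np.concatenate([d_act.ravel(), d_rep.ravel()]))
        better = d < best_d - 1e-15  # strict: ties keep the earlier (smaller) lag
        best_d = np.where(better, d, best_d)
        best_lag_arr = np.where(better, lag, best_lag_arr)
        best_sign = np.where(better, sign, best_sign)

    population = np.concatenate(pooled_all) if pool == "all" else best_d.ravel()
    threshold = float(np.percentile(population, percentile))
    edges = []
    for i, tid in enumerate(tr_ids):
        for j, mid in enumerate(mod_ids):
            if best_d[i, j] < threshold:
                edges.append(
                    InfluenceEdge(
                        tr_id=tid,
                        module_id=mid,
                        lag=float(best_lag_arr[i, j]),
                        distance=float(best_d[i, j]),
                        sign="activation" if best_sign[i, j] > 0 else "repression",
                    )
                )
    edges.sort(key=lambda e: (e.tr_id, e.module_id))
    return edges


def edges_to_frame(edges: list[InfluenceEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tr_id": e.tr_id,
                "module_id": e.module_id,
                "lag_min": e.lag,
                "distance": e.distance,
                "sign": e.sign,
            }
            for e in edges
        ],
        columns=["tr_id", "module_id", "lag_min", "distance", "sign"],
    )
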