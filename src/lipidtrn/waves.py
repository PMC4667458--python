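"""Temporal ordering of co-regulated modules into transcriptional waves.

A module's temporal profile is the unweighted mean log2 ratio of its member
transcripts, smoothed onto a minute grid. Dynamics are classified as

    monotonic  the profile crosses the twofold threshold and stays beyond it
               (a new steady state) through the end of the time course;
    transient  the profile crosses the threshold but returns within it by the
               final timepoint (back to pre-starvation levels);
    flat       the profile never crosses the threshold (excluded from waves).

Each non-flat module gets a minute-resolution timestamp: the earliest time at
which |smoothed r| exceeds the threshold, refined linearly between grid points.
Modules sharing (dynamics class, direction, timestamp quantized to the sampled
grid point at or before the crossing) form one wave; waves are labeled by that
timestamp and mapped onto early / mid / late response stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import LogRatioMatrix
from .smoothing import SmoothProfile, smooth_and_resample

__all__ = [
    "StageScheme",
    "ModuleDynamics",
    "Wave",
    "module_mean_profile",
    "classify_dynamics",
    "crossing_timestamp",
    "assign_stage",
    "group_into_waves",
    "classify_modules",
]


class NoCrossingError(ValueError):
    """The smoothed profile never exceeds the fold threshold."""


@dataclass(frozen=True)
class StageScheme:
    """Stage boundaries in minutes; upper bounds are closed (18 min is early)."""

    early_end: float = 18.0
    mid_end: float = 60.0
    late_end: float = 480.0


def assign_stage(timestamp: float, scheme: StageScheme = StageScheme()) -> str:
    if timestamp < 0:
        raise ValueError("timestamp must be non-negative")
    if timestamp <= scheme.early_end:
        return "early"
    if timestamp <= scheme.mid_end:
        return "mid"
    # everything after the mid boundary, including > late_end, is a late response
    return "late"


def module_mean_profile(ratios: LogRatioMatrix, member_ids) -> np.ndarray:
    """Unweighted arithmetic mean of the member log-ratio profiles at sampled times."""
    members = [m for m in member_ids if m in ratios.data.index]
    if not members:
        raise ValueError("module has no members present in the log-ratio matrix")
    return ratios.data.loc[members].to_numpy(dtype=float).mean(axis=0)


def _first_crossing_index(values: np.ndarray, fold_threshold: float) -> int | None:
    above = np.abs(values) > fold_threshold
    idx = np.flatnonzero(above)
    return int(idx[0]) if idx.size else None


def classify_dynamics(sp: SmoothProfile, fold_threshold: float = 1.0) -> tuple[str, str | None]:
    """Return (class, direction) with class in {monotonic, transient, flat}."""
    i = _first_crossing_index(sp.values, fold_threshold)
    if i is None:
        return "flat", None
    direction = "up" if sp.values[i] > 0 else "down"
    returned = abs(sp.values[-1]) < fold_threshold
    return ("transient" if returned else "monotonic"), direction


def crossing_timestamp(sp: SmoothProfile, fold_threshold: float = 1.0) -> float:
    """Earliest grid time with |r| > threshold, linearly refined between grid points."""
    i = _first_crossing_index(sp.values, fold_threshold)
    if i is None:
        raise NoCrossingError(f"profile {sp.source_id!r} never exceeds {fold_threshold}")
    if i == 0:
        return float(sp.grid[0])
    a, b = abs(sp.values[i - 1]), abs(sp.values[i])
    frac = (fold_threshold - a) / (b - a) if b > a else 1.0
    return float(sp.grid[i - 1] + frac * (sp.grid[i] - sp.grid[i - 1]))


@dataclass
class ModuleDynamics:
    module_id: str
    dynamics: str  # monotonic | transient | flat
    direction: str | None
    timestamp: float | None  # minutes; None for flat modules
    profile: SmoothProfile


def classify_modules(
    ratios: LogRatioMatrix,
    assignment: dict[str, set[str] | list[str]],
    *,
    fold_threshold: float = 1.0,
    grid_step_min: float = 1.0,
    lam: float | None = None,
) -> list[ModuleDynamics]:
    """Mean profile -> smooth -> classify -> timestamp, for every module."""
    out = []
    for module_id in sorted(assignment):
        mean = module_mean_profile(ratios, assignment[module_id])
        sp = smooth_and_resample(
            ratios.times, mean, source_id=module_id, grid_step_min=grid_step_min, lam=lam
        )
        dyn, direction = classify_dynamics(sp, fold_threshold)
        ts = crossing_timestamp(sp, fold_threshold) if dyn != "flat" else None
        out.append(ModuleDynamics(module_id, dyn, direction, ts, sp))
    return out


@dataclass
class Wave:
    wave_id: str
    dynamics: str
    direction: str
    timestamp: float  # minutes: first twofold crossing of the member-mean profile
    stage: str
    module_ids: list[str]
    n_transcripts: int
    mean_profile: SmoothProfile | None = field(default=None, repr=False)


def _quantize(timestamp: float, sampled_times: np.ndarray) -> float:
    """Sampled grid point at or before the crossing (waves sharing it are merged)."""
    idx = np.searchsorted(sampled_times, timestamp, side="right") - 1
    return float(sampled_times[max(idx, 0)])


def group_into_waves(
    modules: list[ModuleDynamics],
    ratios: LogRatioMatrix,
    assignment: dict,
    *,
    fold_threshold: float = 1.0,
    grid_step_min: float = 1.0,
    lam: float | None = None,
    scheme: StageScheme = StageScheme(),
) -> list[Wave]:
    """Partition classified (non-flat) modules into timestamp-ordered waves.

    The wave timestamp and mean profile are recomputed over the union of member
    transcripts, so it is the crossing of the wave's own mean trajectory that is
    reported, not an average of module timestamps.
    """
    groups: dict[tuple, list[ModuleDynamics]] = {}
    sampled = ratios.times
    for md in modules:
        if md.dynamics == "flat":
            continue
        key = (md.dynamics, md.direction, _quantize(md.timestamp, sampled))
        groups.setdefault(key, []).append(md)

    waves = []
    for (dyn, direction, qts) in sorted(groups, key=lambda k: (k[2], k[0], k[1])):
        members = groups[(dyn, direction, qts)]
        module_ids = sorted(md.module_id for md in members)
        transcripts = sorted(set().union(*(set(assignment[m]) for m in module_ids)))
        mean = module_mean_profile(ratios, transcripts)
        sp = smooth_and_resample(
            sampled, mean, source_id="|".join(module_ids), grid_step_min=grid_step_min, lam=lam
        )
        try:
            ts = crossing_timestamp(sp, fold_threshold)
        except NoCrossingError:
            # averaging across modules can dilute the crossing; fall back to the
            # earliest member-module timestamp so the wave keeps its schedule
            ts = min(md.timestamp for md in members)
        waves.append(
            Wave(
                wave_id="",
                dynamics=dyn,
                direction=direction,
                timestamp=ts,
                stage=assign_stage(ts, scheme),
                module_ids=module_ids,
                n_transcripts=len(transcripts),
                mean_profile=sp,
            )
        )
    waves.sort(key=lambda w: (w.timestamp, w.dynamics, w.direction))
    for i, w in enumerate(waves, start=1):
        w.wave_id = f"W{i:02d}"
    return waves


def waves_to_frame(waves: list[Wave]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "wave_id": w.wave_id,
                "class": w.dynamics,
                "direction": w.direction,
                "timestamp_min": w.timestamp,
                "stage": w.stage,
                "module_ids": ",".join(w.module_ids),
                "n_transcripts": w.n_transcripts,
            }
            for w in waves
        ]
    )
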