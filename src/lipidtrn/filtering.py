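"""Differential-regulation filter for starvation time courses.

For each transcript the log2 expression ratio against the pre-starvation
reference is

    r_i(t) = log2((x_i(t) + 1) / (x_i(0) + 1))

with x in FPKM and a +1 pseudocount on the FPKM scale. A transcript is retained
when either of two rules fires:

rule 1  |r| exceeds the fold threshold at the lipid-accumulation timepoints
        (8, 12, 24 and 48 h by default; `lipid_rule_mode` selects whether all
        of them or any one suffices). Sign consistency across those timepoints
        is not required, but is recorded in the report.
rule 2  |r| exceeds the threshold with constant sign over a run of consecutive
        sampled timepoints whose span (last - first) is at least `min_period`
        minutes. A single isolated timepoint never qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, LogRatioMatrix, ValidationError

__all__ = ["FilterConfig", "FilterReport", "compute_log_ratios", "filter_transcripts"]

DEFAULT_LIPID_TIMEPOINTS = (480.0, 720.0, 1440.0, 2880.0)


@dataclass
class FilterConfig:
    fold_threshold: float = 1.0  # log2 units, strict inequality
    lipid_timepoints: tuple[float, ...] = DEFAULT_LIPID_TIMEPOINTS
    min_period: float = 30.0  # minutes
    lipid_rule_mode: str = "all"  # 'all' or 'any'

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0:
            raise ValidationError("fold_threshold must be > 0")
        if self.min_period <= 0:
            raise ValidationError("min_period must be > 0")
        if self.lipid_rule_mode not in ("all", "any"):
            raise ValidationError("lipid_rule_mode must be 'all' or 'any'")
        self.lipid_timepoints = tuple(float(t) for t in self.lipid_timepoints)


@dataclass
class FilterReport:
    """Per-transcript retention decision with the rule trace."""

    table: pd.DataFrame  # index transcript_id; kept, rule, first_pass_time_min, rule1_sign_consistent
    config: FilterConfig = field(default_factory=FilterConfig)

    @property
    def kept(self) -> set[str]:
        return set(self.table.index[self.table["kept"]])

    def rule_for(self, transcript_id: str) -> str:
        return str(self.table.loc[transcript_id, "rule"])

    def to_tsv(self, path) -> None:
        cfg = self.config
        header = [
            f"fold_threshold = {cfg.fold_threshold:g}",
            f"lipid_timepoints = {','.join(f'{t:g}' for t in cfg.lipid_timepoints)}",
            f"min_period = {cfg.min_period:g}",
            f"lipid_rule_mode = {cfg.lipid_rule_mode}",
        ]
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", float_format="%.10g")


def compute_log_ratios(expr: ExpressionMatrix) -> LogRatioMatrix:
    """Element-wise log2((x_t + 1)/(x_0 + 1)); the +1 pseudocount keeps ratios finite."""
    x = expr.values
    if expr.times[0] != 0:
        raise ValidationError("reference sample at t = 0 is required")
    ratios = np.log2((x + 1.0) / (x[:, [0]] + 1.0))
    df = pd.DataFrame(ratios, index=expr.data.index, columns=expr.data.columns)
    return LogRatioMatrix(df)


def _rule1(row: np.ndarray, lipid_idx: np.ndarray, cfg: FilterConfig):
    vals = row[lipid_idx]
    exceed = np.abs(vals) > cfg.fold_threshold
    fired = exceed.all() if cfg.lipid_rule_mode == "all" else exceed.any()
    if not fired:
        return False, np.nan, False
    first_time = float(np.asarray(cfg.lipid_timepoints)[exceed][0])
    signs = np.sign(vals[exceed])
    return True, first_time, bool(np.all(signs == signs[0]))


def _rule2(row: np.ndarray, times: np.ndarray, cfg: FilterConfig):
    # consecutive sampled timepoints, same sign, |r| > threshold, span >= min_period
    state = np.where(row > cfg.fold_threshold, 1, np.where(row < -cfg.fold_threshold, -1, 0))
    start = 0
    for i in range(1, len(state) + 1):
        if i == len(state) or state[i] != state[start]:
            if state[start] != 0 and times[i - 1] - times[start] >= cfg.min_period:
                return True, float(times[start])
            start = i
    return False, np.nan


def filter_transcripts(ratios: LogRatioMatrix, cfg: FilterConfig | None = None) -> FilterReport:
    cfg = cfg or FilterConfig()
    times = ratios.times
    if ratios.data.shape[0] == 0:
        raise ValidationError("empty log-ratio matrix")
    missing = [t for t in cfg.lipid_timepoints if t not in set(times)]
    if missing:
        raise ValidationError(f"lipid timepoints absent from the time axis: {missing}")
    lipid_idx = np.array([int(np.where(times == t)[0][0]) for t in cfg.lipid_timepoints])

    records = []
    for tid, row in zip(ratios.transcript_ids, ratios.values):
        r1, t1, consistent = _rule1(row, lipid_idx, cfg)
        r2, t2 = _rule2(row, times, cfg)
        rule = {(False, False): "none", (True, False): "1", (False, True): "2", (True, True): "both"}[(r1, r2)]
        first = np.nanmin([t1, t2]) if (r1 or r2) else np.nan
        records.append((tid, r1 or r2, rule, first, consistent))
    table = pd.DataFrame.from_records(
        records,
        columns=["transcript_id", "kept", "rule", "first_pass_time_min", "rule1_sign_consistent"],
    ).set_index("transcript_id")
    return FilterReport(table=table, config=cfg)
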