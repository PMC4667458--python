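"""Expression-matrix containers and TSV input/output.

The pipeline operates on a transcript x timepoint matrix of FPKM values with a
minute-valued time axis whose first sample (t = 0) is the pre-starvation
reference, and on the derived matrix of log2 expression ratios against that
reference. Both are thin wrappers around a pandas DataFrame (rows = transcript
ids, columns = integer minutes) that enforce the structural invariants every
downstream stage relies on.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LogRatioMatrix",
    "read_expression_tsv",
    "read_expression_long_tsv",
]


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _validate_axes(data: pd.DataFrame, *, require_zero_start: bool = True) -> pd.DataFrame:
    if data.shape[1] < 3:
        raise ValidationError("at least 3 timepoints are required")
    times = np.asarray(data.columns, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("time axis must be strictly increasing")
    if require_zero_start and times[0] != 0:
        raise ValidationError(
            "first timepoint must be 0 min (the pre-starvation reference sample)"
        )
    if data.index.duplicated().any():
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate transcript ids: {dups[:5]}")
    data = data.copy()
    data.columns = times
    return data


@dataclass
class ExpressionMatrix:
    """FPKM values, rows = transcripts, columns = minutes since starvation onset."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_axes(self.data)
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite FPKM values")
        if (values < 0).any():
            raise ValidationError("negative FPKM values are not allowed")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        write_matrix_tsv(self.data, path)


@dataclass
class LogRatioMatrix:
    """log2((x_t + 1) / (x_0 + 1)) per transcript; the t = 0 column is identically 0."""

    data: pd.DataFrame
    _zero_tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        self.data = _validate_axes(self.data)
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("log ratios must be finite")
        if np.abs(values[:, 0]).max(initial=0.0) > self._zero_tol:
            raise ValidationError("log-ratio column at t = 0 must be 0")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def profile(self, transcript_id: str) -> np.ndarray:
        return self.data.loc[transcript_id].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        write_matrix_tsv(self.data, path)


def _format_time_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out.columns = [f"{t:g}" for t in df.columns]
    out.index.name = "transcript_id"
    return out


def write_matrix_tsv(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    buf = _io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    _format_time_columns(df).to_csv(buf, sep="\t")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_matrix_tsv(path) -> pd.DataFrame:
    # round_trip parsing keeps write->read bit-identical
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    df.columns = [float(c) for c in df.columns]
    return df


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a wide-format TSV: first column transcript_id, remaining columns minutes."""
    return ExpressionMatrix(_read_matrix_tsv(path))


def read_log_ratio_tsv(path) -> LogRatioMatrix:
    return LogRatioMatrix(_read_matrix_tsv(path))


def read_expression_long_tsv(path) -> ExpressionMatrix:
    """Read a long-format TSV with columns (transcript_id, time_min, fpkm)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"transcript_id", "time_min", "fpkm"}
    if not expected.issubset(df.columns):
        raise ValidationError(f"long format needs columns {sorted(expected)}")
    wide = df.pivot(index="transcript_id", columns="time_min", values="fpkm")
    wide = wide.sort_index(axis=1)
    if wide.isna().any().any():
        raise ValidationError("long-format input is missing (transcript, time) entries")
    return ExpressionMatrix(wide)
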