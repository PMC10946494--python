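"""Per-sample chemical-shift tables.

A :class:`ShiftTable` is a samples x spin-systems matrix of chemical shifts
(delta, ppm) with missing entries allowed. Shifts are recorded to a fixed
number of decimals (4 by default, matching standard 600 MHz profiling
pipelines); ingest rounds half-even and canonicalizes values so that
read -> write -> read round-trips are bit-identical.
"""

from __future__ import annotations

import csv
import decimal
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ShiftTable",
    "ShiftTableError",
    "ShiftTableFormatError",
    "ShiftTableParseError",
    "read_shift_table",
    "write_shift_table",
    "center_columns",
    "paired_values",
    "quantize_ppm",
]


class ShiftTableError(ValueError):
    pass


class ShiftTableFormatError(ShiftTableError):
    """Structural problem: duplicate ids, empty table..."""


class ShiftTableParseError(ShiftTableError):
    """Unparseable cell; message carries row/column coordinates."""


def quantize_ppm(value: float, precision: int = 4) -> float:
    """Round a float ppm value to `precision` decimals (half-even on the
    stored double) and canonicalize it to the float nearest the decimal
    string, so equal printed values compare equal bitwise."""
    if not np.isfinite(value):
        return float("nan")
    return float(f"{value:.{precision}f}")


def _quantize_str(cell: str, precision: int) -> float:
    # Exact decimal half-even: "0.98605" -> 0.9860.
    q = decimal.Decimal(cell).quantize(
        decimal.Decimal(1).scaleb(-precision), rounding=decimal.ROUND_HALF_EVEN
    )
    return float(q)


@dataclass
class ShiftTable:
    """Samples x spin-systems matrix of chemical shifts in ppm.

    ``data`` is a float DataFrame indexed by sample id with spin-system ids as
    columns; NaN marks a missing (undetected/unassigned) value.
    """

    data: pd.DataFrame
    precision: int = 4

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ShiftTableFormatError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ShiftTableFormatError(f"duplicate spin-system ids: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def systems(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data.index)

    def n_present(self, system_id: str | None = None):
        """Count of present (non-missing) values, per column or for one."""
        counts = self.data.notna().sum()
        if system_id is None:
            return counts
        if system_id not in self.data.columns:
            raise KeyError(f"unknown spin system {system_id!r}")
        return int(counts[system_id])

    def column(self, system_id: str) -> pd.Series:
        if system_id not in self.data.columns:
            raise KeyError(f"unknown spin system {system_id!r}")
        return self.data[system_id]

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        write_shift_table(self, path, sep=sep)


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_shift_table(
    path: str | Path, sep: str | None = None, precision: int = 4
) -> ShiftTable:
    """Read a delimited shift table.

    Header row names spin systems, first column holds sample ids; empty cells
    or ``NA`` are missing. Values are rounded half-even to ``precision``
    decimals on ingest. Columns with no present value at all are dropped with
    a warning (every retained column carries at least one shift).
    """
    path = Path(path)
    sep = _infer_sep(path, sep)
    rows: list[list[str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows[0]) < 2:
        raise ShiftTableFormatError(f"{path}: no spin-system columns found")
    header = [h.strip() for h in rows[0][1:]]
    seen: set[str] = set()
    for h in header:
        if h in seen:
            raise ShiftTableFormatError(f"{path}: duplicate spin-system id {h!r}")
        seen.add(h)

    sample_ids: list[str] = []
    values = np.full((len(rows) - 1, len(header)), np.nan)
    seen_samples: set[str] = set()
    for i, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        sid = row[0].strip()
        if sid in seen_samples:
            raise ShiftTableFormatError(f"{path}: duplicate sample id {sid!r}")
        seen_samples.add(sid)
        sample_ids.append(sid)
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in ("", "NA"):
                continue
            try:
                values[len(sample_ids) - 1, j] = _quantize_str(cell, precision)
            except decimal.InvalidOperation:
                raise ShiftTableParseError(
                    f"{path}: non-numeric value {cell!r} at row {i} "
                    f"(sample {sid!r}), column {header[j]!r}"
                ) from None
    values = values[: len(sample_ids)]
    df = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample"), columns=header)

    empty = [c for c in df.columns if df[c].notna().sum() == 0]
    if empty:
        warnings.warn(
            f"{path}: dropping all-missing columns {empty}", stacklevel=2
        )
        df = df.drop(columns=empty)
    return ShiftTable(df, precision=precision)


def write_shift_table(t: ShiftTable, path: str | Path, sep: str = ",") -> None:
    """Write with fixed decimals and ``NA`` for missing values."""
    t.data.to_csv(
        path, sep=sep, na_rep="NA", float_format=f"%.{t.precision}f",
        index_label="sample",
    )


def center_columns(t: ShiftTable, scale: bool = False) -> ShiftTable:
    """Subtract each spin system's mean shift (missing pattern unchanged).

    Used to put systems with different nominal positions on a common scale for
    plotting/comparing drift ranges. With ``scale=True`` columns are also
    divided by their standard deviation; the default is centering only.
    Centered values are no longer quantized to the table precision.
    """
    if t.data.empty:
        raise ShiftTableError("cannot center an empty table")
    zero = [c for c in t.data.columns if t.data[c].notna().sum() == 0]
    if zero:
        raise ShiftTableError(f"column(s) with no present values: {zero}")
    out = t.data - t.data.mean()
    if scale:
        sd = t.data.std(ddof=0)
        out = out / sd.replace(0.0, np.nan)
    return ShiftTable(out, precision=t.precision)


def paired_values(
    t: ShiftTable, response_id: str, predictor_id: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pairwise-complete observations for one (response, predictor) pair.

    Returns ``(y, x, n)`` keeping only samples where both shifts are present,
    in table sample order. Self-pairs are disallowed.
    """
    if response_id == predictor_id:
        raise ShiftTableError(f"self-pair requested for {response_id!r}")
    y = t.column(response_id)
    x = t.column(predictor_id)
    mask = y.notna() & x.notna()
    yv = y[mask].to_numpy(dtype=float)
    xv = x[mask].to_numpy(dtype=float)
    return yv, xv, int(mask.sum())
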