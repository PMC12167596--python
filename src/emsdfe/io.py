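"""Plant-level data model and delimited-text I/O.

The exchange format between every stage of the pipeline is a flat table with
one row per plant:

``founder_id, line_id, subline_id, block_id, ems_treated, survived, dry_weight_mg``

Dry weight is stored in raw milligrams; a plant that died before harvest has
``survived = False`` and ``dry_weight_mg = 0``.  The log10 transform used by
the statistical model is always computed on the fly (`log10_weight`), never
stored, so a table cannot end up double-transformed.  Controls are ordinary
lines with ``line_id = "control"`` and ``ems_treated = False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "ValidationError",
    "ExperimentTable",
    "read_experiment_table",
    "write_experiment_table",
    "design_counts",
]

REQUIRED_COLUMNS = (
    "founder_id",
    "line_id",
    "subline_id",
    "block_id",
    "ems_treated",
    "survived",
    "dry_weight_mg",
)


class SchemaError(ValueError):
    """The on-disk table is missing required columns."""


class ValidationError(ValueError):
    """Row-level invariants of the plant data model are violated."""


def _as_bool(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].index[:5].tolist()
        raise ValidationError(f"column {name!r} is not boolean at rows {bad}")
    return out.astype(bool)


@dataclass
class ExperimentTable:
    """A validated collection of plant records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; construct
    through :func:`read_experiment_table` or the simulator so the invariants
    have been checked.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df["ems_treated"] = _as_bool(df["ems_treated"], "ems_treated")
        df["survived"] = _as_bool(df["survived"], "survived")
        w = pd.to_numeric(df["dry_weight_mg"], errors="coerce")
        if w.isna().any():
            rows = df.index[w.isna()].tolist()[:10]
            raise ValidationError(f"non-numeric dry_weight_mg at rows {rows}")
        df["dry_weight_mg"] = w.astype(float)
        neg = df.index[w < 0].tolist()
        if neg:
            raise ValidationError(f"negative dry_weight_mg at rows {neg[:10]}")
        dead_nonzero = df.index[(~df["survived"]) & (w != 0)].tolist()
        if dead_nonzero:
            raise ValidationError(
                f"survived=False but dry_weight_mg != 0 at rows {dead_nonzero[:10]}"
            )
        alive_zero = df.index[df["survived"] & (w <= 0)].tolist()
        if alive_zero:
            raise ValidationError(
                f"survived=True but dry_weight_mg <= 0 at rows {alive_zero[:10]}"
            )
        # EMS flag must be constant within a line
        per_line = df.groupby(["founder_id", "line_id"], sort=False)["ems_treated"].nunique()
        mixed = per_line[per_line > 1]
        if len(mixed):
            raise ValidationError(f"line(s) with mixed ems_treated flag: {list(mixed.index)}")

    @property
    def log10_weight(self) -> pd.Series:
        """log10 dry weight (mg) for survivors, NaN for dead plants."""
        w = self.df["dry_weight_mg"].to_numpy(dtype=float)
        out = np.full(len(w), np.nan)
        alive = self.df["survived"].to_numpy(dtype=bool)
        out[alive] = np.log10(w[alive])
        return pd.Series(out, index=self.df.index, name="log10_weight")

    def design_counts(self) -> pd.DataFrame:
        return design_counts(self)

    def equals(self, other: "ExperimentTable") -> bool:
        a = self.df[list(REQUIRED_COLUMNS)].reset_index(drop=True)
        b = other.df[list(REQUIRED_COLUMNS)].reset_index(drop=True)
        if len(a) != len(b):
            return False
        for c in REQUIRED_COLUMNS:
            if c == "dry_weight_mg":
                if not np.array_equal(a[c].to_numpy(), b[c].to_numpy()):
                    return False
            elif not (a[c].astype(str) == b[c].astype(str)).all():
                return False
        return True


def read_experiment_table(
    path: str | Path,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> ExperimentTable:
    """Read a delimited-text plant table and validate it.

    Parameters
    ----------
    path
        File with a header row naming the plant-record fields.
    delimiter
        Field separator, default comma.
    column_map
        Optional mapping ``{file_column: canonical_column}`` for deposits
        whose headers differ from the canonical names.
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip",
                     dtype={"founder_id": str, "line_id": str,
                            "subline_id": str, "block_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    return ExperimentTable(df)


def write_experiment_table(
    table: ExperimentTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write a table as delimited text, re-readable losslessly.

    Floats are serialized with ``repr`` (pandas default), which round-trips
    IEEE doubles exactly.
    """
    table.df[list(REQUIRED_COLUMNS)].to_csv(path, sep=delimiter, index=False)


def design_counts(table: ExperimentTable) -> pd.DataFrame:
    """Number of lines and seedlings per (founder, treatment).

    Treatment is ``"EMS"`` for mutagenized lines and ``"control"`` otherwise.
    """
    df = table.df.copy()
    df["treatment"] = np.where(df["ems_treated"], "EMS", "control")
    out = (
        df.groupby(["founder_id", "treatment"], sort=False)
        .agg(n_lines=("line_id", "nunique"), n_seedlings=("line_id", "size"))
        .reset_index()
    )
    return out
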