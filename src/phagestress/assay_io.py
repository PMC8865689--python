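"""Reading, validating and writing the raw-data and result tables.

Two raw inputs exist: plaque-count tables (one row per plate: sample
metadata, serial-dilution exponent, plated volume, plaque count) and
plate-reader OD600 time series (long or wide) plus a well-layout table.
CSV is the sole format, UTF-8, "." decimal separator. Units are normalized
on read: time in minutes, volumes in mL, concentrations in mol/L,
temperatures in degrees C.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "PlateTimeSeries",
    "read_plaque_counts",
    "validate_plaque_counts",
    "read_plate_timeseries",
    "write_results",
]

STRESSORS = {"heat", "urea", "saline", "none"}

PLAQUE_COLUMNS = ["sample_id", "stressor", "level", "duration_min", "stock_id",
                  "dilution_exponent", "volume_ml", "plaques"]
LAYOUT_COLUMNS = ["well_id", "treatment", "stock_id", "inoculated_pfu",
                  "target_moi", "control_type"]
MEASUREMENT_COLUMNS = ["well_id", "time_min", "od600"]


class SchemaError(ValueError):
    """A required column is missing or a table-level contract is broken."""


class ValidationError(ValueError):
    """A row violates an invariant; the message names the row index."""


@dataclass
class PlateTimeSeries:
    """A plate-reader run: well layout plus long-format measurements."""

    layout: pd.DataFrame
    measurements: pd.DataFrame

    def wells(self) -> list[str]:
        return list(self.layout["well_id"])

    def well_series(self, well_id: str) -> pd.DataFrame:
        m = self.measurements
        return m[m["well_id"] == well_id].reset_index(drop=True)


def _apply_mapping(df: pd.DataFrame, mapping: dict[str, str] | None) -> pd.DataFrame:
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})
    return df


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s): {', '.join(missing)}")


def read_plaque_counts(path: str | Path,
                       schema_config: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a plaque-count table.

    `schema_config` maps canonical column names to the file's column names,
    e.g. ``{"plaques": "num_plaques"}``. Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _apply_mapping(pd.read_csv(path), schema_config)
    _require_columns(df, PLAQUE_COLUMNS, f"plaque counts {path.name}")
    return validate_plaque_counts(df[PLAQUE_COLUMNS].copy())


def validate_plaque_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the plaque-count invariants; returns the normalized table."""
    _require_columns(df, PLAQUE_COLUMNS, "plaque counts")
    df = df.reset_index(drop=True)
    for i, row in df.iterrows():
        if row["stressor"] not in STRESSORS:
            raise ValidationError(
                f"row {i}: unknown stressor {row['stressor']!r} "
                f"(expected one of {sorted(STRESSORS)})")
        p = row["plaques"]
        if not np.isfinite(p) or p < 0 or float(p) != int(p):
            raise ValidationError(
                f"row {i}: plaques must be a non-negative integer, got {p!r}")
        d = row["dilution_exponent"]
        if not np.isfinite(d) or d < 0 or float(d) != int(d):
            raise ValidationError(
                f"row {i}: dilution_exponent must be a non-negative integer, got {d!r}")
        if not (np.isfinite(row["volume_ml"]) and row["volume_ml"] > 0):
            raise ValidationError(f"row {i}: volume_ml must be positive and finite")
        if not (np.isfinite(row["duration_min"]) and row["duration_min"] >= 0):
            raise ValidationError(f"row {i}: duration_min must be >= 0")
    df["plaques"] = df["plaques"].astype(int)
    df["dilution_exponent"] = df["dilution_exponent"].astype(int)
    # replicate plates of one sample at one dilution are distinguished by
    # their position; duplicated (sample, dilution) rows are legitimate
    # triplicates, so uniqueness is enforced on (sample, dilution, replicate)
    df["plate_replicate"] = df.groupby(
        ["sample_id", "dilution_exponent"]).cumcount()
    return df


def read_plate_timeseries(measurements_path: str | Path,
                          layout_path: str | Path,
                          dialect: str = "long") -> PlateTimeSeries:
    """Read a plate-reader run in ``long`` or ``wide`` dialect.

    Long dialect: columns (well_id, time_min, od600). Wide dialect: a
    time_min column plus one column per well. Both yield identical
    in-memory tables for equivalent content.
    """
    measurements_path, layout_path = Path(measurements_path), Path(layout_path)
    for p in (measurements_path, layout_path):
        if not p.exists():
            raise FileNotFoundError(p)
    layout = pd.read_csv(layout_path)
    _require_columns(layout, ["well_id", "treatment", "stock_id"],
                     f"layout {layout_path.name}")
    for optional in ("inoculated_pfu", "target_moi", "control_type"):
        if optional not in layout.columns:
            layout[optional] = np.nan

    raw = pd.read_csv(measurements_path)
    if dialect == "long":
        _require_columns(raw, MEASUREMENT_COLUMNS,
                         f"measurements {measurements_path.name}")
        meas = raw[MEASUREMENT_COLUMNS].copy()
    elif dialect == "wide":
        _require_columns(raw, ["time_min"], f"measurements {measurements_path.name}")
        well_cols = [c for c in raw.columns if c != "time_min"]
        meas = raw.melt(id_vars="time_min", value_vars=well_cols,
                        var_name="well_id", value_name="od600")
        meas = meas[MEASUREMENT_COLUMNS]
        # preserve well-major ordering to match a long file written well by well
        meas = meas.sort_values(["well_id", "time_min"],
                                kind="stable").reset_index(drop=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    known = set(layout["well_id"])
    unknown = sorted(set(meas["well_id"]) - known)
    if unknown:
        raise ValidationError(
            f"measurement well(s) absent from layout: {', '.join(unknown)}")
    if not np.all(np.isfinite(meas["od600"].to_numpy(dtype=float))):
        raise ValidationError("od600 contains non-finite values")
    for well, grp in meas.groupby("well_id", sort=False):
        t = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"well {well}: time_min not strictly increasing")
    if dialect == "long":
        meas = meas.sort_values(["well_id", "time_min"],
                                kind="stable").reset_index(drop=True)
    return PlateTimeSeries(layout=layout.reset_index(drop=True), measurements=meas)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV; read-back reproduces values.

    Floats are written with ``repr`` precision (pandas default), so a
    read-back reproduces them to better than 12 significant digits.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")
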