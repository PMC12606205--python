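"""Hierarchical filament-width measurements.

The measurement protocol prints several lines per (pressure, repeat), and
measures each line's width at a few positions (start, middle, end).  A
dataset is a flat table of those records in SI units; the hierarchy
pressure -> repeat -> line -> position lives in the columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["MeasurementDataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("pressure", "repeat", "line", "position", "width")


@dataclass(frozen=True)
class MeasurementDataset:
    """Width records as a table with columns pressure, repeat, line, position, width.

    ``pressure`` is the gauge pressure drop in Pa, ``width`` the measured
    filament width in m; both strictly positive.  ``repeat`` and ``line`` are
    integer identifiers, ``position`` a label along the line.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if len(df) == 0:
            raise ValueError("dataset is empty")
        if (df["width"] <= 0).any():
            bad = df.index[df["width"] <= 0][:5].tolist()
            raise ValueError(f"non-positive widths at rows {bad}")
        if (df["pressure"] <= 0).any():
            bad = df.index[df["pressure"] <= 0][:5].tolist()
            raise ValueError(f"non-positive pressures at rows {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pressures(self) -> pd.Series:
        """Distinct pressure drops, ascending (Pa)."""
        return pd.Series(sorted(self.frame["pressure"].unique()))

    def line_means(self) -> pd.DataFrame:
        """Mean width per (pressure, repeat, line) — the per-line summary.

        Averaging the few per-line position measurements first is the
        measurement protocol's own aggregation; the per-line means are the
        unit of analysis for fitting and residual testing.
        """
        return (
            self.frame.groupby(["pressure", "repeat", "line"], sort=True)["width"]
            .mean()
            .reset_index()
            .rename(columns={"width": "line_mean"})
        )
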