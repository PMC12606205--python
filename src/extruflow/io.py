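"""Readers/writers for measurement tables and material/nozzle configs.

Measurement CSVs carry the columns ``pressure, repeat, line, position,
width`` with declared units (Pa or kPa for pressure, m or mm for width);
everything is converted to SI on read and back on write.  Configs are plain
YAML/JSON mappings.  Numeric output is serialised with 17 significant
digits so re-reading a report reproduces the values exactly.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .dataset import MeasurementDataset, REQUIRED_COLUMNS
from .flow_model import PowerLawFluid
from .nozzle_geometry import ConicalNozzle, GenericNozzle, Nozzle, StraightNozzle

__all__ = [
    "PRESSURE_UNITS",
    "LENGTH_UNITS",
    "SPEED_UNITS",
    "read_measurements",
    "write_measurements",
    "load_material",
    "load_nozzle",
    "material_from_dict",
    "nozzle_from_dict",
    "write_json",
]

PRESSURE_UNITS = {"pa": 1.0, "kpa": 1e3}
LENGTH_UNITS = {"m": 1.0, "mm": 1e-3}
SPEED_UNITS = {"m/s": 1.0, "mm/s": 1e-3}


def _unit_factor(unit: str, table: Mapping[str, float], kind: str) -> float:
    try:
        return table[unit.lower()]
    except KeyError:
        raise ValueError(f"unknown {kind} unit {unit!r}; expected one of {sorted(table)}") from None


def read_measurements(
    path: str | Path, pressure_unit: str = "Pa", length_unit: str = "m"
) -> MeasurementDataset:
    """Read a measurement CSV, converting to SI (Pa, m).

    The file must have a header with the columns ``pressure, repeat, line,
    position, width``; row order is preserved.  Malformed rows are reported
    with their line numbers.
    """
    p_fac = _unit_factor(pressure_unit, PRESSURE_UNITS, "pressure")
    w_fac = _unit_factor(length_unit, LENGTH_UNITS, "length")
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) == 0:
        raise ValueError(f"{path}: empty measurement file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    for col in ("pressure", "width"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric {col!r} at file line(s) {lines}")
        df[col] = numeric
    df["pressure"] = df["pressure"] * p_fac
    df["width"] = df["width"] * w_fac
    for col, bound in (("pressure", "positive"), ("width", "positive")):
        bad = df.index[df[col] <= 0]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise ValueError(f"{path}: non-{bound} {col!r} at file line(s) {lines}")
    return MeasurementDataset(df[list(REQUIRED_COLUMNS)])


def write_measurements(
    dataset: MeasurementDataset,
    path: str | Path,
    pressure_unit: str = "Pa",
    length_unit: str = "m",
) -> None:
    """Write a measurement CSV in the requested units (atomic replace)."""
    p_fac = _unit_factor(pressure_unit, PRESSURE_UNITS, "pressure")
    w_fac = _unit_factor(length_unit, LENGTH_UNITS, "length")
    df = dataset.frame.copy()
    df["pressure"] = df["pressure"] / p_fac
    df["width"] = df["width"] / w_fac
    # repr gives the shortest decimal that parses back to the same float, so
    # an SI-units write/read cycle is bit-identical
    _atomic_write(Path(path), df.to_csv(index=False, float_format=lambda v: repr(float(v))))


def material_from_dict(spec: Mapping) -> PowerLawFluid:
    """Material from a config mapping: ``{n, K}`` or Newtonian ``{mu}``."""
    if "mu" in spec:
        return PowerLawFluid.newtonian(float(spec["mu"]))
    try:
        return PowerLawFluid(n=float(spec["n"]), K=float(spec["K"]))
    except KeyError as exc:
        raise ValueError(f"material spec needs keys ('n', 'K') or 'mu'; missing {exc}") from None


def nozzle_from_dict(spec: Mapping) -> Nozzle:
    """Nozzle from a config mapping with millimetre fields.

    ``{type: conical, Di_mm, Do_mm, Lc_mm}``, ``{type: straight, DN_mm,
    LN_mm}`` or ``{type: generic, profile: [[z_mm, r_mm], ...]}``.
    """
    kind = str(spec.get("type", "")).lower()
    mm = 1e-3
    if kind == "conical":
        return ConicalNozzle(
            Di=float(spec["Di_mm"]) * mm, Do=float(spec["Do_mm"]) * mm, Lc=float(spec["Lc_mm"]) * mm
        )
    if kind == "straight":
        return StraightNozzle(DN=float(spec["DN_mm"]) * mm, LN=float(spec["LN_mm"]) * mm)
    if kind == "generic":
        profile = [(float(z) * mm, float(r) * mm) for z, r in spec["profile"]]
        return GenericNozzle(L=profile[-1][0], radius_profile=profile)
    raise ValueError(f"unknown nozzle type {spec.get('type')!r}; expected conical|straight|generic")


def _load_config(path: str | Path) -> Mapping:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_material(path: str | Path) -> PowerLawFluid:
    """Load a material spec from a YAML/JSON file."""
    return material_from_dict(_load_config(path))


def load_nozzle(path: str | Path) -> Nozzle:
    """Load a nozzle spec from a YAML/JSON file (mm fields)."""
    return nozzle_from_dict(_load_config(path))


def write_json(obj, path: str | Path) -> None:
    """Serialise a mapping to JSON with full float precision (atomic replace)."""
    _atomic_write(Path(path), json.dumps(obj, indent=2, default=float) + "\n")


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
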