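"""Readers and writers for the package's plain-text table formats.

All tables are CSV with an optional block of ``# key=value`` header comments
carrying provenance (run seed, constants hash, package version).  Two input
schemas are defined:

MID table
    columns ``metabolite, fragment_formula, time_min, replicate, mass_shift,
    intensity`` — one row per isotopologue intensity.  ``fragment_formula``
    uses the ``C6H12O6@6`` notation (``@n`` = tracer-labelable positions).

Plate table
    columns ``well, group, measurement, time_min, phase, OCR, ECAR,
    protein_ug`` — one row per well and measurement cycle, with phases in the
    canonical injection order.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .bioenergetics import PlateAssay
from .errors import SchemaError
from .isocorrect import RawMID, parse_formula

__all__ = [
    "read_mid_table",
    "write_mid_table",
    "read_plate",
    "write_plate",
    "read_header_metadata",
]

MID_COLUMNS = ["metabolite", "fragment_formula", "time_min", "replicate", "mass_shift", "intensity"]
PLATE_COLUMNS = ["well", "group", "measurement", "time_min", "phase", "OCR", "ECAR", "protein_ug"]


def _write_csv(df: pd.DataFrame, path: Path, metadata: Mapping[str, object] | None) -> None:
    with open(path, "w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_header_metadata(path: str | Path) -> Dict[str, str]:
    """Parse the ``# key=value`` comment block at the top of a table."""
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_mid_table(path: str | Path) -> List[RawMID]:
    """Read a MID table into typed records; unknown columns are ignored as metadata."""
    df = _read_csv(path, MID_COLUMNS)
    negative = df.index[df["intensity"] < 0]
    if len(negative):
        raise SchemaError(f"{path}: negative intensity at row(s) {list(negative[:5])}")
    records: List[RawMID] = []
    keys = ["metabolite", "fragment_formula", "time_min", "replicate"]
    for (met, formula_str, t, rep), sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("mass_shift")
        shifts = sub["mass_shift"].to_numpy()
        if not np.array_equal(shifts, np.arange(len(shifts))):
            raise SchemaError(
                f"{path}: {met}/{rep}/t={t}: mass shifts must be contiguous from 0"
            )
        records.append(
            RawMID(
                metabolite=str(met),
                formula=parse_formula(str(formula_str)),
                time_min=float(t),
                replicate=str(rep),
                intensities=sub["intensity"].to_numpy(dtype=float),
            )
        )
    return records


def write_mid_table(
    records: Sequence[RawMID], path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    rows = []
    for r in records:
        for shift, intensity in enumerate(r.intensities):
            rows.append(
                {
                    "metabolite": r.metabolite,
                    "fragment_formula": str(r.formula),
                    "time_min": r.time_min,
                    "replicate": r.replicate,
                    "mass_shift": shift,
                    "intensity": repr(float(intensity)),
                }
            )
    _write_csv(pd.DataFrame(rows, columns=MID_COLUMNS), Path(path), metadata)


def read_plate(path: str | Path) -> PlateAssay:
    """Read a plate table; validates schema, duplicates, and phase order."""
    df = _read_csv(path, PLATE_COLUMNS)
    dup = df.duplicated(subset=["well", "measurement"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (well, measurement) at row(s) {list(df.index[dup][:5])}")
    protein = {}
    for well, sub in df.groupby("well"):
        values = sub["protein_ug"].unique()
        if len(values) != 1:
            raise SchemaError(f"{path}: well {well} has inconsistent protein_ug values")
        protein[str(well)] = float(values[0])
    data = df.rename(columns={"OCR": "ocr", "ECAR": "ecar"})[
        ["well", "group", "measurement", "time_min", "phase", "ocr", "ecar"]
    ]
    return PlateAssay(data=data, protein_ug=protein)


def write_plate(
    plate: PlateAssay, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    df = plate.data.rename(columns={"ocr": "OCR", "ecar": "ECAR"}).copy()
    df["protein_ug"] = df["well"].map(plate.protein_ug)
    df = df[PLATE_COLUMNS]
    for col in ("OCR", "ECAR", "protein_ug", "time_min"):
        df[col] = df[col].map(lambda v: repr(float(v)))
    _write_csv(df, Path(path), metadata)
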