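"""Delimited-text sample tables, Esri ASCII grids, and YAML configs."""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    Analyte,
    GridSpec,
    Instrument,
    PredictionGrid,
    Role,
    SamplePoint,
    SampleSet,
    ValidationError,
)

__all__ = [
    "read_samples",
    "write_samples",
    "read_grid_ascii",
    "write_grid_ascii",
    "load_config",
    "load_reference_samples",
    "setup_logging",
]

log = logging.getLogger("krigfuse")

DEFAULT_SCHEMA: Mapping[str, str] = {
    "id": "id", "x": "x", "y": "y", "value": "value",
    "instrument": "instrument", "analyte": "analyte", "role": "role",
    "ec": "ec", "ph": "ph",
}

_REQUIRED = ("id", "x", "y", "value", "instrument", "analyte")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def read_samples(
    path: Union[str, Path],
    schema: Optional[Mapping[str, str]] = None,
    analyte: Optional[Union[str, Analyte]] = None,
) -> SampleSet:
    """Read a sample table (CSV/TSV with header) into a SampleSet.

    ``schema`` maps canonical field names to column names in the file.
    If the file contains several analytes, ``analyte`` selects one;
    otherwise the file must be homogeneous.

    Malformed rows are rejected with their (1-based, header-exclusive)
    row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample table not found: {path}")
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [cols[f] for f in _REQUIRED if cols[f] not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {missing}")
    if analyte is not None:
        want = Analyte(analyte)
        df = df[df[cols["analyte"]].astype(str) == want.value]
    if df.empty:
        raise ValidationError(f"{path}: no samples")

    points: list[SamplePoint] = []
    errors: list[str] = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            def _opt(field: str) -> Optional[float]:
                col = cols.get(field)
                if col is None or col not in df.columns or pd.isna(row[col]):
                    return None
                return float(row[col])

            role_col = cols.get("role")
            role = Role.TRAIN
            if role_col in df.columns and not pd.isna(row[role_col]):
                role = Role(str(row[role_col]).strip().lower())
            value = float(row[cols["value"]])
            if value <= 0:
                raise ValidationError("non-positive concentration")
            points.append(
                SamplePoint(
                    id=str(row[cols["id"]]),
                    x=float(row[cols["x"]]),
                    y=float(row[cols["y"]]),
                    value=value,
                    instrument=Instrument(str(row[cols["instrument"]]).strip().lower()),
                    analyte=Analyte(str(row[cols["analyte"]]).strip()),
                    role=role,
                    ec=_opt("ec"),
                    ph=_opt("ph"),
                )
            )
        except (ValueError, ValidationError) as exc:
            errors.append(f"row {row_no}: {exc}")
    if errors:
        raise ValidationError(f"{path}: malformed rows:\n  " + "\n  ".join(errors))

    analytes = {p.analyte for p in points}
    if len(analytes) != 1:
        raise ValidationError(
            f"{path}: mixed analytes {sorted(a.value for a in analytes)}; "
            "pass analyte= to select one"
        )
    return SampleSet(points, analytes.pop())


def write_samples(samples: SampleSet, path: Union[str, Path]) -> None:
    """Write a SampleSet to CSV such that read_samples round-trips it."""
    path = Path(path)
    if samples.log_transformed:
        raise ValidationError("write_samples expects raw (not log) values")
    rows = [
        {
            "id": p.id, "x": p.x, "y": p.y, "value": p.value,
            "instrument": p.instrument.value, "analyte": p.analyte.value,
            "role": p.role.value, "ec": p.ec, "ph": p.ph,
        }
        for p in samples
    ]
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# --- Esri ASCII grid -------------------------------------------------------

_NODATA = -9999.0


def write_grid_ascii(
    grid: Union[PredictionGrid, np.ndarray],
    path: Union[str, Path],
    spec: Optional[GridSpec] = None,
    *,
    layer: str = "estimates",
    precision: int = 6,
) -> None:
    """Write one raster layer as an Esri ASCII grid (.asc).

    Rows are emitted north-to-south; NaN cells become the NODATA value.
    """
    if isinstance(grid, PredictionGrid):
        spec = grid.spec
        data = grid.estimates if layer == "estimates" else grid.variances
    else:
        if spec is None:
            raise ValidationError("spec required when writing a bare array")
        data = np.asarray(grid, dtype=float)
        if data.shape != spec.shape:
            raise ValidationError(f"array shape {data.shape} != grid spec {spec.shape}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_min:.{precision}f}\n")
        fh.write(f"yllcorner {spec.y_min:.{precision}f}\n")
        fh.write(f"cellsize {spec.cell_size:.{precision}f}\n")
        fh.write(f"NODATA_value {_NODATA:g}\n")
        for r in range(spec.n_rows):
            row = [
                f"{_NODATA:g}" if not np.isfinite(v) else f"{v:.{precision}f}"
                for v in data[r]
            ]
            fh.write(" ".join(row) + "\n")


def read_grid_ascii(path: Union[str, Path]) -> tuple[np.ndarray, GridSpec]:
    """Read an Esri ASCII grid; NODATA cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    spec = GridSpec(
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
    )
    nodata = header.get("nodata_value", _NODATA)
    data = np.loadtxt(lines[6:].__iter__(), dtype=float).reshape(spec.shape)
    data[data == nodata] = np.nan
    return data, spec


# --- configs ---------------------------------------------------------------


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML config mapping; empty file yields an empty dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def load_reference_samples(analyte: Union[str, Analyte] = Analyte.CU) -> SampleSet:
    """Bundled lab assay table of 23 soil samples (Cu, Pb, EC, pH).

    12 samples carry role=train (dual-assayed locations) and 11 role=validation.
    Coordinates are synthetic placeholders on a unit layout; the assay values,
    EC and pH are the published measurements.
    """
    ref = importlib.resources.files("krigfuse.data").joinpath("lab_samples_23.csv")
    with importlib.resources.as_file(ref) as p:
        return read_samples(p, analyte=Analyte(analyte))
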