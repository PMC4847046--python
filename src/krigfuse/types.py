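"""Core domain types for dual-instrument spatial assay data.

Coordinates are planar metres in an arbitrary local Cartesian frame
(x = easting, y = northing); all algorithms need only Euclidean distances,
so no CRS handling is provided.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Instrument",
    "Analyte",
    "Role",
    "SamplePoint",
    "SampleSet",
    "GridSpec",
    "PredictionGrid",
    "ValidationError",
]

#: coordinates closer than this (metres) are considered the same location
COLOCATION_EPS = 1e-9


class ValidationError(ValueError):
    """Raised when domain invariants are violated."""


class Instrument(str, enum.Enum):
    """Assay instrument class: sparse accurate lab vs dense noisy field."""

    PRIMARY = "primary"      # ICP-AES-like: accurate, sparse
    SECONDARY = "secondary"  # PXRF-like: biased, noisy, dense


class Analyte(str, enum.Enum):
    CU = "Cu"
    PB = "Pb"


class Role(str, enum.Enum):
    TRAIN = "train"
    VALIDATION = "validation"


@dataclass(frozen=True)
class SamplePoint:
    """One point observation of a single analyte by a single instrument."""

    id: str
    x: float
    y: float
    value: float
    instrument: Instrument
    analyte: Analyte
    role: Role = Role.TRAIN
    ec: Optional[float] = None
    ph: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"sample {self.id!r}: non-finite coordinates")
        if not math.isfinite(self.value):
            raise ValidationError(f"sample {self.id!r}: non-finite value")

    @property
    def coords(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class SampleSet:
    """Ordered collection of sample points of one analyte.

    ``log_transformed`` flags that ``value`` holds natural logs of positive
    raw concentrations rather than mg/kg.
    """

    points: list[SamplePoint]
    analyte: Analyte
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValidationError("no samples: a SampleSet needs at least one point")
        bad = [p.id for p in self.points if p.analyte != self.analyte]
        if bad:
            raise ValidationError(
                f"mixed analytes: points {bad} differ from set analyte {self.analyte.value}"
            )
        if not self.log_transformed:
            nonpos = [p.id for p in self.points if p.value <= 0]
            if nonpos:
                raise ValidationError(
                    f"non-positive concentration for samples {nonpos}; "
                    "concentrations must be > 0 (required for log transform)"
                )
        seen: dict[tuple, str] = {}
        for p in self.points:
            key = (round(p.x, 9), round(p.y, 9), p.instrument, p.analyte)
            if key in seen:
                raise ValidationError(
                    f"duplicate sample location: {p.id!r} duplicates {seen[key]!r} "
                    f"at ({p.x}, {p.y}) [{p.instrument.value}/{p.analyte.value}]"
                )
            seen[key] = p.id

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[SamplePoint]:
        return iter(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points], dtype=float)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.points]

    def subset(self, role: Role) -> "SampleSet":
        pts = [p for p in self.points if p.role == role]
        if not pts:
            raise ValidationError(f"no samples with role {role.value!r}")
        return SampleSet(pts, self.analyte, self.log_transformed)

    def with_values(self, values: Sequence[float], *, log_transformed: Optional[bool] = None) -> "SampleSet":
        """Copy with per-point values replaced (order-aligned)."""
        if len(values) != len(self.points):
            raise ValidationError("value vector length mismatch")
        lt = self.log_transformed if log_transformed is None else log_transformed
        pts = [replace(p, value=float(v)) for p, v in zip(self.points, values)]
        return SampleSet(pts, self.analyte, lt)

    def to_log(self) -> "SampleSet":
        """Natural-log transform of positive raw values."""
        if self.log_transformed:
            return self
        return self.with_values(np.log(self.values), log_transformed=True)

    def from_log(self) -> "SampleSet":
        if not self.log_transformed:
            return self
        return self.with_values(np.exp(self.values), log_transformed=False)


@dataclass(frozen=True)
class GridSpec:
    """Regular raster geometry. Origin at the lower-left corner.

    Default 5 m cells mirror the contour-derived elevation grid used to
    motivate the mapping resolution.
    """

    x_min: float
    y_min: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValidationError("n_cols and n_rows must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, row 0 = north."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell_size
        X, Y = np.meshgrid(xs, ys[::-1])  # row-major north-to-south
        return X, Y

    def centers_flat(self) -> np.ndarray:
        X, Y = self.cell_centers()
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclass
class PredictionGrid:
    """Raster of kriged estimates and kriging variances.

    ``variance_scale`` records whether variances are on the data scale
    ('data') or the natural-log scale ('log') for lognormal kriging.
    """

    spec: GridSpec
    estimates: np.ndarray
    variances: np.ndarray
    variance_scale: str = "data"

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        var = np.asarray(self.variances, dtype=float)
        if est.shape != self.spec.shape or var.shape != self.spec.shape:
            raise ValidationError(
                f"raster shape {est.shape} does not match grid spec {self.spec.shape}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(var[np.isfinite(var)] < 0):
                raise ValidationError("negative kriging variance in grid")
        self.estimates = est
        self.variances = var

    @property
    def mask(self) -> np.ndarray:
        """True where the cell could not be computed."""
        return ~np.isfinite(self.estimates)
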