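"""Inter-instrument calibration and dataset fusion.

The dense low-accuracy (secondary) assays are mapped onto the scale of
the sparse accurate (primary) instrument via an OLS trend line fitted on
co-located pairs, then merged with the primary data, preferring the
primary value wherever both instruments sampled the same point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .types import Analyte, Instrument, SamplePoint, SampleSet, ValidationError

__all__ = [
    "CalibrationModel",
    "colocated_pairs",
    "fit_calibration",
    "transform_secondary",
    "merge_primary_preference",
]

log = logging.getLogger("krigfuse.calibration")

DEFAULT_COLOCATION_TOL = 0.5  # metres
DEFAULT_FLOOR = 1.0  # mg/kg floor for calibrated values driven <= 0


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from secondary readings to primary-equivalent values.

    Regression direction is primary-on-secondary (inverse calibration):
    primary = slope * secondary + intercept.
    """

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    analyte: Analyte

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValidationError("calibration needs at least 2 pairs")
        if not np.isfinite(self.r_squared):
            raise ValidationError("non-finite R^2")

    def predict(self, secondary_values: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(secondary_values, dtype=float) + self.intercept

    def to_config(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_pairs": self.n_pairs,
            "analyte": self.analyte.value,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "CalibrationModel":
        return cls(
            slope=float(cfg["slope"]),
            intercept=float(cfg["intercept"]),
            r_squared=float(cfg["r_squared"]),
            n_pairs=int(cfg["n_pairs"]),
            analyte=Analyte(cfg["analyte"]),
        )


def colocated_pairs(
    primary: SampleSet,
    secondary: SampleSet,
    tolerance: float = DEFAULT_COLOCATION_TOL,
) -> list[tuple[float, float]]:
    """(secondary_value, primary_value) pairs at shared locations."""
    pairs = []
    sc = secondary.coords
    for p in primary:
        d = np.hypot(sc[:, 0] - p.x, sc[:, 1] - p.y)
        j = int(np.argmin(d))
        if d[j] <= tolerance:
            pairs.append((secondary.points[j].value, p.value))
    return pairs


def fit_calibration(
    pairs: list[tuple[float, float]],
    analyte: Analyte = Analyte.CU,
    *,
    method: str = "ols",
) -> CalibrationModel:
    """Fit the calibration trend line on (secondary, primary) pairs.

    ``method='ols'`` (default) regresses primary on secondary;
    ``method='deming'`` applies an errors-in-variables correction with
    unit error-variance ratio, offered for sensitivity checks.
    """
    if len(pairs) < 2:
        raise ValidationError("calibration needs at least 2 co-located pairs")
    sec = np.array([p[0] for p in pairs], dtype=float)
    pri = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(sec) == 0:
        raise ValidationError(
            "degenerate design: all secondary values identical; cannot calibrate"
        )
    if method == "ols":
        res = stats.linregress(sec, pri)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue**2
    elif method == "deming":
        sxx = np.var(sec, ddof=1)
        syy = np.var(pri, ddof=1)
        sxy = np.cov(sec, pri, ddof=1)[0, 1]
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
        intercept = pri.mean() - slope * sec.mean()
        r2 = float(np.corrcoef(sec, pri)[0, 1] ** 2)
    else:
        raise ValidationError(f"unknown calibration method {method!r}")
    return CalibrationModel(float(slope), float(intercept), float(r2),
                            len(pairs), analyte)


def transform_secondary(
    cal: CalibrationModel,
    secondary: SampleSet,
    floor: float = DEFAULT_FLOOR,
) -> SampleSet:
    """Map every secondary value through the calibration line.

    Values driven <= 0 are floored at ``floor`` mg/kg; the count is logged.
    """
    if cal.analyte != secondary.analyte:
        raise ValidationError(
            f"calibration analyte {cal.analyte.value} != set analyte "
            f"{secondary.analyte.value}"
        )
    vals = cal.predict(secondary.values)
    n_floored = int(np.sum(vals <= 0))
    if n_floored:
        log.warning("%d calibrated values <= 0 floored at %g mg/kg",
                    n_floored, floor)
        vals = np.where(vals <= 0, floor, vals)
    return secondary.with_values(vals)


def merge_primary_preference(
    primary: SampleSet,
    transformed_secondary: SampleSet,
    colocation_tolerance: float = DEFAULT_COLOCATION_TOL,
) -> SampleSet:
    """Union the two sets, dropping secondary points that duplicate a
    primary location within the tolerance (primary takes preference).

    Provenance is retained through each point's ``instrument`` field.
    """
    if primary.analyte != transformed_secondary.analyte:
        raise ValidationError("cannot merge sets of different analytes")
    pc = primary.coords
    kept: list[SamplePoint] = list(primary.points)
    for q in transformed_secondary:
        d = np.hypot(pc[:, 0] - q.x, pc[:, 1] - q.y)
        if d.min() > colocation_tolerance:
            kept.append(q)
    return SampleSet(kept, primary.analyte, primary.log_transformed)
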