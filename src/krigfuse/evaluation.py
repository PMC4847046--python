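"""Descriptive screening and prediction-error metrics.

Error sign convention: ME = mean(observed - predicted), so positive ME
means underestimation.  RMSE is the root-mean-square of the same
residuals; both are reported on the data (mg/kg) scale, back-transformed
when a lognormal method is evaluated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy import stats

from .kriging import cokrige_points, krige_lognormal, krige_points
from .types import SampleSet, ValidationError
from .variography import CrossVariogramModel, VariogramModel

__all__ = [
    "ValidationReport",
    "summary_stats",
    "skewness_screen",
    "correlation_screen",
    "cross_validate_loo",
    "validate_holdout",
    "predict_at",
]

log = logging.getLogger("krigfuse.evaluation")

SKEW_THRESHOLD = 1.0


@dataclass(frozen=True)
class ValidationReport:
    """ME/RMSE (and Pearson R for holdout) for one approach run."""

    approach_id: int
    analyte: str
    mode: str  # cross_validation | holdout
    me: float
    rmse: float
    n: int
    pearson_r: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("report needs n >= 1")
        if self.rmse + 1e-9 < abs(self.me):
            raise ValidationError(f"rmse {self.rmse} < |me| {self.me}")
        if self.pearson_r is not None and not math.isnan(self.pearson_r):
            if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
                raise ValidationError("pearson_r outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "approach_id": self.approach_id,
            "analyte": self.analyte,
            "mode": self.mode,
            "me": self.me,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "n": self.n,
        }


def summary_stats(values) -> dict:
    """min / max / mean / sd of a sample; sd uses the n-1 estimator."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValidationError("summary_stats needs at least one value")
    out = {
        "n": int(v.size),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size >= 2 else float("nan"),
    }
    return out


def skewness_screen(values, threshold: float = SKEW_THRESHOLD) -> dict:
    """Adjusted Fisher-Pearson sample skewness and a log-transform flag."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("skewness needs n >= 3")
    if np.ptp(v) == 0:
        raise ValidationError("skewness undefined for zero-variance data")
    g1 = float(stats.skew(v, bias=False))
    return {"skewness": g1, "recommend_log": g1 > threshold}


def correlation_screen(table: dict, alpha: float = 0.05) -> dict:
    """Pairwise Pearson r with two-sided p-values over named columns.

    ``table`` maps column name -> values (equal lengths, complete cases).
    Returns per-pair {r, p, significant}.
    """
    names = list(table)
    arrays = {k: np.asarray(v, dtype=float) for k, v in table.items()}
    n = {len(a) for a in arrays.values()}
    if len(n) != 1:
        raise ValidationError("columns must have equal length")
    if n.pop() < 3:
        raise ValidationError("correlation screen needs n >= 3")
    for k, a in arrays.items():
        if np.ptp(a) == 0:
            raise ValidationError(f"constant column {k!r}")
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r, p = stats.pearsonr(arrays[a], arrays[b])
            out[f"{a}-{b}"] = {
                "r": float(r),
                "p": float(p),
                "significant": bool(p < alpha),
            }
    return out


def predict_at(
    targets: np.ndarray,
    method: str,
    samples: SampleSet,
    model: Union[VariogramModel, CrossVariogramModel],
    secondary: Optional[SampleSet] = None,
    back_transform: str = "naive_exp",
    allow_invalid_lmc: bool = True,
) -> np.ndarray:
    """Predict raw-scale values at arbitrary targets with one method.

    method: 'ok' (values as-is), 'ok-log' (lognormal OK on raw mg/kg),
    'ck' (ordinary co-kriging, optionally on log scale if both sets are
    log-transformed).
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if method == "ok":
        est, _, _ = krige_points(samples, model, targets)
        return est
    if method == "ok-log":
        est, _ = krige_lognormal(samples, model, targets, back_transform)
        return est
    if method == "ck":
        if secondary is None:
            raise ValidationError("co-kriging needs a secondary SampleSet")
        est, _, _ = cokrige_points(
            samples, secondary, model, targets, allow_invalid_lmc=allow_invalid_lmc
        )
        return est
    raise ValidationError(f"unknown method {method!r}")


def _error_report(
    approach_id: int,
    analyte: str,
    mode: str,
    observed: np.ndarray,
    predicted: np.ndarray,
    with_r: bool = False,
) -> ValidationReport:
    resid = observed - predicted
    me = float(resid.mean())
    rmse = float(np.sqrt(np.mean(resid**2)))
    r = None
    if with_r:
        if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
            log.warning("degenerate predictions: Pearson R undefined")
            r = float("nan")
        else:
            r = float(stats.pearsonr(observed, predicted)[0])
    return ValidationReport(approach_id, analyte, mode, me, rmse,
                            len(observed), r)


def cross_validate_loo(
    samples: SampleSet,
    model: Union[VariogramModel, CrossVariogramModel],
    method: str = "ok",
    secondary: Optional[SampleSet] = None,
    back_transform: str = "naive_exp",
    approach_id: int = 0,
) -> ValidationReport:
    """Leave-one-out cross-validation with a fixed variogram model.

    Each point is withheld in turn and predicted from the rest; the model
    is NOT refit per fold (one parameter set per approach).  For
    co-kriging only the primary point is withheld; the secondary set
    stays intact.  Folds whose system cannot be solved are skipped with
    a warning and excluded from n.
    """
    if samples.n < 3:
        raise ValidationError("LOO needs at least 3 samples")
    obs, pred = [], []
    skipped = 0
    for i in range(samples.n):
        rest = SampleSet(
            samples.points[:i] + samples.points[i + 1:],
            samples.analyte, samples.log_transformed,
        )
        target = np.asarray([samples.points[i].coords])
        try:
            p = predict_at(target, method, rest, model, secondary, back_transform)
        except (ValidationError, np.linalg.LinAlgError) as exc:
            skipped += 1
            log.warning("LOO fold %d skipped: %s", i, exc)
            continue
        obs.append(samples.points[i].value)
        pred.append(float(p[0]))
    if skipped:
        log.warning("LOO skipped %d of %d folds", skipped, samples.n)
    if not obs:
        raise ValidationError("all LOO folds failed")
    return _error_report(
        approach_id, samples.analyte.value, "cross_validation",
        np.asarray(obs), np.asarray(pred),
    )


def validate_holdout(
    predictor: Callable[[np.ndarray], np.ndarray],
    validation: SampleSet,
    approach_id: int = 0,
) -> ValidationReport:
    """Score a predictor at independent holdout points.

    ``predictor`` maps an (n, 2) coordinate array to predicted values on
    the raw data scale; predictions are made at the exact validation
    coordinates (not nearest grid cells).
    """
    if validation.n < 1:
        raise ValidationError("empty validation set")
    predicted = np.asarray(predictor(validation.coords), dtype=float)
    return _error_report(
        approach_id, validation.analyte.value, "holdout",
        validation.values, predicted, with_r=True,
    )
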