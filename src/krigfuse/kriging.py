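"""Ordinary kriging and ordinary co-kriging in semivariance form.

Systems are assembled as gamma matrices bordered by Lagrange rows and
solved densely; with a global neighborhood the left-hand side is
factorized once per dataset and reused across all prediction targets.

Conventions
-----------
- Exact interpolation at data points: gamma(0) = 0, so a target that
  coincides with a datum reproduces its value with zero variance (the
  nugget is treated as a spatial discontinuity, not measurement error).
- OK constraint: sum(lambda) = 1.  Ordinary co-kriging adds the
  traditional secondary constraint sum(k) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.linalg import lu_factor, lu_solve, solve
from scipy.spatial.distance import cdist, pdist, squareform

from .types import GridSpec, PredictionGrid, SampleSet, ValidationError
from .variography import CrossVariogramModel, VariogramModel, check_lmc, model_gamma

__all__ = [
    "KrigingSolution",
    "krige_point",
    "krige_grid",
    "krige_points",
    "krige_lognormal",
    "cokrige_point",
    "cokrige_grid",
    "cokrige_points",
]

log = logging.getLogger("krigfuse.kriging")

#: coordinates closer than this (m) count as the same location
DUPLICATE_TOL = 1e-9
#: negative variances within this tolerance are clamped to zero
VAR_CLAMP = 1e-10
WEIGHT_TOL = 1e-8


@dataclass
class KrigingSolution:
    """Weights and prediction at one target point."""

    weights_primary: np.ndarray
    weights_secondary: np.ndarray
    lagrange_multipliers: np.ndarray
    estimate: float
    kriging_variance: float

    def __post_init__(self) -> None:
        lam = np.asarray(self.weights_primary, dtype=float)
        k = np.asarray(self.weights_secondary, dtype=float)
        if abs(lam.sum() - 1.0) > WEIGHT_TOL:
            raise ValidationError(
                f"primary weights sum to {lam.sum():.12f}, expected 1"
            )
        if k.size and abs(k.sum()) > WEIGHT_TOL:
            raise ValidationError(
                f"secondary weights sum to {k.sum():.2e}, expected 0"
            )
        if self.kriging_variance < -VAR_CLAMP:
            raise ValidationError(
                f"negative kriging variance {self.kriging_variance:.3e}"
            )
        if self.kriging_variance < 0:
            log.warning(
                "kriging variance %.3e clamped to 0", self.kriging_variance
            )
            self.kriging_variance = 0.0


def _check_duplicates(samples: SampleSet) -> None:
    coords = samples.coords
    if len(coords) < 2:
        return
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    i, j = np.where(d < DUPLICATE_TOL)
    if i.size:
        a, b = i[0], j[0]
        raise ValidationError(
            f"duplicate coordinates: samples {samples.ids[a]!r} and "
            f"{samples.ids[b]!r} coincide within {DUPLICATE_TOL} m"
        )


def _gamma_block(
    model: VariogramModel, a: np.ndarray, b: np.ndarray, sign: float = 1.0
) -> np.ndarray:
    dx = a[:, None, 0] - b[None, :, 0]
    dy = a[:, None, 1] - b[None, :, 1]
    return model_gamma(model, dx, dy, sign=sign)


def _select_neighborhood(
    coords: np.ndarray, target: np.ndarray, max_points: Optional[int]
) -> np.ndarray:
    if max_points is None or len(coords) <= max_points:
        return np.arange(len(coords))
    d = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
    return np.sort(np.argsort(d)[:max_points])


def _ok_lhs(model: VariogramModel, coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = _gamma_block(model, coords, coords)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def _solve_system(A: np.ndarray, B: np.ndarray, what: str) -> np.ndarray:
    import warnings

    from scipy.linalg import LinAlgWarning

    try:
        with warnings.catch_warnings():
            # near-singular systems are expected (e.g. clone secondaries);
            # we validate the solution and fall back to least squares
            warnings.simplefilter("ignore", LinAlgWarning)
            X = solve(A, B)
        if np.all(np.isfinite(X)):
            return X
    except np.linalg.LinAlgError:
        pass
    log.debug("%s system singular; using least-squares fallback", what)
    X, *_ = np.linalg.lstsq(A, B, rcond=None)
    if not np.all(np.isfinite(X)):
        raise ValidationError(f"{what} system could not be solved")
    return X


def krige_points(
    samples: SampleSet,
    model: VariogramModel,
    targets: np.ndarray,
    max_points: Optional[int] = None,
    *,
    return_full: bool = False,
):
    """Ordinary kriging at many targets.

    Returns (estimates, variances, lagrange) arrays; with ``return_full``
    also the (n, T) weight matrix.  The global-neighborhood path
    factorizes the kriging matrix once and back-substitutes per target.
    """
    _check_duplicates(samples)
    coords = samples.coords
    z = samples.values
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    T = len(targets)
    n = len(coords)

    if max_points is not None and n > max_points:
        est = np.empty(T)
        var = np.empty(T)
        mu = np.empty(T)
        W = np.zeros((n, T)) if return_full else None
        for t in range(T):
            idx = _select_neighborhood(coords, targets[t], max_points)
            sub = SampleSet(
                [samples.points[i] for i in idx], samples.analyte,
                samples.log_transformed,
            )
            e, v, m, w = krige_points(sub, model, targets[t:t + 1],
                                      return_full=True)
            est[t], var[t], mu[t] = e[0], v[0], m[0]
            if return_full:
                W[idx, t] = w[:, 0]
        return (est, var, mu, W) if return_full else (est, var, mu)

    A = _ok_lhs(model, coords)
    dxt = coords[:, None, 0] - targets[None, :, 0]
    dyt = coords[:, None, 1] - targets[None, :, 1]
    B = np.empty((n + 1, T))
    B[:n] = model_gamma(model, dxt, dyt)
    B[n] = 1.0
    X = _solve_system(A, B, "ordinary kriging")
    lam = X[:n]
    mu = X[n]
    est = lam.T @ z
    var = np.einsum("it,it->t", lam, B[:n]) + mu
    # exact interpolation at coincident data points
    d0 = np.hypot(dxt, dyt)
    hit_i, hit_t = np.where(d0 < DUPLICATE_TOL)
    for i, t in zip(hit_i, hit_t):
        est[t] = z[i]
        var[t] = 0.0
        mu[t] = 0.0
        lam[:, t] = 0.0
        lam[i, t] = 1.0
    var = np.where((var < 0) & (var > -VAR_CLAMP), 0.0, var)
    if return_full:
        return est, var, mu, lam
    return est, var, mu


def krige_point(
    samples: SampleSet,
    model: VariogramModel,
    target: tuple[float, float],
    max_points: Optional[int] = None,
) -> KrigingSolution:
    """Ordinary kriging at a single target point."""
    est, var, mu, lam = krige_points(
        samples, model, np.asarray([target], dtype=float),
        max_points=max_points, return_full=True,
    )
    return KrigingSolution(
        weights_primary=lam[:, 0],
        weights_secondary=np.empty(0),
        lagrange_multipliers=np.array([mu[0]]),
        estimate=float(est[0]),
        kriging_variance=float(var[0]),
    )


def krige_grid(
    samples: SampleSet,
    model: VariogramModel,
    grid: GridSpec,
    max_points: Optional[int] = None,
) -> PredictionGrid:
    """Ordinary kriging at every cell center of a regular grid."""
    est, var, _ = krige_points(samples, model, grid.centers_flat(), max_points)
    return PredictionGrid(grid, est.reshape(grid.shape), var.reshape(grid.shape))


def krige_lognormal(
    samples: SampleSet,
    model: VariogramModel,
    grid_or_targets: Union[GridSpec, np.ndarray],
    back_transform: str = "naive_exp",
    max_points: Optional[int] = None,
):
    """Lognormal ordinary kriging: log-transform, OK, back-transform.

    ``model`` must be fitted on the log-scale values.  Back-transforms:

    - ``naive_exp``: exp(z*_log) — preserves exactness at data points,
      default for map display.
    - ``unbiased``: exp(z*_log + sigma_OK^2 / 2 - psi) with psi the
      Lagrange multiplier — the standard lognormal-OK mean estimate.

    Returns a PredictionGrid (log-scale variances, flagged) for a
    GridSpec, else (estimates, log_variances) arrays for raw targets.
    """
    if samples.log_transformed:
        raise ValidationError("krige_lognormal expects raw mg/kg samples")
    if back_transform not in ("naive_exp", "unbiased"):
        raise ValidationError(f"unknown back_transform {back_transform!r}")
    logs = samples.to_log()
    is_grid = isinstance(grid_or_targets, GridSpec)
    targets = grid_or_targets.centers_flat() if is_grid else np.atleast_2d(grid_or_targets)
    est_log, var_log, mu = krige_points(logs, model, targets, max_points)
    if back_transform == "naive_exp":
        est = np.exp(est_log)
    else:
        est = np.exp(est_log + var_log / 2.0 - mu)
    if is_grid:
        return PredictionGrid(
            grid_or_targets,
            est.reshape(grid_or_targets.shape),
            var_log.reshape(grid_or_targets.shape),
            variance_scale="log",
        )
    return est, var_log


# --- ordinary co-kriging ---------------------------------------------------


def _ck_lhs(
    lmc: CrossVariogramModel, cp: np.ndarray, cs: np.ndarray
) -> np.ndarray:
    n, m = len(cp), len(cs)
    sz = n + m + 2
    A = np.zeros((sz, sz))
    A[:n, :n] = _gamma_block(lmc.direct_primary, cp, cp)
    A[:n, n:n + m] = _gamma_block(lmc.cross, cp, cs, sign=lmc.cross_sign)
    A[n:n + m, :n] = A[:n, n:n + m].T
    A[n:n + m, n:n + m] = _gamma_block(lmc.direct_secondary, cs, cs)
    A[:n, n + m] = 1.0
    A[n + m, :n] = 1.0
    A[n:n + m, n + m + 1] = 1.0
    A[n + m + 1, n:n + m] = 1.0
    return A


def cokrige_points(
    primary: SampleSet,
    secondary: SampleSet,
    lmc: CrossVariogramModel,
    targets: np.ndarray,
    *,
    allow_invalid_lmc: bool = False,
    return_full: bool = False,
):
    """Ordinary co-kriging of the primary variable at many targets."""
    if primary.n < 1:
        raise ValidationError("co-kriging needs at least one primary datum")
    report = check_lmc(lmc)
    if not report.valid:
        if not allow_invalid_lmc:
            raise ValidationError(
                "coregionalization model fails the sill screen: "
                + "; ".join(report.violations)
                + " (pass allow_invalid_lmc=True to override)"
            )
        log.warning("proceeding with invalid LMC: %s", "; ".join(report.violations))
    _check_duplicates(primary)
    _check_duplicates(secondary)
    cp, cs = primary.coords, secondary.coords
    zp, zs = primary.values, secondary.values
    n, m = len(cp), len(cs)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    T = len(targets)

    A = _ck_lhs(lmc, cp, cs)
    B = np.zeros((n + m + 2, T))
    dxp = cp[:, None, 0] - targets[None, :, 0]
    dyp = cp[:, None, 1] - targets[None, :, 1]
    B[:n] = model_gamma(lmc.direct_primary, dxp, dyp)
    dxs = cs[:, None, 0] - targets[None, :, 0]
    dys = cs[:, None, 1] - targets[None, :, 1]
    B[n:n + m] = model_gamma(lmc.cross, dxs, dys, sign=lmc.cross_sign)
    B[n + m] = 1.0
    X = _solve_system(A, B, "co-kriging")
    lam, k = X[:n], X[n:n + m]
    mu = X[n + m:]
    est = lam.T @ zp + k.T @ zs
    var = (
        np.einsum("it,it->t", lam, B[:n])
        + np.einsum("jt,jt->t", k, B[n:n + m])
        + mu[0]
    )
    d0 = np.hypot(dxp, dyp)
    hit_i, hit_t = np.where(d0 < DUPLICATE_TOL)
    for i, t in zip(hit_i, hit_t):
        est[t] = zp[i]
        var[t] = 0.0
    var = np.where((var < 0) & (var > -VAR_CLAMP), 0.0, var)
    if return_full:
        return est, var, mu, lam, k
    return est, var, mu


def cokrige_point(
    primary: SampleSet,
    secondary: SampleSet,
    lmc: CrossVariogramModel,
    target: tuple[float, float],
    *,
    allow_invalid_lmc: bool = False,
) -> KrigingSolution:
    """Ordinary co-kriging at a single target point."""
    est, var, mu, lam, k = cokrige_points(
        primary, secondary, lmc, np.asarray([target], dtype=float),
        allow_invalid_lmc=allow_invalid_lmc, return_full=True,
    )
    d = np.hypot(primary.coords[:, 0] - target[0], primary.coords[:, 1] - target[1])
    if d.min() < DUPLICATE_TOL:
        i = int(np.argmin(d))
        lam = np.zeros(primary.n)
        lam[i] = 1.0
        k = np.zeros(secondary.n)
        mu = np.zeros((2, 1))
    return KrigingSolution(
        weights_primary=lam[:, 0] if lam.ndim == 2 else lam,
        weights_secondary=k[:, 0] if k.ndim == 2 else k,
        lagrange_multipliers=mu[:, 0],
        estimate=float(est[0]),
        kriging_variance=float(var[0]),
    )


def cokrige_grid(
    primary: SampleSet,
    secondary: SampleSet,
    lmc: CrossVariogramModel,
    grid: GridSpec,
    *,
    allow_invalid_lmc: bool = False,
) -> PredictionGrid:
    """Ordinary co-kriging at every cell center of a regular grid."""
    est, var, _ = cokrige_points(
        primary, secondary, lmc, grid.centers_flat(),
        allow_invalid_lmc=allow_invalid_lmc,
    )
    return PredictionGrid(grid, est.reshape(grid.shape), var.reshape(grid.shape))
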