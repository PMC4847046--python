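"""Experimental and model variograms with geometric anisotropy.

Semivariance estimator: for each lag/direction class,
``gamma = (1 / 2 N_pairs) * sum [z(x_i) - z(x_i + h)]^2`` over the pairs
whose separation vector falls in the class.

Model variograms use the practical-range convention: the Gaussian and
exponential forms reach ~95% of the partial sill at the stated range.
Azimuths are degrees clockwise from north (grid +y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform

from .types import SampleSet, ValidationError

__all__ = [
    "ExperimentalVariogram",
    "VariogramModel",
    "CrossVariogramModel",
    "LMCReport",
    "experimental_variogram",
    "experimental_cross_variogram",
    "model_gamma",
    "fit_variogram",
    "fit_lmc",
    "check_lmc",
]

log = logging.getLogger("krigfuse.variography")

DEFAULT_N_LAGS = 12
DEFAULT_ANGLE_TOL = 22.5  # degrees, each side


@dataclass(frozen=True)
class ExperimentalVariogram:
    """Binned semivariances with pair counts.

    ``direction_azimuth`` is None for omnidirectional variograms.
    Lags with zero pairs are dropped (they carry no gamma value).
    """

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    lag_width: float
    direction_azimuth: Optional[float] = None
    angle_tolerance: float = DEFAULT_ANGLE_TOL

    def __post_init__(self) -> None:
        lags = np.asarray(self.lag_centers, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        n = np.asarray(self.pair_counts, dtype=int)
        if len(lags) == 0:
            raise ValidationError("empty variogram: no pair in any lag class")
        if not (len(lags) == len(g) == len(n)):
            raise ValidationError("variogram arrays must be equal length")
        if np.any(np.diff(lags) <= 0):
            raise ValidationError("lag centers must be strictly increasing")
        if np.any(g < 0) or np.any(n <= 0):
            raise ValidationError("gamma must be >= 0 with positive pair counts")
        object.__setattr__(self, "lag_centers", lags)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "pair_counts", n)

    @property
    def n_lags(self) -> int:
        return len(self.lag_centers)


@dataclass(frozen=True)
class VariogramModel:
    """Authorized variogram model with optional geometric anisotropy.

    ``sill`` (total) = nugget + partial_sill.  Isotropic models have
    range_minor == range_major.  gamma(0) = 0 exactly; the nugget applies
    only for h > 0.
    """

    model_type: str  # gaussian | spherical | exponential
    nugget: float
    partial_sill: float
    range_major: float
    range_minor: Optional[float] = None
    azimuth_major: float = 0.0

    def __post_init__(self) -> None:
        if self.model_type not in ("gaussian", "spherical", "exponential"):
            raise ValidationError(f"unknown model type {self.model_type!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValidationError("nugget and partial_sill must be >= 0")
        rminor = self.range_major if self.range_minor is None else self.range_minor
        object.__setattr__(self, "range_minor", float(rminor))
        if self.range_major <= 0 or self.range_minor <= 0:
            raise ValidationError("ranges must be > 0")
        if self.range_minor > self.range_major + 1e-12:
            raise ValidationError("range_minor must be <= range_major")

    @property
    def sill(self) -> float:
        """Total sill (nugget + partial sill)."""
        return self.nugget + self.partial_sill

    @property
    def isotropic(self) -> bool:
        return abs(self.range_minor - self.range_major) < 1e-12

    def effective_distance(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Anisotropy-corrected distance: 1.0 at the (directional) range."""
        theta = np.deg2rad(self.azimuth_major)
        # azimuth clockwise from north: major axis unit vector (sin t, cos t)
        h_maj = dx * np.sin(theta) + dy * np.cos(theta)
        h_min = dx * np.cos(theta) - dy * np.sin(theta)
        return np.sqrt((h_maj / self.range_major) ** 2 + (h_min / self.range_minor) ** 2)

    @classmethod
    def from_config(cls, cfg: dict) -> "VariogramModel":
        """Build from a config mapping laid out like the published table.

        Accepts ``sill`` with ``sill_is_total`` (default True) or a direct
        ``partial_sill``; ``range`` may be scalar or "major/minor".
        """
        cfg = dict(cfg)
        nugget = float(cfg.get("nugget", 0.0))
        if "partial_sill" in cfg:
            psill = float(cfg["partial_sill"])
        else:
            sill = float(cfg["sill"])
            psill = sill - nugget if cfg.get("sill_is_total", True) else sill
            if psill < 0:
                raise ValidationError(
                    f"total sill {sill} smaller than nugget {nugget}"
                )
        rng = cfg.get("range", cfg.get("range_major"))
        if isinstance(rng, str) and "/" in rng:
            major, minor = (float(t) for t in rng.split("/"))
        elif isinstance(rng, (list, tuple)):
            major, minor = (float(t) for t in rng)
        else:
            major = float(rng)
            minor = float(cfg.get("range_minor", major))
        return cls(
            model_type=str(cfg.get("model", cfg.get("model_type", "gaussian"))).lower(),
            nugget=nugget,
            partial_sill=psill,
            range_major=major,
            range_minor=minor,
            azimuth_major=float(cfg.get("direction", cfg.get("azimuth_major", 0.0))),
        )

    def to_config(self) -> dict:
        return {
            "model": self.model_type,
            "nugget": self.nugget,
            "sill": self.sill,
            "sill_is_total": True,
            "range_major": self.range_major,
            "range_minor": self.range_minor,
            "direction": self.azimuth_major,
        }


@dataclass(frozen=True)
class CrossVariogramModel:
    """Linear-model-of-coregionalization triple: two direct + one cross.

    All three structures must share model type and ranges; only sills
    (and nuggets) differ.  The cross structure may carry a negative
    partial sill conceptually, but VariogramModel stores magnitudes, so
    ``cross_sign`` records the sign.
    """

    direct_primary: VariogramModel
    direct_secondary: VariogramModel
    cross: VariogramModel
    cross_sign: float = 1.0

    def __post_init__(self) -> None:
        p, s, c = self.direct_primary, self.direct_secondary, self.cross
        if not (p.model_type == s.model_type == c.model_type):
            raise ValidationError("LMC structures must share the model type")
        for a in (s, c):
            if (
                abs(a.range_major - p.range_major) > 1e-9
                or abs(a.range_minor - p.range_minor) > 1e-9
                or abs(a.azimuth_major - p.azimuth_major) > 1e-9
            ):
                raise ValidationError("LMC structures must share ranges and azimuth")
        if self.cross_sign not in (-1.0, 1.0):
            raise ValidationError("cross_sign must be +/-1")


@dataclass(frozen=True)
class LMCReport:
    valid: bool
    violations: tuple[str, ...]


def _pair_arrays(coords: np.ndarray, *value_cols: np.ndarray):
    """Upper-triangle pair separations and value columns."""
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    dx = coords[ju, 0] - coords[iu, 0]
    dy = coords[ju, 1] - coords[iu, 1]
    return iu, ju, dx, dy


def _bin_pairs(
    dist: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
    contrib: np.ndarray,
    lag_width: float,
    n_lags: int,
    direction: Optional[float],
    angle_tolerance: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    keep = dist > 0
    if direction is not None:
        # pair azimuth in [0, 180): direction of the separation vector
        az = np.rad2deg(np.arctan2(dx, dy)) % 180.0
        diff = np.abs(az - direction % 180.0)
        diff = np.minimum(diff, 180.0 - diff)
        keep &= diff <= angle_tolerance + 1e-12
    dist, contrib = dist[keep], contrib[keep]
    idx = np.floor(dist / lag_width).astype(int)
    inside = idx < n_lags
    idx, contrib = idx[inside], contrib[inside]
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=contrib, minlength=n_lags)
    pop = counts > 0
    centers = (np.arange(n_lags) + 0.5) * lag_width
    gamma = np.zeros(n_lags)
    gamma[pop] = sums[pop] / (2.0 * counts[pop])
    return centers[pop], gamma[pop], counts[pop]


def _default_lag_width(coords: np.ndarray, n_lags: int) -> float:
    dmax = pdist(coords).max()
    return dmax / (2.0 * n_lags)


def experimental_variogram(
    samples: SampleSet,
    lag_width: Optional[float] = None,
    n_lags: int = DEFAULT_N_LAGS,
    direction: Optional[float] = None,
    angle_tolerance: float = DEFAULT_ANGLE_TOL,
) -> ExperimentalVariogram:
    """Binned experimental semivariogram (omnidirectional or directional)."""
    if samples.n < 2:
        raise ValidationError("variogram needs at least 2 samples")
    coords = samples.coords
    z = samples.values
    iu, ju, dx, dy = _pair_arrays(coords)
    dist = np.hypot(dx, dy)
    sq = (z[iu] - z[ju]) ** 2
    lw = lag_width if lag_width is not None else _default_lag_width(coords, n_lags)
    centers, gamma, counts = _bin_pairs(
        dist, dx, dy, sq, lw, n_lags, direction, angle_tolerance
    )
    if len(centers) == 0:
        raise ValidationError("empty variogram: no pair in any lag class")
    return ExperimentalVariogram(centers, gamma, counts, lw, direction, angle_tolerance)


def experimental_cross_variogram(
    primary: SampleSet,
    secondary: SampleSet,
    lag_width: Optional[float] = None,
    n_lags: int = DEFAULT_N_LAGS,
    direction: Optional[float] = None,
    angle_tolerance: float = DEFAULT_ANGLE_TOL,
    colocation_tol: float = 1e-9,
) -> ExperimentalVariogram:
    """Cross-variogram over co-located pairs of the two sets.

    gamma_12(h) = (1 / 2 N_pairs) * sum [z1(x_i) - z1(x_j)] [z2(x_i) - z2(x_j)].
    Requires at least 2 locations sampled by both instruments.
    """
    sec_by_loc = {}
    for q in secondary:
        sec_by_loc[(round(q.x, 6), round(q.y, 6))] = q.value
    coords, z1, z2 = [], [], []
    for p in primary:
        key = (round(p.x, 6), round(p.y, 6))
        if key in sec_by_loc:
            coords.append([p.x, p.y])
            z1.append(p.value)
            z2.append(sec_by_loc[key])
    if len(coords) < 2:
        raise ValidationError(
            "cross-variography needs >= 2 co-located points "
            f"(found {len(coords)}); sample both instruments at shared locations"
        )
    coords = np.array(coords)
    z1 = np.array(z1)
    z2 = np.array(z2)
    iu, ju, dx, dy = _pair_arrays(coords)
    dist = np.hypot(dx, dy)
    cross = (z1[iu] - z1[ju]) * (z2[iu] - z2[ju])
    lw = lag_width if lag_width is not None else _default_lag_width(coords, n_lags)
    keep = dist > 0
    az_ok = np.ones_like(keep)
    if direction is not None:
        az = np.rad2deg(np.arctan2(dx, dy)) % 180.0
        diff = np.abs(az - direction % 180.0)
        diff = np.minimum(diff, 180.0 - diff)
        az_ok = diff <= angle_tolerance + 1e-12
    keep &= az_ok
    d, c = dist[keep], cross[keep]
    idx = np.floor(d / lw).astype(int)
    inside = idx < n_lags
    idx, c = idx[inside], c[inside]
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=c, minlength=n_lags)
    pop = counts > 0
    if not pop.any():
        raise ValidationError("empty variogram: no pair in any lag class")
    centers = (np.arange(n_lags) + 0.5) * lw
    gamma = np.zeros(n_lags)
    gamma[pop] = sums[pop] / (2.0 * counts[pop])
    # cross semivariance may legitimately be negative; bypass the >=0 invariant
    ev = ExperimentalVariogram.__new__(ExperimentalVariogram)
    object.__setattr__(ev, "lag_centers", centers[pop])
    object.__setattr__(ev, "gamma", gamma[pop])
    object.__setattr__(ev, "pair_counts", counts[pop])
    object.__setattr__(ev, "lag_width", lw)
    object.__setattr__(ev, "direction_azimuth", direction)
    object.__setattr__(ev, "angle_tolerance", angle_tolerance)
    return ev


def _structure(model_type: str, he: np.ndarray) -> np.ndarray:
    """Normalized correlation structure g(he) in [0, 1), g(1) ~ 0.95."""
    if model_type == "gaussian":
        return 1.0 - np.exp(-3.0 * he**2)
    if model_type == "exponential":
        return 1.0 - np.exp(-3.0 * he)
    if model_type == "spherical":
        hec = np.clip(he, 0.0, 1.0)
        return 1.5 * hec - 0.5 * hec**3
    raise ValidationError(f"unknown model type {model_type!r}")


def model_gamma(
    model: VariogramModel,
    dx: Union[float, np.ndarray],
    dy: Union[float, np.ndarray],
    sign: float = 1.0,
) -> Union[float, np.ndarray]:
    """Model semivariance for lag vector(s) (dx, dy).

    gamma(0) = 0 exactly; for h > 0 the nugget is added in full.
    ``sign`` scales nugget and partial sill (cross structures may be negative).
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    he = model.effective_distance(dx, dy)
    g = sign * (model.nugget + model.partial_sill * _structure(model.model_type, he))
    out = np.where(np.hypot(dx, dy) > 0, g, 0.0)
    return float(out) if out.ndim == 0 else out


def _lag_vectors(ev: ExperimentalVariogram) -> tuple[np.ndarray, np.ndarray]:
    """Representative lag vectors for fitting: along the class azimuth,
    or treated as distance along +x for omnidirectional classes."""
    h = ev.lag_centers
    if ev.direction_azimuth is None:
        return h, np.zeros_like(h)
    t = np.deg2rad(ev.direction_azimuth)
    return h * np.sin(t), h * np.cos(t)


def fit_variogram(
    exp_v: Union[ExperimentalVariogram, Sequence[ExperimentalVariogram]],
    model_type: str = "gaussian",
    anisotropy_azimuth: Optional[float] = None,
    *,
    fixed_ranges: Optional[tuple[float, float]] = None,
    nugget_floor_frac: float = 0.0,
) -> VariogramModel:
    """Fit a variogram model by pair-count-weighted least squares.

    Accepts one omnidirectional variogram (isotropic fit) or several
    directional variograms (anisotropic fit with a fixed major azimuth).
    Multi-start from method-of-moments initial values keeps the fit
    reproducible.  ``fixed_ranges`` pins (range_major, range_minor) and
    fits only nugget and partial sill (used for LMC assembly).

    ``nugget_floor_frac`` raises the fitted nugget to at least that
    fraction of the total sill after the fit.  Gaussian models with a
    near-zero nugget produce ill-conditioned kriging systems and wild
    weights; a small floor is the standard stabilization.
    """
    evs = [exp_v] if isinstance(exp_v, ExperimentalVariogram) else list(exp_v)
    dx = np.concatenate([_lag_vectors(ev)[0] for ev in evs])
    dy = np.concatenate([_lag_vectors(ev)[1] for ev in evs])
    gamma = np.concatenate([ev.gamma for ev in evs])
    w = np.sqrt(np.concatenate([ev.pair_counts for ev in evs]).astype(float))
    if len(gamma) < 3:
        raise ValidationError("fit needs >= 3 populated lags")
    anisotropic = anisotropy_azimuth is not None and fixed_ranges is None
    az = 0.0 if anisotropy_azimuth is None else float(anisotropy_azimuth)

    h = np.hypot(dx, dy)
    hmax = h.max()
    g_hi = float(np.mean(gamma[h >= np.median(h)]))
    g_lo = float(gamma[np.argmin(h)])
    nug0 = max(min(g_lo, g_hi) * 0.5, 0.0)
    psill0 = max(g_hi - nug0, 1e-6 * max(g_hi, 1.0))

    def build(params: np.ndarray) -> VariogramModel:
        if fixed_ranges is not None:
            nug, ps = params
            rmaj, rmin = fixed_ranges
        elif anisotropic:
            nug, ps, rmaj, ratio = params
            rmin = rmaj * ratio
        else:
            nug, ps, rmaj = params
            rmin = rmaj
        return VariogramModel(model_type, max(nug, 0.0), max(ps, 0.0),
                              rmaj, rmin, az)

    def resid(params: np.ndarray) -> np.ndarray:
        m = build(params)
        return w * (model_gamma(m, dx, dy) - gamma)

    if fixed_ranges is not None:
        x0s = [np.array([nug0, psill0])]
        lb, ub = [0.0, 0.0], [np.inf, np.inf]
    elif anisotropic:
        x0s = [np.array([nug0, psill0, r0, q0])
               for r0 in (hmax / 3, hmax / 1.5) for q0 in (0.5, 1.0)]
        lb, ub = [0.0, 0.0, 1e-6, 1e-3], [np.inf, np.inf, 10 * hmax, 1.0]
    else:
        x0s = [np.array([nug0, psill0, r0]) for r0 in (hmax / 4, hmax / 2, hmax)]
        lb, ub = [0.0, 0.0, 1e-6], [np.inf, np.inf, 10 * hmax]

    best = None
    for x0 in x0s:
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            log.debug("fit start %s failed: %s", x0, exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ValidationError("variogram fit did not converge from any start")
    if not best.success and best.cost > 1e-8:
        log.warning("variogram fit did not fully converge; final objective %.4g",
                    best.cost)
    fitted = build(best.x)
    total = fitted.nugget + fitted.partial_sill
    floor = nugget_floor_frac * total
    if fitted.nugget < floor:
        # keep the total sill; move variance from the structure to the nugget
        fitted = replace(fitted, nugget=floor, partial_sill=total - floor)
    return fitted


def fit_lmc(
    primary: SampleSet,
    secondary: SampleSet,
    model_type: str = "gaussian",
    anisotropy_azimuth: Optional[float] = None,
    lag_width: Optional[float] = None,
    n_lags: int = DEFAULT_N_LAGS,
    nugget_floor_frac: float = 0.0,
) -> CrossVariogramModel:
    """Pragmatic LMC fit: ranges taken from the dense secondary set, direct
    and cross sills refit with ranges fixed, cross sill clamped into the
    Cauchy-Schwarz bound so the coregionalization stays valid."""
    def _dirs(ss: SampleSet):
        if anisotropy_azimuth is None:
            return experimental_variogram(ss, lag_width, n_lags)
        return [
            experimental_variogram(ss, lag_width, n_lags, direction=d)
            for d in (anisotropy_azimuth, anisotropy_azimuth + 90.0)
        ]

    base = fit_variogram(_dirs(secondary), model_type, anisotropy_azimuth,
                         nugget_floor_frac=nugget_floor_frac)
    ranges = (base.range_major, base.range_minor)
    az = base.azimuth_major

    def _refit(ev) -> VariogramModel:
        m = fit_variogram(ev, model_type, fixed_ranges=ranges,
                          nugget_floor_frac=nugget_floor_frac)
        return replace(m, azimuth_major=az, range_minor=ranges[1])

    direct_p = _refit(_dirs(primary))
    direct_s = replace(base)
    cross_ev = experimental_cross_variogram(primary, secondary, lag_width, n_lags)
    sign = 1.0 if np.average(cross_ev.gamma, weights=cross_ev.pair_counts) >= 0 else -1.0
    pos_ev = ExperimentalVariogram(
        cross_ev.lag_centers, sign * cross_ev.gamma, cross_ev.pair_counts,
        cross_ev.lag_width,
    ) if np.all(sign * cross_ev.gamma >= 0) else None
    if pos_ev is None:
        # mixed-sign cross semivariances: fit on magnitudes of the trend
        pos_ev = ExperimentalVariogram(
            cross_ev.lag_centers, np.abs(cross_ev.gamma), cross_ev.pair_counts,
            cross_ev.lag_width,
        )
    cross = _refit(pos_ev)
    bound = 0.999 * np.sqrt(direct_p.partial_sill * direct_s.partial_sill)
    nug_bound = 0.999 * np.sqrt(direct_p.nugget * direct_s.nugget)
    cross = replace(
        cross,
        partial_sill=min(cross.partial_sill, bound),
        nugget=min(cross.nugget, nug_bound),
    )
    return CrossVariogramModel(direct_p, direct_s, cross, cross_sign=sign)


def check_lmc(model: CrossVariogramModel) -> LMCReport:
    """Cauchy-Schwarz sill screen per structure (nugget and partial sill)."""
    p, s, c = model.direct_primary, model.direct_secondary, model.cross
    violations = []
    bound_ps = np.sqrt(p.partial_sill * s.partial_sill)
    if c.partial_sill > bound_ps + 1e-12:
        violations.append(
            f"cross partial sill {c.partial_sill:g} exceeds "
            f"sqrt({p.partial_sill:g} * {s.partial_sill:g}) = {bound_ps:g}"
        )
    bound_n = np.sqrt(p.nugget * s.nugget)
    if c.nugget > bound_n + 1e-12:
        violations.append(
            f"cross nugget {c.nugget:g} exceeds sqrt({p.nugget:g} * {s.nugget:g})"
            f" = {bound_n:g}"
        )
    return LMCReport(valid=not violations, violations=tuple(violations))
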