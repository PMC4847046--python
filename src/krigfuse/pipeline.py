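"""End-to-end orchestration of the four mapping approaches.

Approach 1 — ordinary kriging of the sparse accurate (primary) data.
Approach 2 — ordinary kriging of the dense low-accuracy (secondary) data,
             left on its biased scale by design.
Approach 3 — calibrate the secondary against co-located primary assays,
             transform it, merge with primary preference, ordinary kriging.
Approach 4 — ordinary co-kriging (primary + secondary).

A natural-log transform is applied when the training values are
positively skewed (or when forced by config), with the back-transform
applied consistently to cross-validation and holdout predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .calibration import (
    colocated_pairs,
    fit_calibration,
    merge_primary_preference,
    transform_secondary,
)
from .evaluation import (
    ValidationReport,
    cross_validate_loo,
    skewness_screen,
    validate_holdout,
)
from .kriging import cokrige_points, krige_grid, krige_lognormal, krige_points, cokrige_grid
from .synthetic import ScenarioConfig, generate_scenario
from .types import Analyte, GridSpec, PredictionGrid, SampleSet, ValidationError
from .variography import (
    CrossVariogramModel,
    VariogramModel,
    experimental_variogram,
    fit_lmc,
    fit_variogram,
)

__all__ = [
    "ApproachConfig",
    "ApproachResult",
    "run_approach",
    "compare_approaches",
    "replicate_study",
]

log = logging.getLogger("krigfuse.pipeline")


@dataclass
class ApproachConfig:
    """Configuration of one approach run."""

    approach_id: int
    analyte: Analyte = Analyte.CU
    variogram: Optional[VariogramModel] = None
    cross_variogram: Optional[CrossVariogramModel] = None
    log_transform: Union[str, bool] = "auto"  # 'auto' | True | False
    grid: Optional[GridSpec] = None
    back_transform: str = "naive_exp"
    anisotropy_azimuth: Optional[float] = None
    colocation_tolerance: float = 0.5
    compute_grid: bool = True
    compute_loo: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.approach_id not in (1, 2, 3, 4):
            raise ValidationError("approach_id must be 1..4")

    @classmethod
    def from_config(cls, cfg: dict) -> "ApproachConfig":
        kwargs = dict(cfg)
        if "analyte" in kwargs:
            kwargs["analyte"] = Analyte(kwargs["analyte"])
        if "variogram" in kwargs and kwargs["variogram"] is not None:
            kwargs["variogram"] = VariogramModel.from_config(kwargs["variogram"])
        if "cross_variogram" in kwargs and kwargs["cross_variogram"] is not None:
            cv = kwargs["cross_variogram"]
            kwargs["cross_variogram"] = CrossVariogramModel(
                VariogramModel.from_config(cv["primary"]),
                VariogramModel.from_config(cv["secondary"]),
                VariogramModel.from_config(cv["cross"]),
                cross_sign=float(cv.get("cross_sign", 1.0)),
            )
        if "grid" in kwargs and kwargs["grid"] is not None:
            kwargs["grid"] = GridSpec(**kwargs["grid"])
        return cls(**kwargs)


@dataclass
class ApproachResult:
    approach_id: int
    grid: Optional[PredictionGrid]
    loo: Optional[ValidationReport]
    holdout: Optional[ValidationReport]
    model: Union[VariogramModel, CrossVariogramModel, None]
    log_used: bool
    n_train: int


def _decide_log(cfg: ApproachConfig, values: np.ndarray) -> bool:
    if cfg.log_transform == "auto":
        return bool(skewness_screen(values)["recommend_log"])
    return bool(cfg.log_transform)


# Gaussian kriging systems need a nonzero nugget to stay well conditioned
AUTO_NUGGET_FLOOR = 0.05


def _auto_fit(samples: SampleSet, azimuth: Optional[float]) -> VariogramModel:
    if azimuth is None:
        return fit_variogram(experimental_variogram(samples), "gaussian",
                             nugget_floor_frac=AUTO_NUGGET_FLOOR)
    evs = [
        experimental_variogram(samples, direction=d)
        for d in (azimuth, azimuth + 90.0)
    ]
    return fit_variogram(evs, "gaussian", anisotropy_azimuth=azimuth,
                         nugget_floor_frac=AUTO_NUGGET_FLOOR)


def _training_data(
    cfg: ApproachConfig, primary: SampleSet, secondary: SampleSet
) -> SampleSet:
    if cfg.approach_id == 1:
        return primary
    if cfg.approach_id == 2:
        return secondary
    if cfg.approach_id == 3:
        pairs = colocated_pairs(primary, secondary, cfg.colocation_tolerance)
        if len(pairs) < 2:
            raise ValidationError(
                "approach 3 requires >= 2 co-located calibration pairs"
            )
        cal = fit_calibration(pairs, cfg.analyte)
        log.info("calibration: slope=%.4f intercept=%.2f R2=%.4f n=%d",
                 cal.slope, cal.intercept, cal.r_squared, cal.n_pairs)
        transformed = transform_secondary(cal, secondary)
        return merge_primary_preference(primary, transformed,
                                        cfg.colocation_tolerance)
    raise ValidationError("approach 4 uses both sets; no single training set")


def run_approach(
    config: ApproachConfig,
    primary: SampleSet,
    secondary: Optional[SampleSet] = None,
    validation: Optional[SampleSet] = None,
) -> ApproachResult:
    """Run one approach end to end: model -> map -> LOO -> holdout."""
    if config.approach_id >= 2 and secondary is None:
        raise ValidationError(
            f"approach {config.approach_id} requires a secondary SampleSet"
        )
    if primary.analyte != config.analyte or (
        secondary is not None and secondary.analyte != config.analyte
    ):
        raise ValidationError("sample analyte does not match the approach config")

    if config.approach_id == 4:
        return _run_cokriging(config, primary, secondary, validation)

    train = _training_data(config, primary, secondary)
    use_log = _decide_log(config, train.values)
    fit_data = train.to_log() if use_log else train
    model = config.variogram or _auto_fit(fit_data, config.anisotropy_azimuth)

    method = "ok-log" if use_log else "ok"
    grid = None
    if config.compute_grid and config.grid is not None:
        if use_log:
            grid = krige_lognormal(train, model, config.grid, config.back_transform)
        else:
            grid = krige_grid(train, model, config.grid)

    loo = None
    if config.compute_loo:
        loo = cross_validate_loo(
            train, model, method, back_transform=config.back_transform,
            approach_id=config.approach_id,
        )

    holdout = None
    if validation is not None:
        def predictor(targets: np.ndarray) -> np.ndarray:
            if use_log:
                est, _ = krige_lognormal(train, model, targets,
                                         config.back_transform)
            else:
                est, _, _ = krige_points(train, model, targets)
            return est

        holdout = validate_holdout(predictor, validation, config.approach_id)

    return ApproachResult(config.approach_id, grid, loo, holdout, model,
                          use_log, train.n)


def _run_cokriging(
    config: ApproachConfig,
    primary: SampleSet,
    secondary: SampleSet,
    validation: Optional[SampleSet],
) -> ApproachResult:
    use_log = _decide_log(config, primary.values)
    pri = primary.to_log() if use_log else primary
    sec = secondary.to_log() if use_log else secondary
    lmc = config.cross_variogram or fit_lmc(
        pri, sec, "gaussian", config.anisotropy_azimuth,
        nugget_floor_frac=AUTO_NUGGET_FLOOR,
    )

    def predict(targets: np.ndarray) -> np.ndarray:
        est, _, _ = cokrige_points(pri, sec, lmc, targets,
                                   allow_invalid_lmc=True)
        return np.exp(est) if use_log else est

    grid = None
    if config.compute_grid and config.grid is not None:
        flat = predict(config.grid.centers_flat())
        _, var, _ = cokrige_points(pri, sec, lmc, config.grid.centers_flat(),
                                   allow_invalid_lmc=True)
        grid = PredictionGrid(
            config.grid, flat.reshape(config.grid.shape),
            var.reshape(config.grid.shape),
            variance_scale="log" if use_log else "data",
        )

    loo = None
    if config.compute_loo:
        obs, pred = [], []
        for i in range(pri.n):
            rest = SampleSet(pri.points[:i] + pri.points[i + 1:],
                             pri.analyte, pri.log_transformed)
            est, _, _ = cokrige_points(
                rest, sec, lmc, np.asarray([pri.points[i].coords]),
                allow_invalid_lmc=True,
            )
            obs.append(primary.points[i].value)
            pred.append(float(np.exp(est[0])) if use_log else float(est[0]))
        resid = np.asarray(obs) - np.asarray(pred)
        loo = ValidationReport(
            config.approach_id, config.analyte.value, "cross_validation",
            float(resid.mean()), float(np.sqrt(np.mean(resid**2))), len(obs),
        )

    holdout = None
    if validation is not None:
        holdout = validate_holdout(predict, validation, config.approach_id)

    return ApproachResult(config.approach_id, grid, loo, holdout, lmc,
                          use_log, pri.n)


def compare_approaches(reports: Sequence[ValidationReport]) -> list[dict]:
    """Rank approach reports by RMSE ascending.

    Ties are broken by |ME|, then approach id.  All reports must share
    analyte and validation mode.
    """
    if len(reports) < 2:
        raise ValidationError("comparison needs >= 2 reports")
    analytes = {r.analyte for r in reports}
    modes = {r.mode for r in reports}
    if len(analytes) != 1:
        raise ValidationError(f"mixed analytes in comparison: {sorted(analytes)}")
    if len(modes) != 1:
        raise ValidationError(f"mixed validation modes: {sorted(modes)}")
    ranked = sorted(reports, key=lambda r: (r.rmse, abs(r.me), r.approach_id))
    return [
        {"rank": i + 1, **r.to_dict()}
        for i, r in enumerate(ranked)
    ]


def replicate_study(
    scenario: Optional[ScenarioConfig] = None,
    n_replicates: int = 50,
    seed: int = 0,
    approaches: Sequence[int] = (1, 2, 3, 4),
) -> dict:
    """Repeat generate -> run all approaches -> rank over many seeds.

    Returns per-approach counts of being best (lowest holdout RMSE) and
    worst, plus mean RMSEs and the per-replicate rankings.  Maps and LOO
    are skipped for speed; only the holdout metric drives the ranking.
    """
    scenario = scenario or ScenarioConfig()
    best: dict[int, int] = {a: 0 for a in approaches}
    worst: dict[int, int] = {a: 0 for a in approaches}
    rmse_sum: dict[int, float] = {a: 0.0 for a in approaches}
    rankings = []
    done = 0
    for rep in range(n_replicates):
        cfg_rep = ScenarioConfig(**{**scenario.__dict__, "seed": seed + 1000 * rep})
        data = generate_scenario(cfg_rep)
        reports = []
        try:
            for a in approaches:
                res = run_approach(
                    ApproachConfig(a, compute_grid=False, compute_loo=False,
                                   anisotropy_azimuth=None),
                    data["primary"], data["secondary"], data["validation"],
                )
                reports.append(res.holdout)
        except ValidationError as exc:
            log.warning("replicate %d failed: %s", rep, exc)
            continue
        ranking = compare_approaches(reports)
        rankings.append([r["approach_id"] for r in ranking])
        best[ranking[0]["approach_id"]] += 1
        worst[ranking[-1]["approach_id"]] += 1
        for r in reports:
            rmse_sum[r.approach_id] += r.rmse
        done += 1
    if done == 0:
        raise ValidationError("all replicates failed")
    return {
        "n_replicates": done,
        "best_counts": best,
        "worst_counts": worst,
        "mean_rmse": {a: rmse_sum[a] / done for a in approaches},
        "rankings": rankings,
    }
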