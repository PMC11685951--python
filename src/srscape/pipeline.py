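"""End-to-end orchestration: build the isoscape, then assign individuals.

Stage order for a build: read -> extract/infill -> collinearity screen ->
(optional) tune -> fit -> cross-validate -> predict mean -> IJ standard
errors -> strict mask / MOP similarity -> diagnostics.  All randomness
flows from one root seed through named substreams, so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .assignment import AssignmentResult, joint_assignment, top_fraction_region
from .forest import CVReport, IsoscapeForest, TuneResult, cross_validate, tune
from .grid import (
    ConfigurationError,
    PredictorStack,
    Raster,
    SampleTable,
    extract_predictors,
    read_raster,
    read_samples,
    write_raster,
)
from .mask import mop_similarity, strict_mask
from .screening import ScreenReport, screen
from .uncertainty import se_surface

log = logging.getLogger("srscape")


def substream(seed: int, tag: str) -> int:
    """Deterministic named substream of a root seed (stable across runs)."""
    ss = np.random.SeedSequence([seed, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Flat configuration for a build/assign run."""

    n_trees: int = 500
    mtry: int = 2
    min_node_size: int = 2
    k_folds: int = 5
    cv_repeats: int = 10
    validation_holdout: int = 20
    mop_fraction: float = 0.10
    ij_bias_correction: bool = True
    sr_extra_sd: float = 0.0
    o_extra_sd: float = 1.0
    run_tune: bool = False
    run_cv: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class BuildResult:
    model: IsoscapeForest
    mean: Raster
    se: Raster
    strict: Raster
    similarity: Raster
    screen_report: ScreenReport
    cv_report: CVReport | None
    tune_result: TuneResult | None
    holdout_r2: float | None
    holdout_rmse: float | None
    residuals: diag.ResidualSummary
    correlogram: diag.Correlogram
    importance: pd.DataFrame
    config: RunConfig


def build_isoscape(
    samples: SampleTable,
    stack: PredictorStack,
    config: RunConfig | None = None,
) -> BuildResult:
    """Fit the Sr isoscape and every companion surface and diagnostic."""
    config = config or RunConfig()
    design = extract_predictors(samples, stack)
    X = design.predictors()
    y = samples.frame["sr_ratio"].to_numpy(dtype=float)
    categorical = design.categorical_columns
    log.info("design: %d samples x %d predictors, %d infilled entries",
             len(X), X.shape[1], len(design.infill_log))

    screen_report = screen(design)

    tune_result = None
    mtry, node = config.mtry, config.min_node_size
    if config.run_tune:
        tune_result = tune(
            X, y, categorical=categorical, seed=substream(config.seed, "tune")
        )
        mtry, node = tune_result.best_mtry, tune_result.best_min_node_size
        log.info("tuned: mtry=%d min_node_size=%d", mtry, node)

    # validation holdout, chosen uniformly at random with the run seed
    holdout_r2 = holdout_rmse = None
    rng = np.random.default_rng(substream(config.seed, "holdout"))
    n = len(X)
    if config.validation_holdout and n > config.validation_holdout + config.k_folds:
        hold = rng.choice(n, size=config.validation_holdout, replace=False)
        train = np.setdiff1d(np.arange(n), hold)
    else:
        hold = np.array([], dtype=int)
        train = np.arange(n)

    model = IsoscapeForest(
        n_trees=config.n_trees,
        mtry=mtry,
        min_node_size=node,
        categorical=categorical,
        random_state=substream(config.seed, "fit"),
    )
    model.fit(X.iloc[train], y[train])
    log.info("fit: OOB R2=%.3f RMSE=%.5f", model.oob_r2_, model.oob_rmse_)

    if hold.size:
        pred = model.predict(X.iloc[hold])
        resid = y[hold] - pred
        sse = float(resid @ resid)
        sst = float(((y[hold] - y[hold].mean()) ** 2).sum())
        holdout_rmse = float(np.sqrt(sse / hold.size))
        holdout_r2 = 1.0 - sse / sst if sst > 0 else float("nan")
        log.info("holdout (n=%d): R2=%.3f RMSE=%.5f", hold.size, holdout_r2, holdout_rmse)

    cv_report = None
    if config.run_cv:
        cv_report = cross_validate(
            X.iloc[train],
            y[train],
            k_folds=config.k_folds,
            repeats=config.cv_repeats,
            seed=substream(config.seed, "cv"),
            n_trees=config.n_trees,
            mtry=mtry,
            min_node_size=node,
            categorical=categorical,
        )
        log.info("CV (%dx%d): R2=%.3f RMSE=%.5f",
                 config.k_folds, config.cv_repeats, cv_report.r2, cv_report.rmse)

    mean = model.predict_surface(stack)
    se = se_surface(model, stack, bias_correction=config.ij_bias_correction)
    strict = strict_mask(stack, model.training_ranges_)
    mean_masked = Raster(
        np.where(strict.values > 0, np.nan, mean.values), mean.spec
    )
    se_masked = Raster(np.where(strict.values > 0, np.nan, se.values), se.spec)
    similarity = mop_similarity(
        stack,
        X.iloc[train],
        design.kinds,
        fraction=config.mop_fraction,
        exclude=strict,
    )
    log.info("mask: %d of %d cells strict-extrapolation",
             int(strict.values.sum()), strict.values.size)

    residuals = diag.residual_summary(model, y[train])
    seen = ~np.isnan(model.oob_prediction_)
    corr = diag.correlogram(
        residuals.residuals,
        samples.frame["longitude"].to_numpy()[train][seen],
        samples.frame["latitude"].to_numpy()[train][seen],
        seed=substream(config.seed, "correlogram"),
    )
    imp = diag.importance(
        model, X.iloc[train], y[train], seed=substream(config.seed, "importance")
    )

    return BuildResult(
        model=model,
        mean=mean_masked,
        se=se_masked,
        strict=strict,
        similarity=similarity,
        screen_report=screen_report,
        cv_report=cv_report,
        tune_result=tune_result,
        holdout_r2=holdout_r2,
        holdout_rmse=holdout_rmse,
        residuals=residuals,
        correlogram=corr,
        importance=imp,
        config=config,
    )


def write_build(result: BuildResult, out_dir) -> Path:
    """Persist every build artifact under ``out_dir``."""
    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster(result.mean, out / "sr_mean.tif")
    write_raster(result.se, out / "sr_se.tif")
    write_raster(result.strict, out / "strict_mask.tif")
    write_raster(result.similarity, out / "mop_similarity.tif")
    joblib.dump(result.model, out / "model.joblib")
    result.screen_report.write(out / "screen")
    if result.cv_report is not None:
        pd.DataFrame(
            {"r2": result.cv_report.fold_r2, "rmse": result.cv_report.fold_rmse}
        ).to_csv(out / "cv_folds.csv", index=False)
    result.correlogram.to_frame().to_csv(out / "correlogram.csv", index=False)
    result.importance.to_csv(out / "importance.csv", index=False)
    summary = {
        "config": asdict(result.config),
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "oob_r2": result.model.oob_r2_,
        "oob_rmse": result.model.oob_rmse_,
        "holdout_r2": result.holdout_r2,
        "holdout_rmse": result.holdout_rmse,
        "cv_r2": result.cv_report.r2 if result.cv_report else None,
        "cv_rmse": result.cv_report.rmse if result.cv_report else None,
        "residual_fraction_within_band": result.residuals.fraction_within,
        "strict_masked_cells": int(result.strict.values.sum()),
    }
    (out / "run.json").write_text(json.dumps(summary, indent=2))
    return out


@dataclass
class AssignmentRun:
    results: dict[str, AssignmentResult] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    summary: pd.DataFrame | None = None


def assign_individuals(
    individuals: pd.DataFrame,
    sr_mean: Raster,
    sr_se: Raster,
    o_mean: Raster | None = None,
    o_sd: Raster | None = None,
    priors: dict[str, Raster] | None = None,
    config: RunConfig | None = None,
    top_q: float = 0.2,
) -> AssignmentRun:
    """Assign each individual; per-individual failures do not stop the run.

    ``individuals`` columns: individual_id, sr87_sr86, optionally
    d18o_carb_vpdb, region_prior (name into ``priors``), sr_meas_sd.
    """
    config = config or RunConfig()
    priors = priors or {}
    run = AssignmentRun()
    rows = []
    for _, row in individuals.iterrows():
        ind = str(row["individual_id"])
        try:
            prior = None
            prior_name = row.get("region_prior")
            if isinstance(prior_name, str) and prior_name.strip():
                if prior_name not in priors:
                    raise ConfigurationError(f"unknown region prior {prior_name!r}")
                prior = priors[prior_name]
            d18o = row.get("d18o_carb_vpdb")
            d18o = None if pd.isna(d18o) else float(d18o)
            sr_sd = row.get("sr_meas_sd")
            sr_sd = 0.0 if pd.isna(sr_sd) else float(sr_sd)
            result = joint_assignment(
                float(row["sr87_sr86"]),
                sr_mean,
                sr_se,
                d18o_carb_vpdb=d18o,
                o_mean=o_mean,
                o_sd=o_sd,
                sr_extra_sd=max(sr_sd, config.sr_extra_sd),
                o_extra_sd=config.o_extra_sd,
                prior=prior,
            )
            run.results[ind] = result
            region = top_fraction_region(result, top_q)
            r, c = result.argmax_cell
            x, y = sr_mean.spec.cell_center(r, c)
            rows.append(
                {
                    "individual_id": ind,
                    "isotopes": "sr+o18" if d18o is not None else "sr",
                    "argmax_lon": float(x),
                    "argmax_lat": float(y),
                    "top_region_cells": int(region.sum()),
                    "top_region_q": top_q,
                }
            )
        except Exception as exc:  # per-individual isolation
            log.error("assignment failed for %s: %s", ind, exc)
            run.errors[ind] = str(exc)
    run.summary = pd.DataFrame(rows)
    return run


def write_assignments(run: AssignmentRun, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ind, result in run.results.items():
        write_raster(result.posterior, out / f"{ind}_posterior.tif")
        write_raster(result.display, out / f"{ind}_display.tif")
    if run.summary is not None:
        run.summary.to_csv(out / "summary.csv", index=False)
    if run.errors:
        (out / "errors.json").write_text(json.dumps(run.errors, indent=2))
    return out


def load_isoscape(directory) -> tuple[Raster, Raster]:
    directory = Path(directory)
    return read_raster(directory / "sr_mean.tif"), read_raster(directory / "sr_se.tif")
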