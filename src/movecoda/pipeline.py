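"""End-to-end pipeline: epochs -> compositions -> walkability -> models.

``run_pipeline`` ties the stages into one reproducible run, writing the five
analysis tables (descriptives, compositional effect tables and linear effect
tables per sex stratum), residual diagnostics, run metadata and a
machine-readable invariant report.  Any stage failure aborts the run with a
stage-named error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .accelerometry import process_epoch_table
from .composition import DEFAULT_PARTS, PivotBasis, pivot_coordinates_matrix, pivot_inverse_matrix
from .models import (
    BehaviourLinearModel,
    CodaRegression,
    descriptives,
    fit_stratified,
)
from .walkability import first_principal_component

logger = logging.getLogger("movecoda")

__all__ = ["RunConfig", "run_pipeline", "check_invariants"]


@dataclass
class RunConfig:
    epoch_csv: str | Path
    covariate_csv: str | Path
    indicator_csv: str | Path
    out_dir: str | Path
    total: float = 1440.0
    include_safety: bool = False
    strata: tuple[str, ...] = ("F", "M")
    seed: int = 0
    rounding: int = 2

    def __post_init__(self) -> None:
        if self.rounding < 0:
            raise ValueError("rounding must be >= 0")

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, e) from e
            return out
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute accelerometry -> walkability -> models and write the report
    bundle.  Returns a dict of the in-memory results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out_dir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write(df: pd.DataFrame, path: Path, written: list[Path],
           rounding: int | None = None) -> None:
    if rounding is not None:
        df = df.copy()
        for c in df.select_dtypes(include=[float]).columns:
            df[c] = df[c].round(rounding)
    df.to_csv(path, index=False)
    written.append(path)


def _run(config: RunConfig, out_dir: Path, written: list[Path]) -> dict:
    read_epochs = _stage("read-epochs")(mio.read_epoch_csv)
    epochs = read_epochs(config.epoch_csv)
    logger.info("read %d epoch rows, %d subjects", len(epochs),
                epochs["subject_id"].nunique())

    behaviour = _stage("accelerometry")(process_epoch_table)(epochs)
    n_valid = int(behaviour["valid"].sum())
    logger.info("accelerometry: %d/%d subjects valid", n_valid,
                len(behaviour))

    covariates = _stage("read-covariates")(mio.read_covariate_csv)(
        config.covariate_csv)
    indicators = _stage("read-indicators")(mio.read_indicator_csv)(
        config.indicator_csv)

    scores = _stage("walkability")(first_principal_component)(
        indicators.set_index("subject_id"))
    logger.info("walkability PC1 variance share: %.3f",
                scores.variance_explained)

    @_stage("assemble-cohort")
    def assemble():
        beh = behaviour.rename(columns={
            "sleep_min": "sleep", "sb_min": "SB",
            "lpa_min": "LPA", "mvpa_min": "MVPA"})
        merged = covariates.merge(beh, on="subject_id", how="inner")
        merged = merged.merge(
            scores.scores.rename("walkability"),
            left_on="subject_id", right_index=True, how="inner")
        included = merged[merged["valid"]].reset_index(drop=True)
        excluded = merged[~merged["valid"]].reset_index(drop=True)
        if len(included) == 0:
            raise ValueError("no valid subjects after accelerometry rules")
        return included, excluded

    included, excluded = assemble()
    logger.info("cohort: %d included, %d excluded", len(included),
                len(excluded))

    @_stage("descriptives")
    def make_descriptives():
        cont = ["age", "bmi_z", "walkability"]
        cat = ["summer", "puberty", "parent_edu", "safety"]
        inc = included.copy()
        exc = excluded.copy()
        inc["female"] = (inc["sex"] == "F").astype(int)
        exc["female"] = (exc["sex"] == "F").astype(int)
        for p in DEFAULT_PARTS:
            inc[f"{p}_hours"] = inc[p] / 60.0
            if p in exc.columns:
                exc[f"{p}_hours"] = exc[p] / 60.0
        cont = cont + [f"{p}_hours" for p in DEFAULT_PARTS]
        return descriptives(inc, exc, continuous=cont,
                            categorical=["female"] + cat)

    table1 = make_descriptives()
    _write(table1, out_dir / "table_descriptives.csv", written)

    coda_fits = _stage("coda-models")(fit_stratified)(
        included, CodaRegression, include_safety=config.include_safety)
    linear_fits = _stage("linear-models")(fit_stratified)(
        included, BehaviourLinearModel,
        include_safety=config.include_safety)

    invariants = {"product_to_one_max_abs_error": {},
                  "linear_covariate_sum_max_abs": {},
                  "linear_intercept_sum": {}}
    for sex, res in coda_fits.items():
        _write(res.effect_table(), out_dir / f"table_coda_{sex}.csv",
               written, rounding=config.rounding)
        _write(res.diagnostics().reset_index(names="part"),
               out_dir / f"diagnostics_coda_{sex}.csv", written)
        invariants["product_to_one_max_abs_error"][sex] = float(
            res.product_to_one_error().max())
    for sex, res in linear_fits.items():
        _write(res.effect_table(), out_dir / f"table_linear_{sex}.csv",
               written, rounding=config.rounding)
        sums = res.coefficient_sums()
        invariants["linear_covariate_sum_max_abs"][sex] = float(
            sums.drop("const").abs().max())
        invariants["linear_intercept_sum"][sex] = float(sums["const"])

    # round-trip closure check on one stored composition
    comps = included[list(DEFAULT_PARTS)].to_numpy(dtype=float)
    basis = PivotBasis(DEFAULT_PARTS[0], DEFAULT_PARTS)
    z = pivot_coordinates_matrix(comps, basis)
    back = pivot_inverse_matrix(z, basis, total=config.total)
    invariants["pivot_round_trip_max_abs_error"] = float(
        np.abs(back - comps * (config.total / comps.sum(axis=1,
                                                        keepdims=True))).max())

    meta = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "include_safety": config.include_safety,
        "n_included": len(included),
        "n_excluded": len(excluded),
        "n_per_stratum": {s: int((included["sex"] == s).sum())
                          for s in config.strata},
        "walkability_variance_explained": scores.variance_explained,
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    written.append(out_dir / "run_metadata.json")
    (out_dir / "invariants.json").write_text(json.dumps(invariants, indent=2))
    written.append(out_dir / "invariants.json")

    return {
        "behaviour": behaviour,
        "included": included,
        "excluded": excluded,
        "scores": scores,
        "descriptives": table1,
        "coda": coda_fits,
        "linear": linear_fits,
        "invariants": invariants,
        "metadata": meta,
    }


def check_invariants(out_dir, tol: float = 1e-9) -> dict:
    """Re-read a run's invariant report and flag violations."""
    path = Path(out_dir) / "invariants.json"
    inv = json.loads(path.read_text())
    checks = {
        "product_to_one": all(
            v < 1e-10 for v in inv["product_to_one_max_abs_error"].values()),
        "linear_covariate_sums_zero": all(
            v < tol for v in inv["linear_covariate_sum_max_abs"].values()),
        "linear_intercepts_sum_24": all(
            abs(v - 24.0) < tol
            for v in inv["linear_intercept_sum"].values()),
        "pivot_round_trip": inv["pivot_round_trip_max_abs_error"] < 1e-10,
    }
    checks["all_passed"] = all(checks.values())
    return checks
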