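"""End-to-end workflows: calibrate-and-validate, and quantify-and-speciate.

A single :class:`RunConfig` drives both workflows; every JSON artifact is
stamped with the config hash and seed so a rerun with the same config is
reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import calibration as cal
from . import simulate, speciation, validation
from .chromatograms import DEFAULT_REFERENCES

__all__ = [
    "RunConfig",
    "ValidationFailure",
    "run_calibration_workflow",
    "run_speciation_workflow",
    "load_config",
]

log = logging.getLogger("sulfispec")


class CalibrationConfig(BaseModel):
    kind: str = "linear"
    max_conc: Optional[float] = cal.REDUCED_MAX_CONC_UM
    alpha: float = 0.05
    reporting_decimals: int = 1
    rmse_denominator: str = "n"


class ChromatographyConfig(BaseModel):
    references: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    tolerance: float = 0.2
    baseline: str = "linear_endpoints"


class CohortConfig(BaseModel):
    reference: str = "T0"


class RunConfig(BaseModel):
    """Configuration of a full pipeline run."""

    seed: int = 0
    standards_path: Optional[str] = None
    model_path: Optional[str] = None
    areas_path: Optional[str] = None
    out_dir: str = "sulfispec_out"
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    chromatography: ChromatographyConfig = Field(default_factory=ChromatographyConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)

    @field_validator("calibration")
    @classmethod
    def _check_alpha(cls, v: CalibrationConfig) -> CalibrationConfig:
        if not (0 < v.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")
        return v

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ValidationFailure(RuntimeError):
    """The cross-validation conformity test failed; artifacts were still written."""


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML or JSON config file, with optional dotted-key overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        node = raw
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return RunConfig(**raw)


def _stamp(config: RunConfig, payload: dict) -> dict:
    return {"config_hash": config.content_hash(), "seed": config.seed, **payload}


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def run_calibration_workflow(
    config: RunConfig, standards: pd.DataFrame | None = None
) -> dict:
    """reduce_range -> fit -> LOO-CV -> conformity test -> LoD/LoQ, with JSON artifacts.

    Returns a dict with the fitted model, CV result and detection limits.
    Raises :class:`ValidationFailure` (after writing all artifacts) when the
    conformity test fails, so callers can map it to a distinct exit status.
    """
    if standards is None:
        if config.standards_path is None:
            raise ValueError("no standards table: set standards_path or pass a DataFrame")
        standards = pd.read_csv(config.standards_path)
    ccfg = config.calibration
    log.info(
        "calibration defaults: OLS (unweighted), rmse denominator %s, "
        "trapezoidal integration with %s baseline, alpha %s",
        ccfg.rmse_denominator, config.chromatography.baseline, ccfg.alpha,
    )
    if ccfg.max_conc is not None:
        standards = cal.reduce_range(standards, ccfg.max_conc)
        log.info("%s", standards.attrs.get("range_reduction", ""))
    model = cal.fit_calibration(standards, ccfg.kind, rmse_denominator=ccfg.rmse_denominator)
    recalc = validation.loo_cv(standards, ccfg.kind)
    cv = validation.validate_recalc_regression(
        standards["area_au"].to_numpy(), recalc, alpha=ccfg.alpha, mode="cv"
    )
    out = Path(config.out_dir)
    _write_json(out / "model.json", _stamp(config, json.loads(model.to_json())))
    _write_json(
        out / "validation.json",
        _stamp(
            config,
            {
                "mode": cv.mode,
                "intercept": cv.line_intercept,
                "s_intercept": cv.s_intercept,
                "slope": cv.line_slope,
                "s_slope": cv.s_slope,
                "r_squared": cv.r_squared,
                "rmse": cv.rmse,
                "model_p_value": cv.model_p_value,
                "conforms": cv.conforms,
                "alpha": cv.alpha,
            },
        ),
    )
    limits = None
    if ccfg.kind == "linear":
        try:
            limits = cal.compute_lod_loq(model, reporting_decimals=ccfg.reporting_decimals)
        except ValueError as exc:
            _write_json(out / "limits.json", _stamp(config, {"error": str(exc)}))
        else:
            _write_json(
                out / "limits.json",
                _stamp(
                    config,
                    {
                        "lod_um": limits.lod,
                        "loq_um": limits.loq,
                        "lod_raw_um": limits.lod_raw,
                        "loq_raw_um": limits.loq_raw,
                    },
                ),
            )
    else:
        _write_json(
            out / "limits.json",
            _stamp(
                config,
                {
                    "error": "LoD/LoQ require the linear model; "
                    "reduce the concentration range (e.g. max_conc 6) and refit linearly"
                },
            ),
        )
    log.info("%s", cv.summary())
    result = {"model": model, "cv": cv, "limits": limits, "standards": standards}
    if not cv.conforms:
        raise ValidationFailure(cv.summary())
    return result


def run_speciation_workflow(
    config: RunConfig,
    model: cal.CalibrationModel | None = None,
    areas: pd.DataFrame | None = None,
) -> dict:
    """Quantify the three arms per sample, speciate, and run cohort statistics.

    ``areas`` is a long table (patient_id, timepoint, arm, injection, area_au)
    with arm in {free, acid, total}; a missing arm for any sample is rejected
    by name.  Writes the per-sample speciation CSV and the cohort-stats JSON.
    """
    if model is None:
        if config.model_path is None:
            raise ValueError("no calibration model: set model_path or pass a model")
        model = cal.CalibrationModel.from_json(Path(config.model_path))
    if areas is None:
        if config.areas_path is None:
            raise ValueError("no area table: set areas_path or pass a DataFrame")
        areas = pd.read_csv(config.areas_path)
    required = {"patient_id", "timepoint", "arm", "area_au"}
    if not required.issubset(areas.columns):
        raise ValueError(f"area table needs columns {sorted(required)}")
    loq = cal.compute_lod_loq(model).loq_raw if model.rmse > 0 else 0.0
    rows = []
    for (pid, tp), sample in areas.groupby(["patient_id", "timepoint"]):
        arms = {}
        for arm in ("free", "acid", "total"):
            arm_areas = sample.loc[sample["arm"] == arm, "area_au"].to_numpy()
            if arm_areas.size == 0:
                raise ValueError(f"sample {pid}/{tp}: missing arm {arm!r}")
            arms[arm] = speciation.quantify_arm(model, arm_areas)
        spec = speciation.speciate(
            max(arms["free"].conc, 0.0), max(arms["acid"].conc, 0.0),
            max(arms["total"].conc, 0.0), loq=loq,
        )
        rows.append(
            {
                "patient_id": pid,
                "timepoint": tp,
                "free_um": spec.free,
                "acid_um": spec.acid,
                "total_um": spec.total,
                "acid_labile_um": spec.acid_labile,
                "bound_sulfane_um": spec.bound_sulfane,
                "flags": ";".join(sorted(spec.flags | set().union(*(a.flags for a in arms.values())))),
            }
        )
    samples = pd.DataFrame(rows)
    cohort = samples.melt(
        id_vars=["patient_id", "timepoint"],
        value_vars=["free_um", "acid_labile_um", "bound_sulfane_um", "total_um"],
        var_name="species",
        value_name="concentration_um",
    )
    cohort["species"] = cohort["species"].str.removesuffix("_um")
    stats_df = speciation.cohort_stats(cohort, reference=config.cohort.reference)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples.to_csv(out / "speciation.csv", index=False, float_format="%.10g")
    _write_json(
        out / "cohort_stats.json",
        _stamp(config, {"records": stats_df.where(pd.notna(stats_df), None).to_dict("records")}),
    )
    return {"samples": samples, "cohort": cohort, "stats": stats_df}
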