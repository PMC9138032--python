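"""Calibration models for SDB peak area versus sulfide concentration.

The assay calibrates FLD peak area (AU) against Na2S standard concentration
(µM).  Over the full 0.8-50 µM standard range the response is parabolic,
y = a + b·x + c·x²; restricting the standards to the low range (0.8-6 µM,
where serum samples actually fall) permits a linear model y = a + b·x whose
detection limits follow the 3.3/6 × RMSE/slope convention.  Concentrations
of unknowns are obtained by inverting the fitted curve, with the classical
inverse-prediction standard deviation that is smallest near the model
centroid (the mean-response region) and grows toward the extremes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PAPER_STANDARD_LEVELS_UM",
    "REDUCED_MAX_CONC_UM",
    "StandardsError",
    "CalibrationModel",
    "DetectionLimits",
    "InvertedConcentration",
    "check_standards",
    "fit_calibration",
    "compute_lod_loq",
    "predict_area",
    "invert_calibration",
    "reduce_range",
]

#: The seven Na2S standard levels (µM) of the reference protocol.
PAPER_STANDARD_LEVELS_UM = (0.8, 1.6, 3.0, 6.0, 12.5, 25.0, 50.0)
#: Upper bound of the reduced low-concentration range used for the linear model.
REDUCED_MAX_CONC_UM = 6.0

STANDARDS_COLUMNS = ["conc_um", "area_au", "day", "replicate"]


class StandardsError(ValueError):
    """Raised when a standards table cannot support the requested fit."""


@dataclass
class CalibrationModel:
    """A fitted linear or parabolic calibration curve.

    Coefficients follow y = a + b·x (+ c·x²) with x in µM and y in AU.
    ``rmse`` uses denominator n by default (``rmse_denominator='n'``); the
    usual unbiased n−p variant is available.  ``centroid_area`` is the mean
    fitted response — the response region where inverse prediction is most
    precise.  ``n_points``, ``sxx`` and ``mean_conc`` are retained for the
    inverse-prediction variance formula.
    """

    kind: str
    a: float
    b: float
    s_a: float
    s_b: float
    r_squared: float
    rmse: float
    model_p_value: float
    conc_range: tuple[float, float]
    centroid_area: float
    n_points: int
    sxx: float
    mean_conc: float
    c: float | None = None
    s_c: float | None = None
    rmse_denominator: str = "n"

    def coefficients(self) -> np.ndarray:
        if self.kind == "parabolic":
            return np.array([self.a, self.b, self.c])
        return np.array([self.a, self.b])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["conc_range"] = list(self.conc_range)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload["conc_range"] = tuple(payload["conc_range"])
        return cls(**payload)


@dataclass
class DetectionLimits:
    """LoD/LoQ of a linear calibration: 3.3 and 6 × RMSE/slope.

    Raw (unrounded) values are retained; reported values are rounded to
    ``reporting_decimals``.  loq_raw/lod_raw is 6/3.3 by construction.
    """

    lod_raw: float
    loq_raw: float
    reporting_decimals: int = 1

    @property
    def lod(self) -> float:
        return round(self.lod_raw, self.reporting_decimals)

    @property
    def loq(self) -> float:
        return round(self.loq_raw, self.reporting_decimals)


@dataclass
class InvertedConcentration:
    """Result of inverting the calibration for one measured area."""

    conc: float
    sd: float
    in_range: bool


def check_standards(standards: pd.DataFrame, kind: str = "linear") -> pd.DataFrame:
    """Validate a standards table for the requested model kind."""
    missing = [c for c in ("conc_um", "area_au") if c not in standards.columns]
    if missing:
        raise StandardsError(f"standards table missing columns {missing}")
    if (standards["conc_um"] <= 0).any():
        raise StandardsError("standard concentrations must be positive")
    n_levels = standards["conc_um"].nunique()
    minimum = {"linear": 3, "parabolic": 4}.get(kind)
    if minimum is None:
        raise StandardsError(f"unknown calibration kind {kind!r}")
    if n_levels < minimum:
        raise StandardsError(
            f"{kind} fit needs >= {minimum} distinct concentration levels, got {n_levels}"
        )
    return standards


def _design(conc: np.ndarray, kind: str) -> np.ndarray:
    cols = [np.ones_like(conc), conc]
    if kind == "parabolic":
        cols.append(conc**2)
    return np.column_stack(cols)


def fit_calibration(
    standards: pd.DataFrame,
    kind: str = "linear",
    rmse_denominator: str = "n",
) -> CalibrationModel:
    """Ordinary unweighted least squares of area on concentration.

    Replicates enter as individual rows.  Standard errors come from the OLS
    coefficient covariance, R² = 1 − SS_res/SS_tot, and the model p-value from
    the overall regression F statistic.
    """
    check_standards(standards, kind)
    conc = standards["conc_um"].to_numpy(dtype=float)
    area = standards["area_au"].to_numpy(dtype=float)
    if rmse_denominator not in ("n", "n_minus_p"):
        raise ValueError("rmse_denominator must be 'n' or 'n_minus_p'")
    X = _design(conc, kind)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StandardsError("rank-deficient design: concentrations do not vary enough")
    res = sm.OLS(area, X).fit()
    n, p = X.shape
    denom = n if rmse_denominator == "n" else n - p
    rmse = float(np.sqrt(res.ssr / denom))
    coefs = res.params
    ses = res.bse
    return CalibrationModel(
        kind=kind,
        a=float(coefs[0]),
        b=float(coefs[1]),
        c=float(coefs[2]) if kind == "parabolic" else None,
        s_a=float(ses[0]),
        s_b=float(ses[1]),
        s_c=float(ses[2]) if kind == "parabolic" else None,
        r_squared=float(res.rsquared),
        rmse=rmse,
        model_p_value=float(res.f_pvalue),
        conc_range=(float(conc.min()), float(conc.max())),
        centroid_area=float(res.fittedvalues.mean()),
        n_points=int(n),
        sxx=float(np.sum((conc - conc.mean()) ** 2)),
        mean_conc=float(conc.mean()),
        rmse_denominator=rmse_denominator,
    )


def compute_lod_loq(model: CalibrationModel, reporting_decimals: int = 1) -> DetectionLimits:
    """Detection and quantification limits of a linear calibration.

    LoD = 3.3 × RMSE / slope and LoQ = 6 × RMSE / slope, reported rounded
    (default 1 decimal) with the raw values retained.
    """
    if model.kind != "linear":
        raise ValueError(
            "LoD/LoQ are defined for the linear model only; "
            "reduce the concentration range and refit linearly first"
        )
    if model.b <= 0:
        raise ValueError("slope must be positive to compute detection limits")
    return DetectionLimits(
        lod_raw=3.3 * model.rmse / model.b,
        loq_raw=6.0 * model.rmse / model.b,
        reporting_decimals=reporting_decimals,
    )


def predict_area(model: CalibrationModel, conc: float | np.ndarray) -> float | np.ndarray:
    """Forward-evaluate the calibration curve at ``conc`` (µM)."""
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0):
        raise ValueError("concentration must be non-negative")
    lo, hi = model.conc_range
    if np.any(conc_arr < lo) or np.any(conc_arr > hi):
        warnings.warn(
            f"concentration outside fitted range [{lo}, {hi}] µM", stacklevel=2
        )
    y = model.a + model.b * conc_arr
    if model.kind == "parabolic":
        y = y + model.c * conc_arr**2
    return float(y) if np.isscalar(conc) else y


def _inverse_sd(model: CalibrationModel, area: float, slope_local: float, m: int) -> float:
    # classical inverse-prediction SD: (s/b)·sqrt(1/m + 1/n + (y0 − ȳ)² / (b² Sxx))
    if model.sxx <= 0:
        return float("nan")
    term = 1.0 / m + 1.0 / model.n_points
    term += (area - model.centroid_area) ** 2 / (slope_local**2 * model.sxx)
    return float(model.rmse / abs(slope_local) * np.sqrt(term))


def invert_calibration(
    model: CalibrationModel,
    area: float,
    n_sample_reps: int = 1,
) -> InvertedConcentration:
    """Invert the calibration for a measured mean area of ``n_sample_reps`` injections.

    Linear: conc = (area − a)/b.  Parabolic: the root of c·x² + b·x + (a − area)
    lying inside the fitted range; if both or neither root qualifies, the larger
    real root ≥ 0 is returned and flagged out of range.  ``in_range`` is False
    when the concentration falls outside the fitted range or (linear) below LoQ.
    """
    if not np.isfinite(area):
        raise ValueError("area must be finite")
    if n_sample_reps < 1:
        raise ValueError("n_sample_reps must be >= 1")
    lo, hi = model.conc_range
    if model.kind == "linear":
        if model.b <= 0:
            raise ValueError("slope must be positive to invert")
        conc = (area - model.a) / model.b
        sd = _inverse_sd(model, area, model.b, n_sample_reps)
        loq = compute_lod_loq(model).loq_raw if model.rmse > 0 else 0.0
        in_range = (lo <= conc <= hi) and conc >= loq
        return InvertedConcentration(float(conc), sd, bool(in_range))
    # parabolic
    c2, b1, a0 = model.c, model.b, model.a - area
    disc = b1**2 - 4 * c2 * a0
    if disc < 0:
        raise ValueError("no real solution: area outside the reachable response range")
    roots = np.array([(-b1 - np.sqrt(disc)) / (2 * c2), (-b1 + np.sqrt(disc)) / (2 * c2)])
    inside = [r for r in roots if lo <= r <= hi]
    if len(inside) == 1:
        conc, in_range = float(inside[0]), True
    else:
        nonneg = roots[roots >= 0]
        conc = float(nonneg.max() if nonneg.size else roots.max())
        in_range = False
    slope_local = b1 + 2 * c2 * conc
    sd = _inverse_sd(model, area, slope_local, n_sample_reps) if slope_local != 0 else float("inf")
    return InvertedConcentration(conc, sd, in_range)


def reduce_range(standards: pd.DataFrame, max_conc: float) -> pd.DataFrame:
    """Keep standards with concentration ≤ ``max_conc`` µM (e.g. the 0.8–6 µM low range).

    Records a provenance note in ``DataFrame.attrs``.  Rejects the reduction if
    fewer than 3 concentration levels survive.
    """
    check_standards(standards, "linear")
    kept = standards[standards["conc_um"] <= max_conc].copy()
    n_levels = kept["conc_um"].nunique() if not kept.empty else 0
    if n_levels < 3:
        raise StandardsError(
            f"range reduction to <= {max_conc} µM leaves {n_levels} levels; need >= 3"
        )
    kept.attrs = dict(standards.attrs)
    kept.attrs["range_reduction"] = (
        f"restricted to conc_um <= {max_conc} (kept {n_levels} of "
        f"{standards['conc_um'].nunique()} levels)"
    )
    return kept
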