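"""Calibration validation: leave-one-out cross-validation, precision, matrix effect.

The calibration is validated by leave-one-out cross-validation: each
standard point is removed in turn, the curve is refitted on the remaining
points and the removed point's response is recalculated from its
concentration.  Regressing recalculated on experimental responses,
y_recalc = a + b·y_exp, should give an intercept not significantly
different from 0 and a slope not significantly different from 1.  The same
regression run on the plain fitted values (no point removed) is the
"calibration mode" reference.

Precision is summarised per concentration level as intra-day and inter-day
CV%, with a pooled-variance Student's t-test between day-1 replicates and
the other days' replicates.  The matrix effect is assessed from paired
standard/spiked-serum areas as per-level recovery fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .calibration import check_standards, _design

__all__ = [
    "CVResult",
    "PrecisionReport",
    "MatrixEffectResult",
    "loo_cv",
    "validate_recalc_regression",
    "precision_study",
    "matrix_effect_assess",
]


@dataclass
class CVResult:
    """Recalculated-vs-experimental regression line and its (0, 1) conformity verdict."""

    recalculated: np.ndarray
    line_intercept: float
    s_intercept: float
    line_slope: float
    s_slope: float
    r_squared: float
    rmse: float
    model_p_value: float
    conforms: bool
    alpha: float
    mode: str = "cv"

    def summary(self) -> str:
        verdict = "conforms" if self.conforms else "fails"
        return (
            f"{self.mode} validation line: intercept {self.line_intercept:.4g} "
            f"(s {self.s_intercept:.3g}), slope {self.line_slope:.4g} "
            f"(s {self.s_slope:.3g}), R^2 {self.r_squared:.4f} -> {verdict} "
            f"(alpha {self.alpha})"
        )


@dataclass
class PrecisionReport:
    """Per-level intra-day / inter-day precision and replicate comparability."""

    intra_day: pd.DataFrame
    inter_day: pd.DataFrame | None
    t_tests: pd.DataFrame | None
    alpha: float
    flags: set = field(default_factory=set)

    @property
    def passes(self) -> bool:
        """True when no per-level t-test falls below alpha (or tests are degenerate)."""
        if self.t_tests is None:
            return True
        p = self.t_tests["p_value"].dropna()
        return bool((p >= self.alpha).all())


@dataclass
class MatrixEffectResult:
    """Per-level spiked/standard recovery and the trapping verdict."""

    recoveries: pd.DataFrame
    concentration_dependent: bool
    tolerance: float

    @property
    def verdict(self) -> str:
        return (
            "concentration-dependent trapping"
            if self.concentration_dependent
            else "no concentration-dependent trapping"
        )


def loo_cv(standards: pd.DataFrame, kind: str = "linear") -> np.ndarray:
    """Leave-one-out recalculated responses, one per standards row, input order.

    For each row i the model is fitted on all other rows and evaluated at
    concentration i.  For OLS this equals the exact hat-matrix identity
    y_hat_(i) = y_i − e_i/(1 − h_ii), which is what is computed; tests verify
    it against an explicit fold-by-fold refit.
    """
    check_standards(standards, kind)
    conc = standards["conc_um"].to_numpy(dtype=float)
    area = standards["area_au"].to_numpy(dtype=float)
    X = _design(conc, kind)
    n, p = X.shape
    if n <= p:
        raise ValueError("too few rows for leave-one-out refits")
    beta, _, rank, _ = np.linalg.lstsq(X, area, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design: concentrations do not vary enough")
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    if np.any(h > 1 - 1e-10):
        i = int(np.argmax(h))
        raise ValueError(
            f"leave-one-out subfit without row {i} is rank-deficient "
            "(the row is the only support for a model term)"
        )
    resid = area - X @ beta
    return area - resid / (1.0 - h)


def validate_recalc_regression(
    experimental: np.ndarray,
    recalculated: np.ndarray,
    alpha: float = 0.05,
    mode: str = "cv",
    joint: bool = False,
) -> CVResult:
    """OLS of recalculated on experimental responses with the (0, 1) conformity test.

    ``conforms`` is true when coefficient t-tests accept intercept = 0 and
    slope = 1 at ``alpha`` (two-sided, n−2 df); ``joint=True`` instead uses the
    joint F-test of (intercept, slope) = (0, 1).  ``mode`` is a label: "cv" for
    leave-one-out responses, "calibration" for plain fitted values.
    """
    y_exp = np.asarray(experimental, dtype=float)
    y_rec = np.asarray(recalculated, dtype=float)
    if y_exp.shape != y_rec.shape or y_exp.ndim != 1:
        raise ValueError("experimental and recalculated must be 1-D of equal length")
    if y_exp.size < 3:
        raise ValueError("need at least 3 points")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if np.ptp(y_exp) == 0:
        raise ValueError("experimental responses have zero variance")
    X = sm.add_constant(y_exp)
    res = sm.OLS(y_rec, X).fit()
    (a, b), (s_a, s_b) = res.params, res.bse
    n = y_exp.size
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    # numerically exact recalculation (noiseless data) conforms by construction
    tol = 1e-9 * max(1.0, float(np.abs(y_exp).max()))
    if joint:
        ftest = res.f_test((np.eye(2), np.array([0.0, 1.0])))
        exact = abs(a) <= tol and abs(b - 1) <= tol
        conforms = exact or float(np.squeeze(ftest.pvalue)) >= alpha
    else:
        ok_a = abs(a) <= tol or (s_a > 0 and abs(a) / s_a <= tcrit)
        ok_b = abs(b - 1) <= tol or (s_b > 0 and abs(b - 1) / s_b <= tcrit)
        conforms = bool(ok_a and ok_b)
    return CVResult(
        recalculated=y_rec,
        line_intercept=float(a),
        s_intercept=float(s_a),
        line_slope=float(b),
        s_slope=float(s_b),
        r_squared=float(res.rsquared),
        rmse=float(np.sqrt(res.ssr / n)),
        model_p_value=float(res.f_pvalue),
        conforms=conforms,
        alpha=alpha,
        mode=mode,
    )


def precision_study(standards: pd.DataFrame, alpha: float = 0.05) -> PrecisionReport:
    """Intra-/inter-day precision per concentration level.

    Intra-day statistics pool replicates within each day; inter-day statistics
    are taken across day means.  Per level, a two-sided pooled-variance
    Student's t-test compares day-1 replicates with the other days' replicates;
    the study passes when no p-value falls below ``alpha``.  Zero-variance
    groups are reported as non-significant with a flag.
    """
    for col in ("conc_um", "area_au", "day"):
        if col not in standards.columns:
            raise ValueError(f"precision study needs a {col!r} column")
    flags: set[str] = set()
    g = standards.groupby(["conc_um", "day"])["area_au"]
    if (g.count() < 2).any():
        raise ValueError("need >= 2 replicates per level per day")
    intra = g.agg(mean="mean", sd="std").reset_index()
    intra["cv_percent"] = np.where(
        intra["mean"] != 0, 100 * intra["sd"] / intra["mean"].abs(), np.nan
    )
    days = sorted(standards["day"].unique())
    if len(days) < 2:
        flags.add("single_day")
        return PrecisionReport(intra_day=intra, inter_day=None, t_tests=None, alpha=alpha, flags=flags)
    day_means = (
        standards.groupby(["conc_um", "day"])["area_au"].mean().reset_index()
    )
    inter = day_means.groupby("conc_um")["area_au"].agg(mean="mean", sd="std").reset_index()
    inter["cv_percent"] = np.where(
        inter["mean"] != 0, 100 * inter["sd"] / inter["mean"].abs(), np.nan
    )
    rows = []
    ref_day = days[0]
    for conc, level in standards.groupby("conc_um"):
        x = level.loc[level["day"] == ref_day, "area_au"].to_numpy()
        y = level.loc[level["day"] != ref_day, "area_au"].to_numpy()
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            if np.allclose(x.mean(), y.mean()):
                flags.add("zero_variance")
                rows.append((conc, np.nan, 1.0, True))
                continue
        t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append((conc, float(t), float(p), bool(np.isnan(p))))
    t_tests = pd.DataFrame(rows, columns=["conc_um", "t_statistic", "p_value", "degenerate"])
    return PrecisionReport(intra_day=intra, inter_day=inter, t_tests=t_tests, alpha=alpha, flags=flags)


def matrix_effect_assess(
    standard_areas: dict[float, float],
    spiked_areas: dict[float, float],
    tolerance: float = 0.05,
) -> MatrixEffectResult:
    """Per-level recovery = spiked/standard and the trapping verdict.

    The verdict is "concentration-dependent trapping" when recovery drops by
    more than ``tolerance`` (as a fraction, default 5 percentage points) from
    the lowest to the highest concentration.
    """
    if set(standard_areas) != set(spiked_areas):
        raise ValueError("standard and spiked maps must share the same concentration keys")
    if not standard_areas:
        raise ValueError("no concentration levels given")
    levels = sorted(standard_areas)
    recs = []
    for conc in levels:
        std = standard_areas[conc]
        if std == 0:
            raise ValueError(f"zero standard area at {conc} µM")
        recs.append(spiked_areas[conc] / std)
    df = pd.DataFrame({"conc_um": levels, "recovery": recs})
    dependent = bool(len(recs) >= 2 and (recs[0] - recs[-1]) > tolerance)
    return MatrixEffectResult(recoveries=df, concentration_dependent=dependent, tolerance=tolerance)
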