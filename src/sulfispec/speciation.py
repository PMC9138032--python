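"""H2S three-pool speciation arithmetic, cohort statistics, and the SDB mass check.

Serum sulfide is measured in three treatment arms: the free arm (direct
derivatization) responds to free H2S/HS-/S2-; the acid arm (pH 2.6
liberation) additionally releases the acid-labile pool (iron-sulfur
clusters); the total arm (acid + TCEP reduction) additionally releases
bound sulfane sulfur.  The derived pools are differences:

    acid-labile sulfide  = acid level  - free level
    bound sulfane sulfur = total level - acid level

so free + acid-labile + bound-sulfane = total by construction.

Cohort inference follows the clinical design: four patients sampled before
treatment (T0), immediately after the 12-day inhalation cycle (T1) and
three days later (T2); per species, a one-way repeated-measures ANOVA
(patient as the block) followed by Dunnett-adjusted comparisons of each
timepoint against T0.

The identity of the sulfide-dibimane (SDB) product is checked by its
monoisotopic mass: C20H22N4O4S (two bimane moieties bridged by sulfur),
[M+H]+ at m/z 415.14.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.anova import AnovaRM

from .calibration import CalibrationModel, invert_calibration

__all__ = [
    "SDB_FORMULA",
    "SpeciationResult",
    "ElementalFormula",
    "ArmQuantification",
    "speciate",
    "quantify_arm",
    "cohort_stats",
    "monoisotopic_mz",
    "dunnett_max_abs_t_cdf",
]

ELECTRON_MASS = 0.000548579909065  # u
PROTON_MASS = 1.00782503207 - ELECTRON_MASS  # u, 1H minus one electron


@dataclass
class ElementalFormula:
    """An elemental composition with an optional protonation adduct and charge."""

    elements: dict
    adduct: str = "none"
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("formula must contain at least one element")
        for el, n in self.elements.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}")
        if self.adduct not in ("none", "plus_H"):
            raise ValueError(f"unknown adduct {self.adduct!r}")


#: Sulfide dibimane, the product of two MBB molecules bridging one sulfide.
SDB_FORMULA = ElementalFormula({"C": 20, "H": 22, "N": 4, "O": 4, "S": 1}, adduct="plus_H", charge=1)


def monoisotopic_mz(formula: ElementalFormula, decimals: int | None = 2) -> float:
    """Monoisotopic m/z (or neutral mass when charge is 0) of a formula.

    Element masses come from the NIST monoisotopic table; a ``plus_H`` adduct
    adds one proton per |charge|, and the result is divided by |charge| when
    charged.  ``decimals=None`` returns the unrounded value.
    """
    total = 0.0
    for el, n in formula.elements.items():
        try:
            total += n * _ptmass.nist_mass[el][0][0]
        except KeyError:
            raise ValueError(f"unknown element symbol {el!r}") from None
    if formula.charge == 0:
        if formula.adduct != "none":
            raise ValueError("an adduct implies a charge; set charge accordingly")
        value = total
    else:
        if formula.adduct == "plus_H":
            total += PROTON_MASS * abs(formula.charge)
        value = total / abs(formula.charge)
    return value if decimals is None else round(value, decimals)


@dataclass
class SpeciationResult:
    """Free / acid / total measurements and the derived pool levels (µM)."""

    free: float
    acid: float
    total: float
    acid_labile: float
    bound_sulfane: float
    flags: set = field(default_factory=set)


def speciate(free: float, acid: float, total: float, loq: float = 0.0) -> SpeciationResult:
    """Apply the three-pool difference arithmetic to one sample's arm levels.

    Values below ``loq`` are flagged ``below_loq``; negative differences are
    preserved (never clipped) and flagged ``negative_difference``.
    """
    for name, v in (("free", free), ("acid", acid), ("total", total)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} level must be finite and >= 0")
    acid_labile = acid - free
    bound_sulfane = total - acid
    flags: set[str] = set()
    if any(v < loq for v in (free, acid, total)):
        flags.add("below_loq")
    if acid_labile < 0 or bound_sulfane < 0:
        flags.add("negative_difference")
    return SpeciationResult(free, acid, total, acid_labile, bound_sulfane, flags)


@dataclass
class ArmQuantification:
    """Mean concentration over replicate injections of one arm."""

    conc: float
    sd: float
    per_injection: np.ndarray
    flags: set = field(default_factory=set)


def quantify_arm(model: CalibrationModel, areas: list[float] | np.ndarray) -> ArmQuantification:
    """Concentration of one arm from its replicate-injection SDB areas.

    Each injection is inverted through the linear calibration; the sample
    concentration is their mean, with the inverse-prediction SD propagated at
    m = number of injections.  Out-of-range or below-LoQ injections are
    flagged, never dropped.
    """
    if model.kind != "linear":
        raise ValueError("arm quantification uses the linear calibration model")
    areas = np.asarray(areas, dtype=float)
    if areas.ndim != 1 or areas.size == 0:
        raise ValueError("areas must be a non-empty 1-D sequence")
    per = np.array([invert_calibration(model, float(a)).conc for a in areas])
    mean_area = float(areas.mean())
    pooled = invert_calibration(model, mean_area, n_sample_reps=areas.size)
    flags = set() if pooled.in_range else {"out_of_range"}
    return ArmQuantification(conc=float(per.mean()), sd=pooled.sd, per_injection=per, flags=flags)


# ---------------------------------------------------------------------------
# Dunnett-vs-control adjustment for paired (repeated-measures) contrasts.
# ---------------------------------------------------------------------------

def dunnett_max_abs_t_cdf(u: float, df: int, rho: float, k: int, n_z: int = 64, n_s: int = 256) -> float:
    """P(max_j |T_j| <= u) for k equicorrelated central t variates.

    T_j = X_j / S with X_j standard normal, corr(X_i, X_j) = rho, and
    S^2 ~ chi2(df)/df shared by all contrasts — the classical Dunnett
    two-sided probability, evaluated by Gauss-Hermite quadrature over the
    shared normal factor and fixed-order quadrature over the chi density.
    """
    if u <= 0:
        return 0.0
    if k == 1:
        return float(2 * stats.t.cdf(u, df) - 1)
    rho = min(max(rho, 0.0), 0.999)
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_z)  # weight exp(-z^2/2)
    gh_w = gh_w / np.sqrt(2 * np.pi)
    s_hi = np.sqrt(stats.chi2.ppf(1 - 1e-12, df) / df)
    s = np.linspace(1e-9, s_hi, n_s)
    # density of S where S^2 ~ chi2(df)/df
    log_fs = (
        np.log(2.0)
        + (df / 2) * np.log(df / 2.0)
        - gammaln(df / 2.0)
        + (df - 1) * np.log(s)
        - df * s**2 / 2.0
    )
    fs = np.exp(log_fs)
    sq = np.sqrt(1 - rho)
    z = gh_x[:, None]
    us = u * s[None, :]
    upper = stats.norm.cdf((us - np.sqrt(rho) * z) / sq)
    lower = stats.norm.cdf((-us - np.sqrt(rho) * z) / sq)
    inner = np.clip(upper - lower, 0.0, 1.0) ** k
    g = gh_w @ inner  # integral over z, for each s
    return float(np.clip(np.trapezoid(g * fs, s), 0.0, 1.0))


def _dunnett_paired(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dunnett-adjusted two-sided p-values for paired contrasts vs control.

    ``diffs`` is n_subjects × k (each column a timepoint-minus-control
    difference).  Per-contrast t statistics use the paired SD with n−1 df;
    the max-|T| adjustment uses the average off-diagonal correlation of the
    difference columns (multivariate-t quadrature, deterministic).
    """
    n, k = diffs.shape
    means = diffs.mean(axis=0)
    sds = diffs.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ZeroDivisionError("zero variance in paired differences")
    tstats = means / (sds / np.sqrt(n))
    df = n - 1
    if k == 1:
        return tstats, np.array([2 * stats.t.sf(abs(tstats[0]), df)])
    corr = np.corrcoef(diffs, rowvar=False)
    rho = float(np.mean(corr[np.triu_indices(k, 1)]))
    padj = np.array(
        [1.0 - dunnett_max_abs_t_cdf(abs(t), df, rho, k) for t in tstats]
    )
    return tstats, np.clip(padj, 0.0, 1.0)


def cohort_stats(
    cohort: pd.DataFrame,
    reference: str = "T0",
    species: list[str] | None = None,
    anova_correction: str = "none",
) -> pd.DataFrame:
    """Per-species timepoint effects in a repeated-measures cohort.

    For each species: percent change of the mean at each timepoint relative to
    ``reference``, the one-way repeated-measures ANOVA p-value (patient as the
    repeated block; ``anova_correction='gg'`` applies Greenhouse-Geisser), and
    Dunnett-adjusted p-values for each non-reference timepoint vs the
    reference.  Rows with zero variance are flagged instead of given p-values.
    Missing patient × timepoint cells are rejected by name.
    """
    required = {"patient_id", "timepoint", "species", "concentration_um"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    if anova_correction not in ("none", "gg"):
        raise ValueError("anova_correction must be 'none' or 'gg'")
    out_rows = []
    all_species = sorted(cohort["species"].unique()) if species is None else species
    timepoints = sorted(cohort["timepoint"].unique())
    if reference not in timepoints:
        raise ValueError(f"reference timepoint {reference!r} absent from cohort")
    if cohort["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    for sp in all_species:
        sub = cohort[cohort["species"] == sp]
        wide = sub.pivot_table(
            index="patient_id", columns="timepoint", values="concentration_um"
        )
        missing = wide.isna()
        if missing.any().any():
            pid = missing.any(axis=1).idxmax()
            tp = missing.loc[pid].idxmax()
            raise ValueError(f"missing cell: patient {pid}, timepoint {tp}, species {sp}")
        ref_mean = wide[reference].mean()
        # no within-subject spread at all -> ANOVA and Dunnett are undefined
        zero_var = bool(np.ptp(wide.to_numpy() - wide.to_numpy()[:, [0]]) == 0)
        anova_p = np.nan
        if not zero_var:
            long = wide.reset_index().melt(
                id_vars="patient_id", var_name="timepoint", value_name="concentration_um"
            )
            try:
                aov = AnovaRM(
                    long, depvar="concentration_um", subject="patient_id", within=["timepoint"]
                ).fit()
                anova_p = float(aov.anova_table["Pr > F"].iloc[0])
                if anova_correction == "gg":
                    eps = _greenhouse_geisser_epsilon(wide.to_numpy())
                    f = float(aov.anova_table["F Value"].iloc[0])
                    df1 = float(aov.anova_table["Num DF"].iloc[0]) * eps
                    df2 = float(aov.anova_table["Den DF"].iloc[0]) * eps
                    anova_p = float(stats.f.sf(f, df1, df2))
            except Exception:
                zero_var = True
        others = [tp for tp in timepoints if tp != reference]
        diffs = wide[others].to_numpy() - wide[[reference]].to_numpy()
        dunnett = {tp: np.nan for tp in others}
        degenerate = zero_var
        if not zero_var:
            try:
                _, padj = _dunnett_paired(diffs)
                dunnett = dict(zip(others, padj))
            except ZeroDivisionError:
                degenerate = True
        for tp in timepoints:
            pct = 0.0 if tp == reference else 100 * (wide[tp].mean() - ref_mean) / ref_mean
            out_rows.append(
                {
                    "species": sp,
                    "timepoint": tp,
                    "mean_um": float(wide[tp].mean()),
                    "sd_um": float(wide[tp].std(ddof=1)),
                    "percent_change": float(pct),
                    "rm_anova_p": anova_p,
                    "dunnett_p": np.nan if tp == reference else dunnett.get(tp, np.nan),
                    "zero_variance": degenerate,
                }
            )
    return pd.DataFrame(out_rows)


def _greenhouse_geisser_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor from an n × k matrix."""
    k = data.shape[1]
    cov = np.cov(data, rowvar=False)
    mean_diag = np.trace(cov) / k
    grand = cov.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(cov**2) - 2 * k * np.sum(cov.mean(axis=1) ** 2) + k**2 * grand**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))
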