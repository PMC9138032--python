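"""Synthetic data generators for the MBB/HPLC-FLD sulfide workflow.

Everything the pipeline consumes can be simulated here under explicit seeds:
FLD chromatograms with the SDB product near 11.8 min and the MBB reagent
excess near 12.8 min, calibration standards tables at the seven-level
0.8-50 µM series, a small serum cohort sampled at T0/T1/T2 around an
inhalation treatment, and paired standard/spiked-serum areas showing the
concentration-dependent matrix trapping of sulfide.

Every generator is a pure function of its arguments including the seed, and
noiseless outputs are exactly invertible by the corresponding estimation
stage (calibration refit, speciation arithmetic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from .calibration import CalibrationModel, PAPER_STANDARD_LEVELS_UM
from .chromatograms import Chromatogram, MBB_RETENTION_MIN, SDB_RETENTION_MIN

__all__ = [
    "PeakSpec",
    "CohortScenario",
    "MatrixEffectCurve",
    "TABLE_AREA_PRESETS",
    "default_linear_truth",
    "default_parabolic_truth",
    "gen_chromatogram",
    "gen_calibration_dataset",
    "gen_serum_cohort",
    "gen_matrix_effect_pairs",
    "gen_arm_areas",
    "cohort_with_total",
]

#: Preset SDB area pairs (LU·min) for scenario documentation: response of a
#: 12.5 µM Na2S standard, a serum sample and a simulated body fluid at room
#: temperature vs 50 °C (derivatization yield roughly triples with heating,
#: and heated SBF releases protein-bound sulfide).
TABLE_AREA_PRESETS = {
    "na2s_12.5um": {"rt": 270.0, "50C": 800.0},
    "serum": {"rt": 63.0, "50C": 207.0},
    "sbf": {"rt": 2.0, "50C": 230.0},
}

POOL_SPECIES = ("free", "acid_labile", "bound_sulfane")
TIMEPOINTS = ("T0", "T1", "T2")


def _eval_response(model: CalibrationModel, conc: float) -> float:
    # forward curve without the out-of-range warning of predict_area: the true
    # generating model is deliberately evaluated wherever a scenario asks
    y = model.a + model.b * conc
    if model.kind == "parabolic":
        y += model.c * conc**2
    return float(y)


def default_linear_truth() -> CalibrationModel:
    """The reference low-range linear response: area = −0.581 + 3.51·conc (AU, µM)."""
    return CalibrationModel(
        kind="linear",
        a=-0.581,
        b=3.51,
        s_a=0.260,
        s_b=0.0749,
        r_squared=0.995,
        rmse=0.514,
        model_p_value=4.77e-13,
        conc_range=(0.8, 6.0),
        centroid_area=-0.581 + 3.51 * 2.85,
        n_points=20,
        sxx=5 * float(np.sum((np.array([0.8, 1.6, 3.0, 6.0]) - 2.85) ** 2)),
        mean_conc=2.85,
    )


def default_parabolic_truth() -> CalibrationModel:
    """The reference full-range parabolic response over 0.8–50 µM."""
    levels = np.array(PAPER_STANDARD_LEVELS_UM)
    fitted = -13.2 + 5.87 * levels + 0.358 * levels**2
    return CalibrationModel(
        kind="parabolic",
        a=-13.2,
        b=5.87,
        c=0.358,
        s_a=6.61,
        s_b=0.930,
        s_c=0.0181,
        r_squared=0.998,
        rmse=18.16,
        model_p_value=2.2e-16,
        conc_range=(0.8, 50.0),
        centroid_area=float(fitted.mean()),
        n_points=35,
        sxx=5 * float(np.sum((levels - levels.mean()) ** 2)),
        mean_conc=float(levels.mean()),
    )


@dataclass
class PeakSpec:
    """A simulated chromatographic peak.

    ``shape='gaussian'`` gives height·exp(−(t−t_R)²/2σ²); ``shape='emg'``
    convolves that Gaussian with an exponential tail of time constant
    ``tail_tau`` (area-preserving, apex shifts slightly late).
    """

    retention_time: float
    height: float
    width_sigma: float
    shape: str = "gaussian"
    tail_tau: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"peak {self.label or '?'}: height must be >= 0")
        if self.width_sigma <= 0:
            raise ValueError(f"peak {self.label or '?'}: width_sigma must be > 0")
        if self.shape not in ("gaussian", "emg"):
            raise ValueError(f"peak {self.label or '?'}: unknown shape {self.shape!r}")
        if self.shape == "emg" and self.tail_tau <= 0:
            raise ValueError(f"peak {self.label or '?'}: emg needs tail_tau > 0")

    def profile(self, t: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return self.height * np.exp(-((t - self.retention_time) ** 2) / (2 * self.width_sigma**2))
        # EMG normalised to the same total area as the Gaussian
        area = self.height * self.width_sigma * math.sqrt(2 * math.pi)
        k = self.tail_tau / self.width_sigma
        return area * exponnorm.pdf(t, K=k, loc=self.retention_time, scale=self.width_sigma)


def sdb_mbb_peaks(sdb_height: float = 100.0, mbb_height: float = 300.0, width_sigma: float = 0.05) -> list[PeakSpec]:
    """Convenience pair of reference peaks at the SDB and MBB retention times."""
    return [
        PeakSpec(SDB_RETENTION_MIN, sdb_height, width_sigma, label="SDB"),
        PeakSpec(MBB_RETENTION_MIN, mbb_height, width_sigma, label="MBB"),
    ]


def gen_chromatogram(
    peaks: list[PeakSpec],
    duration: float = 23.0,
    sampling_rate: float = 300.0,
    baseline_level: float = 0.0,
    drift_slope: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Chromatogram:
    """Simulate an FLD trace on a uniform grid of ceil(duration × sampling_rate) points.

    Defaults mirror the reference separation: a 23-minute run read at 5 points
    per second.  Identical arguments and seed reproduce the trace bit-for-bit.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for p in peaks:
        if not (0.0 <= p.retention_time <= duration):
            raise ValueError(
                f"peak {p.label or '?'} at {p.retention_time} min outside [0, {duration}]"
            )
    n = math.ceil(duration * sampling_rate)
    t = np.arange(n) / sampling_rate
    y = baseline_level + drift_slope * t
    for p in peaks:
        y = y + p.profile(t)
    rng = np.random.default_rng(seed)
    y = y + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else y
    meta = {
        "detector": "FLD",
        "excitation_nm": 390,
        "emission_nm": 475,
        "gradient": "water/acetonitrile + 0.1% TFA, 85:15 to 55:45 over 16 min, 23 min total",
        "seed": seed,
    }
    return Chromatogram(t, y, meta)


def gen_calibration_dataset(
    true_model: CalibrationModel | None = None,
    conc_levels: list[float] | None = None,
    replicates_per_level: int = 5,
    noise_sd: float = 0.514,
    n_days: int = 3,
    day_effect_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a standards table: area = model prediction + day offset + replicate noise.

    Defaults follow the reference protocol — five replicates of each level on
    each of three days, replicate noise at the linear model's residual scatter
    (0.514 AU).  Day offsets are additive on area and shared by all levels of a
    day; their magnitude defaults to 0 so the default noise model is pure
    replicate scatter.  With ``noise_sd=0`` and ``day_effect_sd=0`` the areas
    equal the model predictions exactly.
    """
    if true_model is None:
        true_model = default_linear_truth()
    levels = np.asarray(
        PAPER_STANDARD_LEVELS_UM if conc_levels is None else conc_levels, dtype=float
    )
    if levels.size == 0 or np.any(levels <= 0):
        raise ValueError("conc_levels must be non-empty and positive")
    if replicates_per_level < 1 or n_days < 1:
        raise ValueError("replicates_per_level and n_days must be >= 1")
    rng = np.random.default_rng(seed)
    day_offsets = (
        rng.normal(0.0, day_effect_sd, size=n_days) if day_effect_sd > 0 else np.zeros(n_days)
    )
    rows = []
    for day in range(1, n_days + 1):
        for conc in levels:
            mu = _eval_response(true_model, float(conc)) + day_offsets[day - 1]
            noise = rng.normal(0.0, noise_sd, size=replicates_per_level) if noise_sd > 0 else np.zeros(replicates_per_level)
            for rep in range(1, replicates_per_level + 1):
                rows.append((float(conc), float(mu + noise[rep - 1]), day, rep))
    return pd.DataFrame(rows, columns=["conc_um", "area_au", "day", "replicate"])


@dataclass
class CohortScenario:
    """Study conditions for a simulated serum cohort sampled at T0/T1/T2.

    The treatment raises the expected total sulfide at T2 by
    ``t2_total_increase`` (the extra sulfide loads onto the acid-labile and
    bound-sulfane pools) while the free pool changes by ``free_change``
    (default: unchanged).  T1 applies ``t1_fraction`` of the T2 effect.
    Patient offsets (SD ``between_patient_sd``) are constant across
    timepoints within a patient; replicate noise is i.i.d. per row.
    """

    n_patients: int = 4
    pool_means_t0: dict = field(
        default_factory=lambda: {"free": 0.6, "acid_labile": 1.2, "bound_sulfane": 1.5}
    )
    t2_total_increase: float = 0.4
    free_change: float = 0.0
    t1_fraction: float = 0.5
    between_patient_sd: float = 0.3
    within_replicate_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if set(self.pool_means_t0) != set(POOL_SPECIES):
            raise ValueError(f"pool_means_t0 must provide exactly {POOL_SPECIES}")
        if any(v < 0 for v in self.pool_means_t0.values()):
            raise ValueError("pool means must be >= 0")
        if self.t2_total_increase <= -1 or self.free_change <= -1:
            raise ValueError("effect fractions must exceed -1")
        if self.between_patient_sd < 0 or self.within_replicate_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def expected_pools(self, timepoint: str) -> dict[str, float]:
        """Noiseless pool expectations (µM) at a timepoint."""
        f = {"T0": 0.0, "T1": self.t1_fraction, "T2": 1.0}[timepoint]
        free0 = self.pool_means_t0["free"]
        al0 = self.pool_means_t0["acid_labile"]
        bs0 = self.pool_means_t0["bound_sulfane"]
        total0 = free0 + al0 + bs0
        free_k = free0 * (1 + f * self.free_change)
        target_total = (1 + f * self.t2_total_increase) * total0
        gain = (target_total - free_k) / (al0 + bs0) if (al0 + bs0) > 0 else 0.0
        return {"free": free_k, "acid_labile": gain * al0, "bound_sulfane": gain * bs0}


def gen_serum_cohort(scenario: CohortScenario) -> pd.DataFrame:
    """Simulate pool concentrations for every patient × timepoint × species.

    The three pools are generated and any total a consumer needs is their sum,
    so free + acid_labile + bound_sulfane always equals the implied total.
    Concentrations are clipped at zero (only reachable under large noise).
    """
    rng = np.random.default_rng(scenario.seed)
    patient_offsets = {
        pid: {
            sp: rng.normal(0.0, scenario.between_patient_sd) if scenario.between_patient_sd > 0 else 0.0
            for sp in POOL_SPECIES
        }
        for pid in range(1, scenario.n_patients + 1)
    }
    rows = []
    for pid in range(1, scenario.n_patients + 1):
        for tp in TIMEPOINTS:
            means = scenario.expected_pools(tp)
            for sp in POOL_SPECIES:
                value = means[sp] + patient_offsets[pid][sp]
                if scenario.within_replicate_sd > 0:
                    value += rng.normal(0.0, scenario.within_replicate_sd)
                rows.append((f"P{pid}", tp, sp, max(value, 0.0)))
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "species", "concentration_um"])


def cohort_with_total(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append 'total' rows (sum of the three pools) to a pool-level cohort table."""
    if "total" in cohort["species"].unique():
        return cohort
    totals = (
        cohort[cohort["species"].isin(POOL_SPECIES)]
        .groupby(["patient_id", "timepoint"], as_index=False)["concentration_um"]
        .sum()
    )
    totals["species"] = "total"
    return pd.concat([cohort, totals[cohort.columns.tolist()]], ignore_index=True)


@dataclass
class MatrixEffectCurve:
    """Concentration-dependent recovery of spiked sulfide in serum.

    ``recovery_at_level`` maps Na2S spike concentration (µM) to the fraction
    of the standard-solution SDB area retained in spiked serum.  The default
    anchors reproduce the reference standard/spiked area ratios 25/22,
    180/100 and 400/200 at 5, 12.5 and 25 µM — recovery falls as more sulfide
    is trapped by the serum matrix.  Between anchors the recovery is
    interpolated log-linearly in concentration.
    """

    recovery_at_level: dict = field(
        default_factory=lambda: {5.0: 22.0 / 25.0, 12.5: 100.0 / 180.0, 25.0: 200.0 / 400.0}
    )

    def __post_init__(self) -> None:
        if not self.recovery_at_level:
            raise ValueError("need at least one recovery anchor")
        for conc, frac in self.recovery_at_level.items():
            if conc <= 0:
                raise ValueError("anchor concentrations must be positive")
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"recovery at {conc} µM is {frac}; must be in (0, 1]")

    def recovery(self, conc: float) -> float:
        if conc <= 0:
            raise ValueError("concentration must be positive")
        anchors = sorted(self.recovery_at_level.items())
        xs = np.log(np.array([a for a, _ in anchors]))
        ys = np.array([r for _, r in anchors])
        return float(np.interp(np.log(conc), xs, ys))


def gen_matrix_effect_pairs(
    conc_levels: list[float] | None = None,
    curve: MatrixEffectCurve | None = None,
    true_model: CalibrationModel | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired SDB areas for standard solutions vs spiked serum at each level.

    Standard areas come from the forward calibration; spiked areas are
    recovery × standard (plus optional noise).
    """
    if curve is None:
        curve = MatrixEffectCurve()
    if true_model is None:
        true_model = default_parabolic_truth()
    levels = [5.0, 12.5, 25.0] if conc_levels is None else list(conc_levels)
    rng = np.random.default_rng(seed)
    rows = []
    for conc in levels:
        rec = curve.recovery(conc)
        if not (0.0 < rec <= 1.0):
            raise ValueError(f"interpolated recovery {rec} at {conc} µM outside (0, 1]")
        standard = _eval_response(true_model, conc)
        spiked = rec * standard
        if noise_sd > 0:
            standard += rng.normal(0.0, noise_sd)
            spiked += rng.normal(0.0, noise_sd)
        rows.append((conc, standard, spiked, rec))
    return pd.DataFrame(rows, columns=["conc_um", "standard_area_au", "spiked_area_au", "recovery"])


def gen_arm_areas(
    cohort: pd.DataFrame,
    model: CalibrationModel | None = None,
    n_injections: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn cohort pool concentrations into per-injection SDB areas for the three arms.

    The free arm responds to the free pool, the acid arm to free + acid-labile,
    and the total arm to free + acid-labile + bound-sulfane; each sample is
    injected ``n_injections`` times with i.i.d. area noise.
    """
    if model is None:
        model = default_linear_truth()
    rng = np.random.default_rng(seed)
    pools = cohort[cohort["species"].isin(POOL_SPECIES)].pivot_table(
        index=["patient_id", "timepoint"], columns="species", values="concentration_um"
    )
    rows = []
    for (pid, tp), r in pools.iterrows():
        arm_conc = {
            "free": r["free"],
            "acid": r["free"] + r["acid_labile"],
            "total": r["free"] + r["acid_labile"] + r["bound_sulfane"],
        }
        for arm, conc in arm_conc.items():
            mu = _eval_response(model, float(conc))
            for inj in range(1, n_injections + 1):
                area = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((pid, tp, arm, inj, float(area)))
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "arm", "injection", "area_au"])
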