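# Methods

This note documents the models, defaults and numerical choices behind
`sulfispec`, and what its synthetic-data generators do and do not emulate.

## Assay model

The MBB/HPLC-FLD assay measures sulfide via its fluorescent derivative
sulfide dibimane (SDB).  Each serum sample is measured in three arms —
direct derivatization (free), acid liberation at pH 2.6 (acid), and acid +
TCEP reduction (total) — and the pools are differences: acid-labile =
acid − free, bound sulfane = total − acid.  Negative differences (possible
under noise when a pool is near zero) are reported as-is and flagged
`negative_difference`, never clipped: clipping would silently bias pool
sums and break the conservation identity free + acid-labile +
bound-sulfane = total, which the package preserves exactly on every output
row.

## Chromatograms and integration

Chromatograms are uniform time grids (minutes) of FLD intensity (LU);
reference landmarks are the SDB apex at 11.8 min and the MBB reagent
excess at 12.8 min, with identity assigned by nearest reference retention
time within a tolerance (default 0.2 min — one fifth of the SDB–MBB gap,
so the two cannot be confused; a contested reference goes to the closer
apex and the loser stays `unknown`).

Peak areas are trapezoidal integrals over a window after baseline
subtraction; the default baseline is the chord joining the window
endpoints (`linear_endpoints`), chosen because it is the simplest
auditable rule and is exactly invariant to constant intensity offsets.
Integration is additive over adjacent windows (baseline `none`) and, on
noiseless Gaussians sampled at ≥ 20 points per σ, accurate to better than
0.1%.

Peak detection is `scipy.signal.find_peaks` (height + prominence) with two
additions: an optional Gaussian pre-smoothing (`smooth_sigma`, minutes) —
a matched-filter-style step that stabilises apex location on noisy traces
— and sub-sample apex refinement by a local parabola.  Integration windows
start from the prominence bases, are truncated at the inter-peak valley
for adjacent peaks, and are tightened to apex ± 4σ with σ estimated from
the half-height width; without this last step the bases land on distant
noise minima and the baseline chord anchors systematically low.  Areas are
always integrated on the raw (unsmoothed) signal.  Overlapping peaks
(apices closer than `merge_window`, default 0.2 min) are reported
separately and flagged, not deconvolved: no curve fitting keeps the area
operator deterministic.

## Calibration

Standards follow the seven-level series 0.8, 1.6, 3, 6, 12.5, 25, 50 µM.
Fits are ordinary unweighted least squares with replicates as individual
rows (no level averaging, no variance weighting).  The full range needs
the parabolic model y = a + bx + cx²; the reduced 0.8–6 µM range — whose
centroid sits near the response region of real serum samples — supports
the linear model used for quantification.

**RMSE convention.**  RMSE defaults to √(SS_res/n) — the root of the plain
mean squared residual — with an `n_minus_p` option for the unbiased
variant.  The reported detection limits LoD = 3.3·RMSE/b and
LoQ = 6·RMSE/b are rounded to 1 decimal (raw values retained); their raw
ratio is 6/3.3 identically.

**Inverse prediction.**  Linear: x₀ = (y₀ − a)/b with
sd = (RMSE/b)·√(1/m + 1/n + (y₀ − ȳ)²/(b²·Sxx)), m = sample replicates,
which is minimal at the centroid ȳ and grows outward.  Parabolic: the root
of c·x² + b·x + (a − y₀) inside the fitted range; if both or neither root
qualifies, the larger real root ≥ 0 is returned flagged out of range.  Its
sd uses the local slope b + 2cx₀ in place of b (delta method).  A result
is `in_range` only when inside the fitted concentration range and (linear)
at or above LoQ.

## Validation

Leave-one-out recalculated responses are computed with the exact OLS
identity ŷ₍ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ) (hat matrix h); the test suite verifies
this against an explicit fold-by-fold refit oracle.  The conformity test
regresses recalculated on experimental responses and requires, by
two-sided coefficient t-tests at α (default 0.05, n − 2 df), intercept not
significantly different from 0 and slope not significantly different
from 1; a joint (intercept, slope) F-ellipse test is available as an
option.  Numerically exact recalculations (noiseless data, residuals at
machine precision) conform by construction.  "Calibration mode" runs the
same regression on plain fitted values; its R² equals the original fit's
R² exactly.

Precision: intra-day statistics pool replicates within a day, inter-day
statistics pool day means; per level, a two-sided pooled-variance
Student's t-test compares day-1 replicates against the other days'
replicates (the classical "Student" variant; the grouping contrasts the
calibration day with later verification days).  Zero-variance groups are
flagged and reported non-significant rather than erroring.

Matrix effect: recovery = spiked/standard per level; the verdict
"concentration-dependent trapping" requires the recovery to fall by more
than 5 percentage points (default tolerance) from the lowest to the
highest level.

## Cohort statistics

Per species, a one-way repeated-measures ANOVA (statsmodels `AnovaRM`,
patient as subject) with sphericity assumed — four subjects give no power
for corrections, though a Greenhouse–Geisser option is exposed — followed
by Dunnett-style comparisons of each timepoint against T0.  The Dunnett
adjustment is computed for *paired* contrasts: per-timepoint paired t
statistics (n − 1 df) are referred to the distribution of the maximum
absolute component of a multivariate t with the contrasts' average
off-diagonal correlation, evaluated by deterministic Gauss–Hermite ×
fixed-order quadrature over the shared scale factor.  With a single
contrast this reduces exactly to the paired t-test; the quadrature is
verified against a seeded Monte-Carlo multivariate-t oracle in the tests.
Degenerate (zero-variance) species are flagged instead of given p-values.

## SDB identity check

The monoisotopic m/z uses the NIST monoisotopic mass table (via
pyteomics), with a `plus_H` adduct adding one proton (1.0072765 u) per
charge: C₂₀H₂₂N₄O₄S + H⁺ gives 415.14 at two decimals, matching the SDB
molecular ion; neutral H₂S is 33.9877 u.

## Synthetic-data generators

Every generator is a pure function of its arguments including the seed,
and noiseless outputs are exactly invertible by the matching estimation
stage.  Study-condition defaults:

- **Chromatograms**: 23-min run at 300 points/min, Gaussian peaks
  (optional exponentially-modified tailing, area-preserving), flat or
  drifting baseline, i.i.d. Gaussian noise.
- **Standards**: 5 replicates × 3 days at the seven levels; replicate
  noise SD 0.514 AU (the reference linear model's residual scatter).  Day
  offsets are additive on area and default to 0, so the default noise
  model is exactly that residual scatter; set `day_effect_sd > 0` for
  precision-study scenarios.
- **Cohort**: 4 patients × T0/T1/T2.  T0 pool means free 0.6,
  acid-labile 1.2, bound-sulfane 1.5 µM — low-micromolar serum levels
  chosen as a realistic operating point, since the clinical figures print
  no numeric means.  The T2 effect raises the expected total by 40% with
  the free pool unchanged (the extra sulfide loads proportionally onto the
  two bound pools); T1 applies half the T2 effect, an interpolation
  choice, overridable via `t1_fraction`.  Between-patient SD 0.3 µM
  (constant within patient across timepoints), within-replicate SD
  0.05 µM.
- **Matrix effect**: recovery anchors 22/25, 100/180, 200/400 at 5, 12.5,
  25 µM, interpolated log-linearly in concentration between anchors
  (three anchors constrain nothing smoother).
- **Arm areas**: free arm responds to the free pool, acid arm to
  free + acid-labile, total arm to the pool sum; three injections per
  sample.

What the generators do *not* emulate: derivatization kinetics, O₂/pH/
temperature chemistry, peak-shape drift, heteroscedastic detector noise,
carry-over, or any real between-run retention shifts.  Passing tests
therefore demonstrate the correctness of the *computational* chain under
the stated statistical model, not the behaviour of the assay on real
instruments or sera.

## Problem sizes

Monte-Carlo checks use 500 seeded standards tables for LOO conformity and
parameter recovery, 200 seeded cohorts for effect detection, and 50 seeded
signals for integration accuracy — sizes at which the binomial error of
the estimated rates is comfortably below the asserted margins.

## Known limitations

- Absolute peak areas of the reference system are not reproducible (its
  integration windows and baseline treatment are proprietary to the
  instrument software); only ratios and statistical structure are
  emulated.
- The recalculated-vs-experimental "s" values are reported as regression
  standard errors of the validation line, one defensible reading where
  the convention is ambiguous.
- Overlapping peaks are truncated at the valley, which biases both areas
  low for strongly fused peaks; deconvolution is out of scope.
- The Dunnett adjustment approximates the contrast correlation matrix by
  its average off-diagonal element (exact for two timepoints vs control,
  i.e. one or two contrasts with equicorrelation).
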