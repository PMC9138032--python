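"""Validate the calibration by leave-one-out cross-validation.

Each standard point is removed in turn, the curve refitted, and the removed
response recalculated; regressing recalculated on experimental responses
should give a line not significantly different from intercept 0, slope 1.
"""

import sulfispec as s

standards = s.reduce_range(s.gen_calibration_dataset(seed=5), max_conc=6.0)
experimental = standards["area_au"].to_numpy()

recalc = s.loo_cv(standards, "linear")
cv = s.validate_recalc_regression(experimental, recalc, alpha=0.05, mode="cv")
print(cv.summary())

# calibration mode projects points onto the original fit without removal
model = s.fit_calibration(standards, "linear")
fitted = s.predict_area(model, standards["conc_um"].to_numpy())
print(s.validate_recalc_regression(experimental, fitted, mode="calibration").summary())

report = s.precision_study(standards, alpha=0.05)
print("\nper-level inter-day comparability (day 1 vs later days):")
print(report.t_tests.to_string(index=False))
print("precision study passes:", report.passes)
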