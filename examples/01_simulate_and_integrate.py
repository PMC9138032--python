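"""Simulate an FLD chromatogram, find the SDB peak and measure its area.

The sulfide-dibimane (SDB) product elutes near 11.8 min and the excess
monobromobimane (MBB) reagent near 12.8 min; SDB's baseline-corrected peak
area (LU·min) is the assay's raw response.
"""

import sulfispec as s

chrom = s.gen_chromatogram(
    s.sdb_mbb_peaks(sdb_height=100.0, mbb_height=300.0),
    baseline_level=2.0,
    drift_slope=0.05,
    noise_sd=0.5,
    seed=42,
)
print(f"simulated {chrom.time.size} points over {chrom.duration:.1f} min")

peaks = s.assign_identity(s.detect_peaks(chrom, min_height=20.0, min_prominence=10.0))
for p in peaks:
    print(f"{p.label:>8s}: apex {p.retention_time:.3f} min, "
          f"height {p.height:.1f} LU, area {p.area:.2f} LU*min")

sdb = next(p for p in peaks if p.label == "SDB")
area = s.integrate_peak(chrom, sdb.window, baseline="linear_endpoints")
# a Gaussian of height 100 LU and sigma 0.05 min has area 100*0.05*sqrt(2*pi) = 12.53
print(f"SDB area {area:.2f} LU*min (analytic value for the simulated peak: 12.53)")
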