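"""Assess matrix trapping: spiked serum recovers less SDB than pure standards.

Recovery (spiked area / standard area) falls with spike concentration when
the serum matrix traps part of the added sulfide, which is why calibration
uses aqueous Na2S standards rather than standard addition to serum.
"""

import sulfispec as s

# reference area pairs: standard solution vs serum spiked at the same level
standard = {5.0: 25.0, 12.5: 180.0, 25.0: 400.0}
spiked = {5.0: 22.0, 12.5: 100.0, 25.0: 200.0}

result = s.matrix_effect_assess(standard, spiked)
print(result.recoveries.to_string(index=False))
print("verdict:", result.verdict)

# the synthetic generator reproduces the same recovery curve
pairs = s.gen_matrix_effect_pairs(conc_levels=[5.0, 8.0, 12.5, 18.0, 25.0], seed=0)
print("\nsimulated pairs (recovery interpolated log-linearly between anchors):")
print(pairs.round(3).to_string(index=False))
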