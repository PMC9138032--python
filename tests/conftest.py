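import numpy as np
import pytest

import sulfispec as s


@pytest.fixture
def linear_truth() -> s.CalibrationModel:
    """Reference low-range linear response (a = −0.581 AU, b = 3.51 AU/µM)."""
    return s.default_linear_truth()


@pytest.fixture
def parabolic_truth() -> s.CalibrationModel:
    """Reference full-range parabolic response (a = −13.2, b = 5.87, c = 0.358)."""
    return s.default_parabolic_truth()


@pytest.fixture
def noiseless_standards(linear_truth):
    """Low-range standards table lying exactly on the linear response."""
    return s.gen_calibration_dataset(
        linear_truth, conc_levels=[0.8, 1.6, 3.0, 6.0], noise_sd=0.0, seed=0
    )


@pytest.fixture
def noisy_standards(linear_truth):
    """Low-range standards with replicate noise at the reference residual scatter."""
    return s.gen_calibration_dataset(
        linear_truth, conc_levels=[0.8, 1.6, 3.0, 6.0], noise_sd=0.514, seed=12345
    )


@pytest.fixture
def single_gaussian():
    """One isolated Gaussian peak (height 100 LU, sigma 0.05 min) on zero baseline."""
    peak = s.PeakSpec(retention_time=11.8, height=100.0, width_sigma=0.05, label="SDB")
    return peak, s.gen_chromatogram([peak], duration=23.0, sampling_rate=300.0, seed=0)
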