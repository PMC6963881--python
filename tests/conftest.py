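import numpy as np
import pytest

from chromaval.calibration import CalibrationSeries
from chromaval.peakmetrics import PeakMeasurement

# Reference-peak descriptors back-solved from the published suitability values
# (k' = 6.51, N = 4085, As = 0.82 at t_R = 15.43 min): only t_R is printed, so
# t_0, W_half and F are recovered by inverting the defining formulas.
REF_T_R = 15.43
REF_T_0 = REF_T_R / 7.51                      # k' = t_R/t_0 - 1 = 6.51
REF_W_HALF = REF_T_R / np.sqrt(4085.0 / 5.54)  # N = 5.54 (t_R/W_half)^2
REF_W_5 = 1.0
REF_F = REF_W_5 / (2.0 * 0.82)                 # As = W_5/(2F) = 0.82


def make_peak(t_r=REF_T_R, area=2432036.0, scale_widths=True):
    s = t_r / REF_T_R if scale_widths else 1.0
    return PeakMeasurement(
        t_r=t_r, t_0=REF_T_0, area=area,
        w_half=REF_W_HALF * s, w_5=REF_W_5 * s, f_front=REF_F * s,
    )


@pytest.fixture
def reference_peaks():
    """Five plausible replicate injections around the reference peak."""
    t_rs = [15.43, 15.15, 15.84, 15.33, 15.51]
    areas = [2432036, 2356539, 2368076, 2342875, 2401008]
    return [make_peak(t, a) for t, a in zip(t_rs, areas)]


@pytest.fixture
def exact_line_series():
    """Triplicate 8-level series exactly on y = 2x + 1."""
    conc = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    y = 2.0 * conc + 1.0
    return CalibrationSeries(conc, np.column_stack([y, y, y]))


@pytest.fixture
def noisy_series():
    """A fixed mildly heteroscedastic series for regression cross-checks."""
    rng = np.random.default_rng(2024)
    conc = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    mu = 1.2e6 * conc + 5e4
    resp = mu[:, None] * (1.0 + 0.03 * rng.standard_normal((conc.size, 3)))
    return CalibrationSeries(conc, resp)
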