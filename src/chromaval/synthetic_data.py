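"""Seeded generators for calibration series, decay courses and raw traces.

These generators produce inputs with the statistical structure the analysis
modules assume, so every pipeline stage is testable without instrument data:

* :func:`simulate_calibration` — a linear detector response with Gaussian
  noise whose spread may grow with the response (the heteroscedastic
  structure that motivates weighted calibration).  The noise standard
  deviation at a noiseless response mu is sqrt(sigma0^2 + (sigma1*mu)^2),
  i.e. independent additive and proportional components.
* :func:`simulate_decay` — exponential first-order decay with multiplicative
  Gaussian noise, normalized so the mean at t = 0 is 100%.
* :func:`simulate_trace` / :func:`measure_peak` — skew-normal-shaped
  chromatographic peaks on a drifting baseline, and a threshold-crossing
  measurer recovering the standard peak descriptors (apex, widths at 50%
  and 5% height, leading-edge front segment, area).  Negative skew produces
  fronting peaks (asymmetry factor < 1).

All generators are pure functions of their spec (seed included): identical
inputs give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _st

from .calibration import CalibrationSeries
from .errors import InvalidSpecError, MeasurementError
from .kinetics import KineticSeries
from .peakmetrics import PeakMeasurement

__all__ = [
    "DEFAULT_CALIBRATION_LEVELS",
    "DEFAULT_DECAY_TIMES",
    "CalibrationSimSpec",
    "DecaySimSpec",
    "TraceSimSpec",
    "simulate_calibration",
    "simulate_decay",
    "simulate_trace",
    "measure_peak",
]

#: Eight-level calibration grid, 0.5-7.0 mg/mL.
DEFAULT_CALIBRATION_LEVELS: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
#: Seven-point stability sampling grid, hours.
DEFAULT_DECAY_TIMES: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0)


@dataclass(frozen=True)
class CalibrationSimSpec:
    """Specification of a simulated calibration series.

    ``sigma0`` is an additive noise SD in response units; ``sigma1`` a
    proportional noise fraction applied to the noiseless response.  Any
    ``sigma1 > 0`` yields heteroscedastic data (variance grows with
    response).
    """

    true_slope: float = 1.2e6          # response units per mg/mL
    true_intercept: float = 0.0
    levels: tuple[float, ...] = DEFAULT_CALIBRATION_LEVELS
    replicates: int = 3
    sigma0: float = 0.0
    sigma1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.sigma1 < 0:
            raise InvalidSpecError("noise standard deviations must be non-negative")
        if self.replicates < 1:
            raise InvalidSpecError("at least one replicate per level")
        if len(self.levels) < 2 or any(c <= 0 for c in self.levels):
            raise InvalidSpecError("levels must be >= 2 strictly positive concentrations")


@dataclass(frozen=True)
class DecaySimSpec:
    """Specification of a simulated first-order decay course."""

    k_true: float = 0.005              # per hour
    times: tuple[float, ...] = DEFAULT_DECAY_TIMES
    noise_sd_frac: float = 0.02        # multiplicative noise fraction
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true <= 0:
            raise InvalidSpecError("k_true must be positive")
        if self.noise_sd_frac < 0:
            raise InvalidSpecError("noise fraction must be non-negative")
        if self.replicates < 1:
            raise InvalidSpecError("at least one replicate")


@dataclass(frozen=True)
class TraceSimSpec:
    """Specification of a raw chromatographic trace.

    ``peaks`` lists (apex time min, height, width min, skew); skew < 0 gives
    a fronting peak, 0 a symmetric one.  ``baseline_drift`` is a linear
    baseline slope in signal units per minute.
    """

    duration: float = 30.0             # minutes
    sampling_rate: float = 200.0       # points per minute
    peaks: tuple[tuple[float, float, float, float], ...] = ()
    baseline_drift: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise InvalidSpecError("duration and sampling rate must be positive")
        for apex, height, width, _skew in self.peaks:
            if not (0 < apex < self.duration):
                raise InvalidSpecError(f"peak apex {apex} outside the trace")
            if width <= 0 or height <= 0:
                raise InvalidSpecError("peak height and width must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise SD must be non-negative")


def simulate_calibration(spec: CalibrationSimSpec) -> CalibrationSeries:
    """Draw a calibration series from a true line plus the spec's noise model."""
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.levels, dtype=float)
    mu = spec.true_slope * conc + spec.true_intercept
    sd = np.sqrt(spec.sigma0**2 + (spec.sigma1 * mu) ** 2)
    resp = mu[:, None] + rng.standard_normal((conc.size, spec.replicates)) * sd[:, None]
    return CalibrationSeries(conc, resp)


def simulate_decay(spec: DecaySimSpec, label: str = "simulated") -> KineticSeries:
    """Draw a % content course: 100*exp(-k t)*(1+eps), renormalized to 100 at t=0.

    With replicates > 1 the per-time replicate matrix is attached and the
    series values are the per-time means (after normalization so the t = 0
    mean is exactly 100).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    mu = 100.0 * np.exp(-spec.k_true * t)
    eps = rng.standard_normal((t.size, spec.replicates)) * spec.noise_sd_frac
    reps = mu[:, None] * (1.0 + eps)
    if np.any(reps <= 0):
        raise InvalidSpecError("noise produced non-positive content; reduce noise_sd_frac")
    reps = reps * (100.0 / reps[0].mean())
    values = reps.mean(axis=1)
    return KineticSeries(
        times=t, values=values, label=label,
        replicate_values=reps if spec.replicates > 1 else None,
    )


def _skew_peak(t: np.ndarray, apex: float, height: float, width: float, skew: float) -> np.ndarray:
    """Skew-normal profile rescaled so its mode sits at ``apex`` with ``height``."""
    if skew == 0.0:
        return height * np.exp(-0.5 * ((t - apex) / width) ** 2)
    # locate the mode of the standard skew-normal numerically (fine grid)
    u = np.linspace(-4, 4, 2001)
    pdf = _st.skewnorm.pdf(u, skew)
    u_mode = u[np.argmax(pdf)]
    peak_pdf = _st.skewnorm.pdf(u_mode, skew)
    z = (t - apex) / width + u_mode
    return height * _st.skewnorm.pdf(z, skew) / peak_pdf


def simulate_trace(spec: TraceSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sum of skewed-Gaussian peaks + linear baseline drift + Gaussian noise.

    Returns (time minutes, signal) arrays; an empty peak list yields a
    baseline-only trace.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate)) + 1
    t = np.linspace(0.0, spec.duration, n)
    y = spec.baseline_drift * t
    for apex, height, width, skew in spec.peaks:
        y = y + _skew_peak(t, apex, height, width, skew)
    if spec.noise_sd > 0:
        y = y + rng.standard_normal(n) * spec.noise_sd
    return t, y


def _cross_time(t: np.ndarray, y: np.ndarray, i: int, j: int, level: float) -> float:
    """Linear interpolation of the time where y crosses ``level`` between i and j."""
    if y[j] == y[i]:
        return float(t[i])
    frac = (level - y[i]) / (y[j] - y[i])
    return float(t[i] + frac * (t[j] - t[i]))


def measure_peak(
    trace: tuple[np.ndarray, np.ndarray],
    apex_hint: float,
    t_0: float,
    window: float | None = None,
) -> PeakMeasurement:
    """Measure standard peak descriptors from a raw trace near ``apex_hint``.

    The apex is the local maximum of the baseline-corrected signal within
    ``window`` minutes of the hint (default: 10% of the trace span).  The
    baseline is the straight line through the median signal of the first and
    last 2% of samples.  Widths are found by walking outward from the apex to
    the 50% and 5% height crossings (linearly interpolated); the front
    segment runs from the leading 5% crossing to the apex; the area is the
    trapezoid of the corrected signal between the 5% crossings.
    """
    t, y = np.asarray(trace[0], float), np.asarray(trace[1], float)
    if t.size != y.size or t.size < 8:
        raise MeasurementError("trace too short to measure")
    span = t[-1] - t[0]
    if window is None:
        window = 0.10 * span
    # baseline from the trace edges
    m = max(3, int(0.02 * t.size))
    x_lo, y_lo = float(np.median(t[:m])), float(np.median(y[:m]))
    x_hi, y_hi = float(np.median(t[-m:])), float(np.median(y[-m:]))
    slope = (y_hi - y_lo) / (x_hi - x_lo) if x_hi != x_lo else 0.0
    yc = y - (y_lo + slope * (t - x_lo))

    sel = np.where(np.abs(t - apex_hint) <= window)[0]
    if sel.size == 0:
        raise MeasurementError(f"no samples within {window} min of apex hint {apex_hint}")
    i_apex = sel[np.argmax(yc[sel])]
    height = yc[i_apex]
    # reject numerically flat signals (baseline-only traces)
    if height <= max(1e-12, 1e-9 * float(np.ptp(y))):
        raise MeasurementError("no positive peak near the apex hint")
    if 0 < i_apex < t.size - 1 and (yc[i_apex] < yc[i_apex - 1] or yc[i_apex] < yc[i_apex + 1]):
        raise MeasurementError("apex is not a local maximum inside the window")

    def walk(level: float, direction: int) -> float:
        i = i_apex
        while 0 <= i + direction < t.size:
            j = i + direction
            if yc[j] <= level:
                return _cross_time(t, yc, i, j, level)
            i = j
        raise MeasurementError(f"{level/height:.0%} threshold never crossed")

    t_half_lead = walk(0.5 * height, -1)
    t_half_trail = walk(0.5 * height, +1)
    t5_lead = walk(0.05 * height, -1)
    t5_trail = walk(0.05 * height, +1)
    apex_time = float(t[i_apex])

    inside = (t >= t5_lead) & (t <= t5_trail)
    area = float(np.trapezoid(np.clip(yc[inside], 0, None), t[inside]))

    return PeakMeasurement(
        t_r=apex_time,
        t_0=t_0,
        area=area,
        w_half=t_half_trail - t_half_lead,
        w_5=t5_trail - t5_lead,
        f_front=apex_time - t5_lead,
    )
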