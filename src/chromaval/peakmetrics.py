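"""System-suitability statistics for chromatographic peaks.

A system-suitability test verifies, before any quantitative work, that the
chromatographic system retains, resolves and reproduces the analyte peak
adequately.  The statistics computed here are the European-Pharmacopoeia
style descriptors used for isocratic reversed-phase assays:

* capacity factor           k' = t_R / t_0 - 1
* theoretical plate count   N  = 5.54 * (t_R / W_half)**2
* asymmetry factor          As = W_5% / (2 * F)
* repeatability             RSD% of retention time and of peak area over
                            replicate injections

where ``t_R`` is the retention time of the analyte, ``t_0`` the void
(unretained) time, ``W_half`` / ``W_5`` the peak widths at 50% and 5% of
peak height, and ``F`` the time from the leading-edge 5%-height crossing to
the apex.  ``As < 1`` indicates a fronting peak, ``As > 1`` a tailing one.

Acceptance limits are data, not code: :data:`DEFAULT_SUITABILITY_LIMITS`
holds the common monograph values (k' > 2, N > 2000, 0.8 <= As <= 1.5,
both RSDs < 5%) and every limit can be overridden per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidPeakError, NoDataError, StatisticUndefinedError

__all__ = [
    "PeakMeasurement",
    "SuitabilityResult",
    "DEFAULT_SUITABILITY_LIMITS",
    "capacity_factor",
    "plate_count",
    "asymmetry_factor",
    "repeatability_rsd",
    "assess_suitability",
    "read_peak_table",
]

#: Default acceptance limits for the suitability verdict.  ``k_prime_min`` and
#: ``n_plates_min`` are strict lower bounds, ``asymmetry_range`` is inclusive
#: on both ends, and the RSD limits are strict upper bounds in percent.
DEFAULT_SUITABILITY_LIMITS: dict = {
    "k_prime_min": 2.0,
    "n_plates_min": 2000.0,
    "asymmetry_range": (0.8, 1.5),
    "rsd_t_r_max": 5.0,
    "rsd_area_max": 5.0,
}


@dataclass(frozen=True)
class PeakMeasurement:
    """Descriptors of one integrated chromatographic peak.

    Parameters
    ----------
    t_r
        Retention time of the peak apex, minutes.
    t_0
        Void (unretained-compound) time, minutes.
    area
        Integrated peak area, arbitrary signal*min units.
    w_half
        Peak width at 50% of peak height, minutes.
    w_5
        Peak width at 5% of peak height, minutes.
    f_front
        Time from the leading-edge 5%-height crossing to the apex, minutes.
    """

    t_r: float
    t_0: float
    area: float
    w_half: float
    w_5: float
    f_front: float

    def __post_init__(self) -> None:
        if not (self.t_r > 0 and self.t_0 > 0):
            raise InvalidPeakError("retention and void times must be positive")
        if not self.w_half > 0:
            raise InvalidPeakError("width at half height must be positive")
        if self.w_5 < self.w_half:
            raise InvalidPeakError("width at 5% height cannot be below width at 50% height")
        if not (0 < self.f_front <= self.w_5):
            raise InvalidPeakError("front segment must satisfy 0 < F <= W_5%")
        if not self.area > 0:
            raise InvalidPeakError("peak area must be positive")


def capacity_factor(t_r: float, t_0: float) -> float:
    """Capacity (retention) factor k' = t_R/t_0 - 1.

    Raises
    ------
    InvalidPeakError
        If ``t_0 <= 0`` or the peak elutes before the void time.
    """
    if t_0 <= 0:
        raise InvalidPeakError(f"void time must be positive, got {t_0}")
    if t_r < t_0:
        raise InvalidPeakError(f"retention time {t_r} precedes void time {t_0}")
    return t_r / t_0 - 1.0


def plate_count(t_r: float, w_half: float) -> float:
    """Number of theoretical plates N = 5.54*(t_R/W_half)**2 (half-height method)."""
    if w_half <= 0:
        raise InvalidPeakError(f"width at half height must be positive, got {w_half}")
    return 5.54 * (t_r / w_half) ** 2


def asymmetry_factor(w_5: float, f_front: float) -> float:
    """Asymmetry factor As = W_5% / (2*F); < 1 fronting, > 1 tailing."""
    if w_5 <= 0 or f_front <= 0:
        raise InvalidPeakError("W_5% and F must both be positive")
    return w_5 / (2.0 * f_front)


def repeatability_rsd(values: Sequence[float]) -> float:
    """Percent relative standard deviation, 100*s/mean with s the (n-1) SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise StatisticUndefinedError("RSD needs at least two replicate values")
    mean = arr.mean()
    if mean == 0:
        raise StatisticUndefinedError("RSD undefined for zero-mean values")
    return 100.0 * arr.std(ddof=1) / abs(mean)


@dataclass
class SuitabilityResult:
    """Suitability statistics for an injection series plus pass/fail flags.

    ``k_prime``, ``n_plates`` and ``asymmetry`` are taken from the designated
    reference injection (the first peak); ``*_mean`` average over all
    injections and ``per_peak`` retains the full per-injection table.  The
    RSDs pool every injection.  ``passed`` maps each criterion name to a
    bool; ``all_passed`` is their conjunction.
    """

    k_prime: float
    n_plates: float
    asymmetry: float
    rsd_t_r: float
    rsd_area: float
    k_prime_mean: float
    n_plates_mean: float
    asymmetry_mean: float
    passed: dict = field(default_factory=dict)
    limits: dict = field(default_factory=dict)
    per_peak: pd.DataFrame | None = None

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())

    def to_dict(self) -> dict:
        return {
            "k_prime": self.k_prime,
            "n_plates": self.n_plates,
            "asymmetry": self.asymmetry,
            "rsd_t_r": self.rsd_t_r,
            "rsd_area": self.rsd_area,
            "k_prime_mean": self.k_prime_mean,
            "n_plates_mean": self.n_plates_mean,
            "asymmetry_mean": self.asymmetry_mean,
            "passed": dict(self.passed),
            "all_passed": self.all_passed,
            "limits": {k: list(v) if isinstance(v, tuple) else v for k, v in self.limits.items()},
        }


def assess_suitability(
    peaks: Sequence[PeakMeasurement],
    limits: Mapping | None = None,
) -> SuitabilityResult:
    """Compute suitability statistics for replicate injections and judge them.

    The first peak is the reference injection for k', N and As; retention-time
    and area repeatability pool all injections.  At least two peaks sharing
    one void time are required.
    """
    if not peaks:
        raise NoDataError("no peaks supplied")
    if len(peaks) < 2:
        raise StatisticUndefinedError("suitability needs at least two injections")
    t0s = {p.t_0 for p in peaks}
    if len(t0s) > 1 and (max(t0s) - min(t0s)) / min(t0s) > 1e-9:
        raise InvalidPeakError("all injections must share one void time")

    lim = dict(DEFAULT_SUITABILITY_LIMITS)
    if limits:
        lim.update(limits)

    per = pd.DataFrame(
        {
            "t_R": [p.t_r for p in peaks],
            "area": [p.area for p in peaks],
            "k_prime": [capacity_factor(p.t_r, p.t_0) for p in peaks],
            "n_plates": [plate_count(p.t_r, p.w_half) for p in peaks],
            "asymmetry": [asymmetry_factor(p.w_5, p.f_front) for p in peaks],
        }
    )
    ref = peaks[0]
    k_prime = capacity_factor(ref.t_r, ref.t_0)
    n_plates = plate_count(ref.t_r, ref.w_half)
    asym = asymmetry_factor(ref.w_5, ref.f_front)
    rsd_t_r = repeatability_rsd(per["t_R"])
    rsd_area = repeatability_rsd(per["area"])

    as_lo, as_hi = lim["asymmetry_range"]
    passed = {
        "k_prime": k_prime > lim["k_prime_min"],
        "n_plates": n_plates > lim["n_plates_min"],
        "asymmetry": as_lo <= asym <= as_hi,
        "rsd_t_r": rsd_t_r < lim["rsd_t_r_max"],
        "rsd_area": rsd_area < lim["rsd_area_max"],
    }
    return SuitabilityResult(
        k_prime=k_prime,
        n_plates=n_plates,
        asymmetry=asym,
        rsd_t_r=rsd_t_r,
        rsd_area=rsd_area,
        k_prime_mean=float(per["k_prime"].mean()),
        n_plates_mean=float(per["n_plates"].mean()),
        asymmetry_mean=float(per["asymmetry"].mean()),
        passed=passed,
        limits=lim,
        per_peak=per,
    )


def read_peak_table(path: str | Path) -> list[PeakMeasurement]:
    """Read a peak-descriptor CSV (columns t_R, t_0, area, W_half, W_5, F_front).

    One row per injection; header required; times in minutes.
    """
    df = pd.read_csv(path)
    required = ["t_R", "t_0", "area", "W_half", "W_5", "F_front"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidPeakError(f"{path}: missing required columns {missing}")
    return [
        PeakMeasurement(
            t_r=float(row.t_R),
            t_0=float(row.t_0),
            area=float(row.area),
            w_half=float(row.W_half),
            w_5=float(row.W_5),
            f_front=float(row.F_front),
        )
        for row in df.itertuples()
    ]
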