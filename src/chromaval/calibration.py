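"""Ordinary and weighted least-squares calibration with scheme selection.

Detector response in HPLC-UV calibration is often heteroscedastic: the
spread of replicate peak areas grows with the response itself, so an
ordinary least-squares (OLS) line — which weights every point equally — is
dominated by the high-concentration end and back-calculates the low end
poorly.  The workflow implemented here is the standard bioanalytical one:

1. fit OLS over all replicate points (:func:`fit_ols`);
2. test variance homogeneity between the lowest and highest calibration
   levels with an F-test at 99% confidence
   (:func:`f_test_homoscedasticity`) and inspect residuals
   (:func:`residuals`);
3. if heteroscedastic, refit under the six empirical weight schemes
   1/y^0.5, 1/y, 1/y^2, 1/x^0.5, 1/x, 1/x^2 (:func:`fit_weighted`);
4. back-calculate each calibration point through each fitted line,
   express the error in percent of nominal (%RE), and pick the scheme
   with the smallest sum of absolute %RE (:func:`select_best_scheme`);
5. derive detection limits LOD = 3.3*S_y/a and LOQ = 10*S_y/a from the
   retained line (:func:`detection_limits`).

Weighted coefficients come from the weighted normal equations with weights
normalized to sum to the number of points n:

    a_w = (sum w x y - n Xw Yw) / (sum w x^2 - n Xw^2),   b_w = Yw - a_w Xw

with weighted means Xw = sum(w x)/sum(w), Yw = sum(w y)/sum(w), and the
weighted correlation coefficient

    r_w = (Sw Swxy - Swx Swy) / sqrt((Sw Swx2 - Swx^2)(Sw Swy2 - Swy^2)).

Unit weights ("1") reduce every formula to the ordinary fit.  1/y weights
use the observed responses, applied in a single pass (no reweighting
iteration).  ``S_y`` is the residual standard error sqrt(SSE/(n-2)) (with
weighted SSE under a scheme); the standard deviation of the intercept is
also exposed since both readings are sanctioned by ICH Q2(R1) for
detection-limit work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    FitUndefinedError,
    InputMismatchError,
    LimitsUndefinedError,
    NoDataError,
    TestUndefinedError,
    WeightUndefinedError,
)

__all__ = [
    "WEIGHT_SCHEMES",
    "CalibrationSeries",
    "RegressionFit",
    "HomoscedasticityResult",
    "DetectionLimits",
    "CalibrationSummary",
    "fit_ols",
    "fit_weighted",
    "residuals",
    "f_test_homoscedasticity",
    "select_best_scheme",
    "detection_limits",
    "calibrate",
    "read_calibration_csv",
]

#: Candidate weight schemes in conventional reporting order; "1" is the
#: unweighted (OLS) fit and the others are the six empirical weights.
WEIGHT_SCHEMES: tuple[str, ...] = (
    "1",
    "1/y^0.5",
    "1/y",
    "1/y^2",
    "1/x^0.5",
    "1/x",
    "1/x^2",
)


@dataclass(frozen=True)
class CalibrationSeries:
    """Concentration levels with replicate detector responses.

    ``concentrations`` holds the distinct levels sorted ascending (mg/mL);
    ``responses`` is an (n_levels, n_replicates) array of peak areas.  The
    replicate count must be identical across levels; build from long-format
    data with :meth:`from_points`.
    """

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if resp.ndim == 1:
            resp = resp[:, None]
        if conc.ndim != 1 or resp.shape[0] != conc.size:
            raise InputMismatchError("responses must have one row per concentration level")
        if np.any(conc <= 0):
            raise FitUndefinedError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            order = np.argsort(conc)
            conc = conc[order]
            resp = resp[order]
            if np.any(np.diff(conc) <= 0):
                raise FitUndefinedError("concentration levels must be distinct")
        if not np.all(np.isfinite(resp)):
            raise FitUndefinedError("all responses must be finite")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)

    @classmethod
    def from_points(
        cls, concentrations: Sequence[float], responses: Sequence[float]
    ) -> "CalibrationSeries":
        """Build from long-format (concentration, response) pairs.

        Replicates are grouped by concentration; a ragged design (unequal
        replicate counts across levels) is rejected.
        """
        df = pd.DataFrame({"c": np.asarray(concentrations, float), "y": np.asarray(responses, float)})
        counts = df.groupby("c").size()
        if counts.nunique() != 1:
            raise InputMismatchError(
                f"unequal replicate counts per level: {dict(counts)}"
            )
        levels = np.sort(counts.index.to_numpy())
        resp = np.vstack([df.loc[df["c"] == c, "y"].to_numpy() for c in levels])
        return cls(levels, resp)

    @property
    def n_levels(self) -> int:
        return self.concentrations.size

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[1]

    @property
    def x(self) -> np.ndarray:
        """Concentrations flattened to one value per point (level-major)."""
        return np.repeat(self.concentrations, self.n_replicates)

    @property
    def y(self) -> np.ndarray:
        """Responses flattened level-major to match :attr:`x`."""
        return self.responses.ravel()


@dataclass
class RegressionFit:
    """One calibration line fitted under one weight scheme."""

    scheme: str
    slope: float
    intercept: float
    r: float
    s_y: float
    sd_slope: float
    sd_intercept: float
    pct_re: np.ndarray
    sum_abs_re: float
    n_points: int
    weights: np.ndarray = field(repr=False, default=None)

    def back_calculate(self, y: np.ndarray | float) -> np.ndarray | float:
        """Concentration read back through the line: (y - b) / a."""
        if self.slope == 0:
            raise FitUndefinedError("cannot back-calculate through a zero slope")
        return (y - self.intercept) / self.slope

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.slope * x + self.intercept

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "s_y": self.s_y,
            "sd_slope": self.sd_slope,
            "sd_intercept": self.sd_intercept,
            "sum_abs_re": self.sum_abs_re,
            "n_points": self.n_points,
        }


@dataclass
class HomoscedasticityResult:
    """Two-extreme-level variance-ratio F-test outcome."""

    f_calc: float
    f_crit: float
    s2_low: float
    s2_high: float
    confidence: float
    df: tuple[int, int]
    heteroscedastic: bool

    def to_dict(self) -> dict:
        return {
            "f_calc": self.f_calc,
            "f_crit": self.f_crit,
            "s2_low": self.s2_low,
            "s2_high": self.s2_high,
            "confidence": self.confidence,
            "df": list(self.df),
            "heteroscedastic": self.heteroscedastic,
        }


@dataclass
class DetectionLimits:
    """LOD/LOQ from the ratio of residual scale to slope."""

    lod: float
    loq: float
    basis: str
    s_y: float
    slope: float

    def to_dict(self) -> dict:
        return {"lod": self.lod, "loq": self.loq, "basis": self.basis,
                "s_y": self.s_y, "slope": self.slope}


def _raw_weights(scheme: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if scheme == "1":
        return np.ones_like(x)
    if scheme.startswith("1/y"):
        base, expo = y, scheme[3:]
    elif scheme.startswith("1/x"):
        base, expo = x, scheme[3:]
    else:
        raise WeightUndefinedError(f"unknown weight scheme {scheme!r}")
    power = {"": 1.0, "^0.5": 0.5, "^2": 2.0}.get(expo)
    if power is None:
        raise WeightUndefinedError(f"unknown weight scheme {scheme!r}")
    if np.any(base <= 0):
        raise WeightUndefinedError(
            f"scheme {scheme!r} requires strictly positive {'responses' if base is y else 'concentrations'}"
        )
    return 1.0 / base**power


def _weighted_fit_core(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r_w from the weighted normal equations, with w
    pre-normalized to sum to n."""
    n = x.size
    xw = float(np.sum(w * x) / np.sum(w))
    yw = float(np.sum(w * y) / np.sum(w))
    denom = float(np.sum(w * x * x) - n * xw * xw)
    if denom <= 0:
        raise FitUndefinedError("zero weighted variance in concentration")
    slope = float((np.sum(w * x * y) - n * xw * yw) / denom)
    intercept = yw - slope * xw
    sw, swx, swy = float(np.sum(w)), float(np.sum(w * x)), float(np.sum(w * y))
    swxy = float(np.sum(w * x * y))
    swx2, swy2 = float(np.sum(w * x * x)), float(np.sum(w * y * y))
    var_x = sw * swx2 - swx**2
    var_y = sw * swy2 - swy**2
    if var_y <= 0:
        r = 1.0  # perfectly flat response: degenerate, treated as exact
    else:
        r = float((sw * swxy - swx * swy) / math.sqrt(var_x * var_y))
    return slope, intercept, r


def _fit(series: CalibrationSeries, scheme: str) -> RegressionFit:
    if series.n_levels < 3:
        raise FitUndefinedError("calibration requires at least three concentration levels")
    x, y = series.x, series.y
    n = x.size
    w = _raw_weights(scheme, x, y)
    w = w * (n / w.sum())  # normalize so sum(w) == n
    slope, intercept, r = _weighted_fit_core(x, y, w)
    resid = y - (slope * x + intercept)
    sse = float(np.sum(w * resid**2))
    s_y = math.sqrt(sse / (n - 2)) if n > 2 else 0.0
    # coefficient SDs from the weighted design matrix
    xw = float(np.sum(w * x) / np.sum(w))
    sxx = float(np.sum(w * (x - xw) ** 2))
    sd_a = s_y / math.sqrt(sxx) if sxx > 0 else float("nan")
    sd_b = s_y * math.sqrt(1.0 / n + xw**2 / sxx) if sxx > 0 else float("nan")
    if slope == 0:
        pct_re = np.full_like(x, np.nan)
        sum_abs = float("nan")
    else:
        c_exp = (y - intercept) / slope
        pct_re = 100.0 * (c_exp - x) / x
        sum_abs = float(np.sum(np.abs(pct_re)))
    return RegressionFit(
        scheme=scheme,
        slope=slope,
        intercept=intercept,
        r=r,
        s_y=s_y,
        sd_slope=sd_a,
        sd_intercept=sd_b,
        pct_re=pct_re,
        sum_abs_re=sum_abs,
        n_points=n,
        weights=w,
    )


def fit_ols(series: CalibrationSeries) -> RegressionFit:
    """Unweighted least-squares line over all replicate points (scheme "1")."""
    return _fit(series, "1")


def fit_weighted(series: CalibrationSeries, scheme: str) -> RegressionFit:
    """Weighted least-squares line under one of :data:`WEIGHT_SCHEMES`."""
    if scheme not in WEIGHT_SCHEMES:
        raise WeightUndefinedError(
            f"unknown scheme {scheme!r}; supported: {WEIGHT_SCHEMES}"
        )
    return _fit(series, scheme)


def residuals(series: CalibrationSeries, fit: RegressionFit) -> np.ndarray:
    """Observed minus fitted response, one value per calibration point."""
    if fit.n_points != series.x.size:
        raise InputMismatchError("fit was not produced on this series")
    return series.y - fit.predict(series.x)


def f_test_homoscedasticity(
    series: CalibrationSeries, confidence: float = 0.99
) -> HomoscedasticityResult:
    """Variance-ratio F-test between the extreme calibration levels.

    The replicate variance at the highest level is divided by that at the
    lowest (larger variance always in the numerator, so F_calc >= 1) and
    compared with the critical F at the given confidence with
    (n_hi - 1, n_lo - 1) degrees of freedom.  With triplicates at 99%
    confidence the critical value is 99.0.  ``heteroscedastic`` is True when
    F_calc exceeds it.
    """
    lo = series.responses[0]
    hi = series.responses[-1]
    if lo.size < 2 or hi.size < 2:
        raise TestUndefinedError("need at least two replicates at each extreme level")
    s2_low = float(np.var(lo, ddof=1))
    s2_high = float(np.var(hi, ddof=1))
    if min(s2_low, s2_high) == 0:
        raise TestUndefinedError("zero replicate variance at an extreme level")
    if s2_high >= s2_low:
        f_calc = s2_high / s2_low
        df = (hi.size - 1, lo.size - 1)
    else:
        f_calc = s2_low / s2_high
        df = (lo.size - 1, hi.size - 1)
    f_crit = float(stats.f.ppf(confidence, *df))
    return HomoscedasticityResult(
        f_calc=f_calc,
        f_crit=f_crit,
        s2_low=s2_low,
        s2_high=s2_high,
        confidence=confidence,
        df=df,
        heteroscedastic=f_calc > f_crit,
    )


def select_best_scheme(fits: Sequence[RegressionFit]) -> RegressionFit:
    """Pick the fit with smallest sum of |%RE|.

    Ties are broken by larger |r|, then by position in the conventional
    scheme order (:data:`WEIGHT_SCHEMES`).
    """
    if not fits:
        raise NoDataError("no fits to select from")

    def rank(f: RegressionFit) -> tuple:
        order = WEIGHT_SCHEMES.index(f.scheme) if f.scheme in WEIGHT_SCHEMES else len(WEIGHT_SCHEMES)
        return (f.sum_abs_re, -abs(f.r), order)

    return min(fits, key=rank)


def detection_limits(fit: RegressionFit, basis: str = "residual") -> DetectionLimits:
    """LOD = 3.3*S_y/|a| and LOQ = 10*S_y/|a| from a calibration line.

    ``basis`` selects the residual standard error (default) or the standard
    deviation of the intercept as S_y; both are ICH-sanctioned readings of
    "standard deviation of the response".
    """
    if fit.slope == 0:
        raise LimitsUndefinedError("detection limits undefined for zero slope")
    if basis == "residual":
        s = fit.s_y
    elif basis == "intercept":
        s = fit.sd_intercept
    else:
        raise LimitsUndefinedError(f"unknown S_y basis {basis!r}")
    ratio = s / abs(fit.slope)
    return DetectionLimits(
        lod=3.3 * ratio, loq=10.0 * ratio, basis=f"{fit.scheme}:{basis}",
        s_y=s, slope=fit.slope,
    )


@dataclass
class CalibrationSummary:
    """Full linearity work-up: OLS, variance test, weighted fits, selection.

    ``homoscedasticity`` is None when the F-test is undefined for the data
    (e.g. zero replicate variance at an extreme level, as with noise-free
    simulations); ``homoscedasticity_note`` then carries the reason.
    """

    ols: RegressionFit
    homoscedasticity: HomoscedasticityResult | None
    fits: list[RegressionFit]
    best: RegressionFit
    limits_ols: DetectionLimits
    limits_best: DetectionLimits
    homoscedasticity_note: str = ""

    def table(self) -> pd.DataFrame:
        """Per-scheme coefficient table (one row per weight scheme)."""
        return pd.DataFrame([f.to_dict() for f in self.fits])

    def to_dict(self) -> dict:
        return {
            "ols": self.ols.to_dict(),
            "homoscedasticity": (
                self.homoscedasticity.to_dict()
                if self.homoscedasticity is not None
                else {"heteroscedastic": False, "undefined": self.homoscedasticity_note}
            ),
            "fits": [f.to_dict() for f in self.fits],
            "selected_scheme": self.best.scheme,
            "limits_ols": self.limits_ols.to_dict(),
            "limits_best": self.limits_best.to_dict(),
        }


def calibrate(
    series: CalibrationSeries,
    schemes: Sequence[str] = WEIGHT_SCHEMES,
    confidence: float = 0.99,
    lod_basis: str = "residual",
) -> CalibrationSummary:
    """Run the complete linearity workflow on one calibration series."""
    fits = [_fit(series, s) for s in schemes]
    ols = next((f for f in fits if f.scheme == "1"), None) or fit_ols(series)
    note = ""
    try:
        homo = f_test_homoscedasticity(series, confidence=confidence)
    except TestUndefinedError as exc:
        homo, note = None, str(exc)
    best = select_best_scheme([f for f in fits if f.scheme != "1"] or fits)
    return CalibrationSummary(
        ols=ols,
        homoscedasticity=homo,
        fits=fits,
        best=best,
        limits_ols=detection_limits(ols, basis=lod_basis),
        limits_best=detection_limits(best, basis=lod_basis),
        homoscedasticity_note=note,
    )


def read_calibration_csv(path: str | Path) -> CalibrationSeries:
    """Read long-format calibration data (columns concentration, response)."""
    df = pd.read_csv(path)
    for col in ("concentration", "response"):
        if col not in df.columns:
            raise InputMismatchError(f"{path}: missing column {col!r}")
    return CalibrationSeries.from_points(df["concentration"], df["response"])
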