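"""First-order degradation kinetics for content-vs-time stability courses.

A drug degrading by first-order kinetics loses content at a rate
proportional to the amount remaining, so the log of the remaining content
is linear in time:

    ln(P_t) = ln(P_0) - k_obs * t

with ``P_0``/``P_t`` the peak areas (or % content) at time zero and time t
and ``k_obs`` the observed rate constant (per hour here).  Fitting ordinary
least squares to (t, ln value) yields -k as the slope; the half-life is
t_half = 0.693/k.  The constant 0.693 (rather than ln 2 = 0.69315) is the
conventional rounded value used in pharmaceutical stability reporting and is
the default; pass ``half_life_constant=math.log(2)`` for the exact one.

By default a series with replicate measurements is fitted on the per-time
means; ``use_replicates=True`` fits every replicate point instead (same
slope in balanced designs, different R^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    FitUndefinedError,
    LogUndefinedError,
    NormalizationError,
)

__all__ = [
    "HALF_LIFE_CONSTANT",
    "KineticSeries",
    "KineticFit",
    "fit_first_order",
    "half_life",
    "content_remaining",
    "read_kinetic_csv",
    "load_reference_stability",
]

#: Conventional rounded half-life constant (0.693 ~= ln 2).
HALF_LIFE_CONSTANT = 0.693


@dataclass(frozen=True)
class KineticSeries:
    """A content-vs-time course for one admixture.

    ``values`` are either % of initial content or raw peak areas, strictly
    positive (their log is taken); ``times`` are hours, strictly increasing,
    with t = 0 permitted.  ``replicate_values`` optionally holds an
    (n_times, n_replicates) array whose row means should match ``values``.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    replicate_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise FitUndefinedError("times and values must have equal length")
        if t.size < 3:
            raise FitUndefinedError("a kinetic series needs at least three time points")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise FitUndefinedError("times must be non-negative and strictly increasing")
        bad = np.where(v <= 0)[0]
        if bad.size:
            raise LogUndefinedError(
                f"non-positive value at t = {t[bad[0]]} h (index {bad[0]})"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.replicate_values is not None:
            r = np.atleast_2d(np.asarray(self.replicate_values, dtype=float))
            if r.shape[0] != t.size:
                raise FitUndefinedError("replicate_values must have one row per time point")
            object.__setattr__(self, "replicate_values", r)


@dataclass
class KineticFit:
    """First-order parameters of one degradation course."""

    label: str
    k: float                 # rate constant, per hour (0 for no decay)
    ln_p0: float
    r_squared: float
    t_half_hours: float
    t_half_days: float
    n_points: int
    degrading: bool          # False when the fitted slope is non-negative
    half_life_constant: float = HALF_LIFE_CONSTANT

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "k_per_hour": self.k,
            "ln_p0": self.ln_p0,
            "r_squared": self.r_squared,
            "t_half_hours": self.t_half_hours,
            "t_half_days": self.t_half_days,
            "n_points": self.n_points,
            "degrading": self.degrading,
            "half_life_constant": self.half_life_constant,
        }


def half_life(k: float, constant: float = HALF_LIFE_CONSTANT) -> float:
    """Half-life constant/k in hours; non-finite (inf) when k <= 0."""
    if k <= 0:
        return float("inf")
    return constant / k


def fit_first_order(
    series: KineticSeries,
    half_life_constant: float = HALF_LIFE_CONSTANT,
    use_replicates: bool = False,
) -> KineticFit:
    """Least-squares fit of ln(value) vs time; k is the negated slope.

    R^2 is the squared correlation of the same regression.  A flat or rising
    course yields k clamped to 0, infinite half-life and ``degrading=False``.
    """
    if use_replicates and series.replicate_values is not None:
        t = np.repeat(series.times, series.replicate_values.shape[1])
        v = series.replicate_values.ravel()
        bad = np.where(v <= 0)[0]
        if bad.size:
            raise LogUndefinedError(f"non-positive replicate value at flat index {bad[0]}")
    else:
        t, v = series.times, series.values
    lnv = np.log(v)
    if np.allclose(lnv, lnv[0]):
        # perfectly constant content: zero slope, R^2 conventionally 1
        return KineticFit(
            label=series.label, k=0.0, ln_p0=float(lnv[0]), r_squared=1.0,
            t_half_hours=float("inf"), t_half_days=float("inf"),
            n_points=t.size, degrading=False,
            half_life_constant=half_life_constant,
        )
    res = stats.linregress(t, lnv)
    slope = float(res.slope)
    k = -slope
    degrading = k > 0
    th = half_life(k, constant=half_life_constant)
    return KineticFit(
        label=series.label,
        k=k if degrading else 0.0,
        ln_p0=float(res.intercept),
        r_squared=float(res.rvalue**2),
        t_half_hours=th,
        t_half_days=th / 24.0,
        n_points=t.size,
        degrading=degrading,
        half_life_constant=half_life_constant,
    )


def content_remaining(
    series: KineticSeries,
    auto_normalize: bool = False,
    atol: float = 1e-9,
) -> np.ndarray:
    """Percent content lost at each time point of a %-of-initial series.

    Requires the series to start at 100% at t = 0 (within ``atol``); with
    ``auto_normalize=True`` the series is rescaled so its first value is 100.
    Returns 100 - value per time point.
    """
    v = series.values
    if auto_normalize:
        v = 100.0 * v / v[0]
    elif abs(v[0] - 100.0) > atol:
        raise NormalizationError(
            f"series starts at {v[0]}, not 100%; pass auto_normalize=True to rescale"
        )
    return 100.0 - v


def read_kinetic_csv(path: str | Path) -> dict[str, KineticSeries]:
    """Read one or more kinetic series from CSV.

    Expected columns: ``time_h``, ``value``; optional ``series`` label
    (multiple courses per file) and ``replicate`` id.  With replicates the
    per-time mean becomes the series value and the replicate matrix is kept.
    """
    df = pd.read_csv(path)
    for col in ("time_h", "value"):
        if col not in df.columns:
            raise FitUndefinedError(f"{path}: missing column {col!r}")
    if "series" not in df.columns:
        df["series"] = ""
    out: dict[str, KineticSeries] = {}
    for label, grp in df.groupby("series", sort=False):
        if "replicate" in grp.columns and grp["replicate"].notna().any():
            pivot = grp.pivot_table(index="time_h", columns="replicate", values="value")
            times = pivot.index.to_numpy(dtype=float)
            reps = pivot.to_numpy(dtype=float)
            out[str(label)] = KineticSeries(
                times=times, values=reps.mean(axis=1), label=str(label),
                replicate_values=reps,
            )
        else:
            grp = grp.sort_values("time_h")
            out[str(label)] = KineticSeries(
                times=grp["time_h"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                label=str(label),
            )
    return out


def load_reference_stability() -> dict[str, KineticSeries]:
    """Packaged reference dataset: ampicillin content (% of initial) in three
    total-parenteral-nutrition admixture compositions (HEN: high-energy,
    HEL: high-electrolyte, LEL: low-electrolyte) stored at 4 °C over 144 h,
    sampled every 24 h.  Values are per-time mean contents from triplicate
    admixtures; the accompanying SDs are carried for reporting only.
    """
    ref = resources.files("chromaval.data").joinpath("ampicillin_tpn_stability.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    out: dict[str, KineticSeries] = {}
    for label, grp in df.groupby("series", sort=False):
        grp = grp.sort_values("time_h")
        out[str(label)] = KineticSeries(
            times=grp["time_h"].to_numpy(dtype=float),
            values=grp["mean_content_pct"].to_numpy(dtype=float),
            label=str(label),
        )
    return out
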