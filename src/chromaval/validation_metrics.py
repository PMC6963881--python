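"""Accuracy, precision and robustness metrics with acceptance limits.

Accuracy is the relative error of the mean determined concentration against
nominal, eps_r = (C_theoret - mean(C_exp))/C_theoret * 100.  Under this
orientation a *negative* eps_r means over-estimation (the determined value
exceeds nominal); the sign is reported exactly as the formula gives it.
Precision is the percent RSD of replicate determined concentrations,
labelled intra-day (repeatability) or inter-day (intermediate precision).
Robustness compares suitability metrics obtained under small deliberate
method perturbations (temperature, flow rate, sample matrix) against the
baseline condition as percent relative differences.

Default acceptance limits — |eps_r| < 5%, RSD < 5%, every |rel_err| < 10% —
are configuration, not code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    InvalidInputError,
    NoDataError,
    StatisticUndefinedError,
)

__all__ = [
    "AccuracyResult",
    "PrecisionResult",
    "RobustnessRow",
    "accuracy",
    "precision",
    "robustness_table",
    "DEFAULT_LIMITS",
]

DEFAULT_LIMITS: dict = {
    "accuracy_pct": 5.0,    # strict: |eps_r| < 5
    "precision_pct": 5.0,   # strict: RSD < 5
    "robustness_pct": 10.0,  # strict: |rel_err| < 10 for every metric
}


@dataclass
class AccuracyResult:
    level: float            # nominal concentration, mg/mL
    eps_r: float            # relative error, percent
    n: int
    passed: bool
    limit: float = 5.0

    def to_dict(self) -> dict:
        return {"level": self.level, "eps_r": self.eps_r, "n": self.n,
                "passed": self.passed, "limit": self.limit}


@dataclass
class PrecisionResult:
    level: float
    rsd: float
    kind: str               # "intra-day" | "inter-day"
    n: int
    passed: bool
    limit: float = 5.0

    def to_dict(self) -> dict:
        return {"level": self.level, "rsd": self.rsd, "kind": self.kind,
                "n": self.n, "passed": self.passed, "limit": self.limit}


@dataclass
class RobustnessRow:
    factor: str
    value: object
    metrics: dict
    rel_err: dict
    passed: bool
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"factor": self.factor, "value": self.value,
                "metrics": dict(self.metrics), "rel_err": dict(self.rel_err),
                "passed": self.passed, "errors": list(self.errors)}


def accuracy(
    c_theoret: float,
    c_exp_values: Sequence[float],
    limit: float = DEFAULT_LIMITS["accuracy_pct"],
) -> AccuracyResult:
    """Relative error of the mean determined concentration vs nominal.

    eps_r = (C_theoret - mean(C_exp)) / C_theoret * 100; a determined mean
    above nominal therefore yields a negative eps_r.  Passes when
    |eps_r| < ``limit`` (strict).
    """
    if c_theoret <= 0:
        raise InvalidInputError(f"nominal concentration must be positive, got {c_theoret}")
    vals = np.asarray(c_exp_values, dtype=float)
    if vals.size < 1:
        raise NoDataError("at least one determined value is required")
    eps_r = (c_theoret - float(vals.mean())) / c_theoret * 100.0
    return AccuracyResult(
        level=c_theoret, eps_r=eps_r, n=vals.size,
        passed=abs(eps_r) < limit, limit=limit,
    )


def precision(
    values: Sequence[float],
    kind: str = "intra-day",
    level: float = float("nan"),
    limit: float = DEFAULT_LIMITS["precision_pct"],
) -> PrecisionResult:
    """Percent RSD of replicate determined concentrations ((n-1) denominator)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise StatisticUndefinedError("precision needs at least two values")
    mean = vals.mean()
    if mean == 0:
        raise StatisticUndefinedError("RSD undefined for zero-mean values")
    rsd = float(100.0 * vals.std(ddof=1) / abs(mean))
    return PrecisionResult(
        level=level, rsd=rsd, kind=kind, n=vals.size,
        passed=rsd < limit, limit=limit,
    )


def robustness_table(
    baseline: Mapping[str, float],
    variants: Sequence[tuple[str, object, Mapping[str, float]]],
    limit: float = DEFAULT_LIMITS["robustness_pct"],
) -> list[RobustnessRow]:
    """Percent relative differences of perturbed-condition metrics vs baseline.

    ``variants`` is a sequence of (factor label, perturbed setting, metric
    mapping); every variant must carry exactly the baseline's metric keys.
    rel_err = 100*(variant - baseline)/baseline per metric; a row passes when
    every defined |rel_err| < ``limit``.  A zero baseline metric is reported
    as a per-metric division-undefined note (rel_err NaN) and the row is
    still emitted.
    """
    if not variants:
        raise NoDataError("no variant conditions supplied")
    rows: list[RobustnessRow] = []
    base_keys = set(baseline)
    for factor, value, metrics in variants:
        if set(metrics) != base_keys:
            raise InvalidInputError(
                f"variant {factor}={value!r} metric keys {sorted(metrics)} "
                f"differ from baseline {sorted(base_keys)}"
            )
        rel: dict = {}
        errs: list = []
        for key in metrics:
            b = baseline[key]
            if b == 0:
                rel[key] = float("nan")
                errs.append(f"baseline metric {key!r} is zero; relative error undefined")
            else:
                rel[key] = 100.0 * (metrics[key] - b) / b
        defined = [v for v in rel.values() if not math.isnan(v)]
        rows.append(
            RobustnessRow(
                factor=factor,
                value=value,
                metrics=dict(metrics),
                rel_err=rel,
                passed=bool(defined) and all(abs(v) < limit for v in defined) and not errs,
                errors=errs,
            )
        )
    return rows
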