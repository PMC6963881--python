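"""End-to-end orchestration of the validation stages into one report.

``run_pipeline`` executes the stages named in a configuration mapping —
suitability, linearity (calibration), accuracy/precision, robustness,
kinetics — in order, each on a CSV input or a simulation spec, and collects
the results into a :class:`ValidationReport` with per-section verdicts and
provenance (input digests, seeds, package version).  Stages without input
are marked skipped with a reason rather than failing the run.  Given the
same configuration and seeds the report is deterministic (modulo its
timestamp).

Configuration schema (YAML/JSON mapping; all stages optional)::

    seed: 42                        # default seed for simulation specs
    limits:                         # every threshold is data with defaults
      suitability: {k_prime_min: 2.0, n_plates_min: 2000,
                    asymmetry_range: [0.8, 1.5],
                    rsd_t_r_max: 5.0, rsd_area_max: 5.0}
      accuracy_pct: 5.0
      precision_pct: 5.0
      robustness_pct: 10.0
      r_min: 0.99                   # linearity verdict threshold on |r|
    suitability: {file: peaks.csv}
    calibration:
      file: calibration.csv         # or simulate: {true_slope: ..., sigma1: ...}
      confidence: 0.99
      schemes: ["1", "1/y^0.5", "1/y", "1/y^2", "1/x^0.5", "1/x", "1/x^2"]
      lod_basis: residual           # or intercept
    accuracy: {file: accuracy.csv}  # columns level, kind, value
    precision: {file: precision.csv}
    robustness: {file: robustness.csv}  # factor, value, is_baseline?, metrics...
    kinetics:
      file: courses.csv             # or builtin: true (packaged stability data)
      half_life_constant: 0.693
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import calibration as _cal
from . import kinetics as _kin
from . import peakmetrics as _pm
from . import synthetic_data as _syn
from . import validation_metrics as _vm
from .errors import ConfigError

__all__ = ["ValidationReport", "run_pipeline", "render_report"]

SECTIONS = ("suitability", "linearity", "limits", "accuracy", "precision",
            "robustness", "kinetics")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _skip(reason: str) -> dict:
    return {"skipped": True, "reason": reason}


@dataclass
class ValidationReport:
    """Assembled results of every validation stage.

    ``sections`` maps each stage name to either its result dict or a
    ``{"skipped": True, "reason": ...}`` marker; ``verdicts`` holds the
    per-section pass flags (absent for skipped sections) and ``overall``
    their conjunction.
    """

    sections: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.verdicts.values()) if self.verdicts else False

    def to_dict(self) -> dict:
        return {
            "sections": self.sections,
            "verdicts": self.verdicts,
            "overall": self.overall,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ValidationReport":
        return cls(
            sections=dict(d.get("sections", {})),
            verdicts=dict(d.get("verdicts", {})),
            provenance=dict(d.get("provenance", {})),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ValidationReport):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and non-finite floats."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return {"inf": obj > 0} if not np.isnan(obj) else None
    return obj


def _resolve(base: Path | None, name: str) -> Path:
    p = Path(name)
    if not p.is_absolute() and base is not None:
        p = base / p
    if not p.exists():
        raise FileNotFoundError(p)
    return p


def read_robustness_csv(path: str | Path) -> tuple[dict, list]:
    """Read robustness conditions: factor, value, optional is_baseline flag,
    remaining numeric columns as metrics.  Without an explicit flag the first
    row is the baseline.  Returns (baseline metrics, variant triples)."""
    df = pd.read_csv(path)
    meta = [c for c in ("block", "factor", "value", "is_baseline") if c in df.columns]
    if "factor" not in meta or "value" not in meta:
        raise ConfigError(f"{path}: robustness file needs 'factor' and 'value' columns")
    metric_cols = [c for c in df.columns if c not in meta and not c.startswith("pct_")]
    if "is_baseline" in df.columns:
        base_rows = df[df["is_baseline"].astype(bool)]
        if base_rows.empty:
            raise ConfigError(f"{path}: no baseline row flagged")
        base = base_rows.iloc[0]
    else:
        base = df.iloc[0]
    baseline = {c: float(base[c]) for c in metric_cols}
    variants = []
    for _, row in df.iterrows():
        metrics = {c: float(row[c]) for c in metric_cols}
        if metrics == baseline:  # the baseline condition may repeat per block
            continue
        variants.append((str(row["factor"]), row["value"], metrics))
    return baseline, variants


def _stage_suitability(cfg: Mapping, base: Path | None, limits: Mapping) -> tuple[dict, bool]:
    peaks = _pm.read_peak_table(_resolve(base, cfg["file"]))
    res = _pm.assess_suitability(peaks, limits=limits.get("suitability"))
    return res.to_dict(), res.all_passed


def _stage_calibration(cfg: Mapping, base: Path | None, seed: int) -> _cal.CalibrationSummary:
    if "file" in cfg:
        series = _cal.read_calibration_csv(_resolve(base, cfg["file"]))
    elif "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", seed)
        if "levels" in sim:
            sim["levels"] = tuple(sim["levels"])
        series = _syn.simulate_calibration(_syn.CalibrationSimSpec(**sim))
    else:
        raise ConfigError("calibration stage needs 'file' or 'simulate'")
    return _cal.calibrate(
        series,
        schemes=tuple(cfg.get("schemes", _cal.WEIGHT_SCHEMES)),
        confidence=float(cfg.get("confidence", 0.99)),
        lod_basis=cfg.get("lod_basis", "residual"),
    )


def _stage_level_metric(cfg: Mapping, base: Path | None, limit: float, which: str) -> tuple[list, bool]:
    df = pd.read_csv(_resolve(base, cfg["file"]))
    for col in ("level", "value"):
        if col not in df.columns:
            raise ConfigError(f"{which} file needs columns 'level' and 'value'")
    if "kind" not in df.columns:
        df["kind"] = "intra-day"
    out = []
    for (level, kind), grp in df.groupby(["level", "kind"], sort=True):
        if which == "accuracy":
            res = _vm.accuracy(float(level), grp["value"].to_numpy(), limit=limit)
            d = res.to_dict()
            d["kind"] = kind
        else:
            res = _vm.precision(grp["value"].to_numpy(), kind=str(kind),
                                level=float(level), limit=limit)
            d = res.to_dict()
        out.append(d)
    return out, all(d["passed"] for d in out)


def _stage_kinetics(cfg: Mapping, base: Path | None) -> tuple[list, bool]:
    if cfg.get("builtin"):
        series = _kin.load_reference_stability()
    elif "file" in cfg:
        series = _kin.read_kinetic_csv(_resolve(base, cfg["file"]))
    else:
        raise ConfigError("kinetics stage needs 'file' or 'builtin: true'")
    const = float(cfg.get("half_life_constant", _kin.HALF_LIFE_CONSTANT))
    fits = [
        _kin.fit_first_order(s, half_life_constant=const,
                             use_replicates=bool(cfg.get("use_replicates", False)))
        for s in series.values()
    ]
    return [f.to_dict() for f in fits], True


def run_pipeline(config: Mapping, base_dir: str | Path | None = None) -> ValidationReport:
    """Execute all configured stages and assemble a :class:`ValidationReport`.

    Relative input paths resolve against ``base_dir``.  A stage whose input
    is missing or unconfigured is marked skipped with the reason; malformed
    files raise :class:`~chromaval.errors.ConfigError` naming the file.
    """
    base = Path(base_dir) if base_dir is not None else None
    limits = dict(config.get("limits", {}))
    seed = int(config.get("seed", 0))
    report = ValidationReport()
    inputs: dict = {}

    def record_input(cfg: Mapping) -> None:
        if isinstance(cfg, Mapping) and "file" in cfg:
            try:
                p = _resolve(base, cfg["file"])
                inputs[str(cfg["file"])] = _digest(p)
            except FileNotFoundError:
                pass

    # suitability
    cfg = config.get("suitability")
    if not cfg:
        report.sections["suitability"] = _skip("no suitability input configured")
    else:
        try:
            record_input(cfg)
            sec, ok = _stage_suitability(cfg, base, limits)
            report.sections["suitability"] = sec
            report.verdicts["suitability"] = ok
        except FileNotFoundError as e:
            report.sections["suitability"] = _skip(f"input not found: {e}")

    # linearity + detection limits
    cfg = config.get("calibration")
    if not cfg:
        report.sections["linearity"] = _skip("no calibration input configured")
        report.sections["limits"] = _skip("no calibration input configured")
    else:
        try:
            record_input(cfg)
            summary = _stage_calibration(cfg, base, seed)
            report.sections["linearity"] = summary.to_dict()
            report.sections["limits"] = {
                "ols": summary.limits_ols.to_dict(),
                "selected": summary.limits_best.to_dict(),
            }
            r_min = float(limits.get("r_min", 0.99))
            report.verdicts["linearity"] = abs(summary.best.r) >= r_min
        except FileNotFoundError as e:
            report.sections["linearity"] = _skip(f"input not found: {e}")
            report.sections["limits"] = _skip(f"input not found: {e}")

    # accuracy / precision
    for which in ("accuracy", "precision"):
        cfg = config.get(which)
        if not cfg:
            report.sections[which] = _skip(f"no {which} input configured")
            continue
        try:
            record_input(cfg)
            rows, ok = _stage_level_metric(
                cfg, base, float(limits.get(f"{which}_pct", 5.0)), which
            )
            report.sections[which] = {"rows": rows}
            report.verdicts[which] = ok
        except FileNotFoundError as e:
            report.sections[which] = _skip(f"input not found: {e}")

    # robustness
    cfg = config.get("robustness")
    if not cfg:
        report.sections["robustness"] = _skip("no robustness input configured")
    else:
        try:
            record_input(cfg)
            baseline, variants = read_robustness_csv(_resolve(base, cfg["file"]))
            rows = _vm.robustness_table(
                baseline, variants, limit=float(limits.get("robustness_pct", 10.0))
            )
            report.sections["robustness"] = {
                "baseline": baseline,
                "rows": [r.to_dict() for r in rows],
            }
            report.verdicts["robustness"] = all(r.passed for r in rows)
        except FileNotFoundError as e:
            report.sections["robustness"] = _skip(f"input not found: {e}")

    # kinetics
    cfg = config.get("kinetics")
    if not cfg:
        report.sections["kinetics"] = _skip("no kinetics input configured")
    else:
        try:
            record_input(cfg)
            fits, ok = _stage_kinetics(cfg, base)
            report.sections["kinetics"] = {"fits": fits}
            report.verdicts["kinetics"] = ok
        except FileNotFoundError as e:
            report.sections["kinetics"] = _skip(f"input not found: {e}")

    report.sections = _jsonable(report.sections)
    report.provenance = {
        "package": "chromaval",
        "version": __version__,
        "seed": seed,
        "inputs": inputs,
        "limits": _jsonable(limits),
        "generated_at": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    }
    return report


def _markdown(report: ValidationReport) -> str:
    """Human-readable report, numbers rounded to report-table precision."""
    lines = [f"# Method validation report (chromaval {report.provenance.get('version', '')})", ""]
    sec = report.sections

    def skipped(name: str) -> bool:
        s = sec.get(name)
        if s is None or (isinstance(s, dict) and s.get("skipped")):
            reason = (s or {}).get("reason", "not configured")
            lines.extend([f"## {name.capitalize()}", "", f"_skipped: {reason}_", ""])
            return True
        return False

    if not skipped("suitability"):
        s = sec["suitability"]
        lines += ["## System suitability", "",
                  "| Parameter | Result | Pass |", "|---|---|---|"]
        for key, label in [("k_prime", "Capacity factor (k')"),
                           ("n_plates", "Theoretical plates (N)"),
                           ("asymmetry", "Asymmetry factor (As)"),
                           ("rsd_t_r", "Repeatability of t_R (%)"),
                           ("rsd_area", "Repeatability of peak area (%)")]:
            lines.append(f"| {label} | {s[key]:.2f} | {s['passed'][key]} |")
        lines.append("")
    if not skipped("linearity"):
        s = sec["linearity"]
        h = s["homoscedasticity"]
        h_line = (
            f"Heteroscedastic: {h['heteroscedastic']} "
            f"(F_calc = {h['f_calc']:.1f}, F_crit = {h['f_crit']:.1f})"
            if "f_calc" in h
            else f"Variance F-test undefined: {h.get('undefined', '')}"
        )
        lines += ["## Linearity", "", h_line, "",
                  "| w_i | a | b | r | Σ%RE |", "|---|---|---|---|---|"]
        for f in s["fits"]:
            lines.append(
                f"| {f['scheme']} | {f['slope']:.0f} | {f['intercept']:.0f} "
                f"| {f['r']:.4f} | {f['sum_abs_re']:.0f} |"
            )
        lines += ["", f"Selected scheme: {s['selected_scheme']}", ""]
    if not skipped("limits"):
        s = sec["limits"]
        lines += ["## Detection limits", "",
                  "| Basis | LOD (mg/mL) | LOQ (mg/mL) |", "|---|---|---|"]
        for key in ("ols", "selected"):
            d = s[key]
            lines.append(f"| {d['basis']} | {d['lod']:.3f} | {d['loq']:.3f} |")
        lines.append("")
    if not skipped("accuracy"):
        lines += ["## Accuracy", "", "| Level (mg/mL) | Kind | ε_r (%) | Pass |", "|---|---|---|---|"]
        for r in sec["accuracy"]["rows"]:
            lines.append(f"| {r['level']} | {r.get('kind', '')} | {r['eps_r']:.2f} | {r['passed']} |")
        lines.append("")
    if not skipped("precision"):
        lines += ["## Precision", "", "| Level (mg/mL) | Kind | RSD (%) | Pass |", "|---|---|---|---|"]
        for r in sec["precision"]["rows"]:
            lines.append(f"| {r['level']} | {r['kind']} | {r['rsd']:.2f} | {r['passed']} |")
        lines.append("")
    if not skipped("robustness"):
        rows = sec["robustness"]["rows"]
        metrics = list(rows[0]["metrics"]) if rows else []
        lines += ["## Robustness", "",
                  "| Factor | Value | " + " | ".join(metrics) + " | Pass |",
                  "|---" * (len(metrics) + 3) + "|"]
        for r in rows:
            cells = " | ".join(
                f"{r['metrics'][m]:g} ({r['rel_err'][m]:.2f}%)"
                if isinstance(r['rel_err'][m], float) and np.isfinite(r['rel_err'][m])
                else f"{r['metrics'][m]:g} (n/a)"
                for m in metrics
            )
            lines.append(f"| {r['factor']} | {r['value']} | {cells} | {r['passed']} |")
        lines.append("")
    if not skipped("kinetics"):
        lines += ["## Degradation kinetics", "",
                  "| Series | R² | k (h⁻¹) | t₀.₅ (h) | t₀.₅ (days) |",
                  "|---|---|---|---|---|"]
        for f in sec["kinetics"]["fits"]:
            th, td = f["t_half_hours"], f["t_half_days"]
            th_s = f"{th:.2f}" if isinstance(th, float) else "∞"
            td_s = f"{td:.2f}" if isinstance(td, float) else "∞"
            lines.append(
                f"| {f['label']} | {f['r_squared']:.4f} | {f['k_per_hour']:.4f} "
                f"| {th_s} | {td_s} |"
            )
        lines.append("")
    lines += [f"**Overall verdict: {'PASS' if report.overall else 'FAIL'}**", ""]
    return "\n".join(lines)


def _csv_bundle(report: ValidationReport) -> dict[str, pd.DataFrame]:
    """One DataFrame per populated tabular section."""
    out: dict[str, pd.DataFrame] = {}
    sec = report.sections

    def live(name: str) -> bool:
        s = sec.get(name)
        return isinstance(s, dict) and not s.get("skipped")

    if live("suitability"):
        s = sec["suitability"]
        out["suitability"] = pd.DataFrame(
            {"parameter": ["k_prime", "n_plates", "asymmetry", "rsd_t_r", "rsd_area"],
             "result": [s[k] for k in ("k_prime", "n_plates", "asymmetry", "rsd_t_r", "rsd_area")],
             "passed": [s["passed"][k] for k in ("k_prime", "n_plates", "asymmetry", "rsd_t_r", "rsd_area")]}
        )
    if live("linearity"):
        out["linearity"] = pd.DataFrame(sec["linearity"]["fits"])
    if live("limits"):
        out["limits"] = pd.DataFrame([sec["limits"]["ols"], sec["limits"]["selected"]])
    if live("accuracy"):
        out["accuracy"] = pd.DataFrame(sec["accuracy"]["rows"])
    if live("precision"):
        out["precision"] = pd.DataFrame(sec["precision"]["rows"])
    if live("robustness"):
        rows = sec["robustness"]["rows"]
        flat = []
        for r in rows:
            d = {"factor": r["factor"], "value": r["value"], "passed": r["passed"]}
            d.update({f"{m}": r["metrics"][m] for m in r["metrics"]})
            d.update({f"rel_err_{m}": r["rel_err"][m] for m in r["rel_err"]})
            flat.append(d)
        out["robustness"] = pd.DataFrame(flat)
    if live("kinetics"):
        out["kinetics"] = pd.DataFrame(sec["kinetics"]["fits"])
    return out


def render_report(report: ValidationReport, format: str = "json",
                  out_dir: str | Path | None = None):
    """Serialize a report.

    ``json`` returns a schema-stable JSON string (machine precision);
    ``markdown`` returns a document with one table per section, rounded to
    report precision; ``csv-bundle`` returns {name: DataFrame} and, when
    ``out_dir`` is given, writes one CSV per table there.
    """
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format == "markdown":
        return _markdown(report)
    if format in ("csv", "csv-bundle"):
        bundle = _csv_bundle(report)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for name, df in bundle.items():
                df.to_csv(out / f"{name}.csv", index=False)
        return bundle
    raise ConfigError(f"unknown report format {format!r}")
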