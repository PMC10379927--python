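"""Method-validation statistics: precision, suitability, limits, selectivity.

Precision uses the sample standard deviation (n-1 denominator) and the
coefficient of variation CV = 100 * S / mean.  Intraday precision pools the
same-day replicates of each calibration level; interday precision takes the
CV across day means per level.  System suitability is the RSD of retention
time and area over consecutive injections of one standard level.  Detection
limits follow the two conventional numeric routes: signal-to-noise
(LOD = 3 * noise / slope, LOQ = 10 * noise / slope) and residual-SD
(LOD = 3.3 * s_y / slope, LOQ = 10 * s_y / slope).
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import CalibrationFit

__all__ = [
    "ReplicateSet",
    "PrecisionResult",
    "SuitabilityResult",
    "DetectionLimits",
    "SelectivityVerdict",
    "ValidationReport",
    "precision",
    "summary_cv",
    "system_suitability",
    "detection_limits",
    "selectivity_report",
    "build_report",
]


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate measurements for one level (and optionally one day)."""

    label: str
    values: "tuple[float, ...]"
    day: Optional[str] = None

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise ValueError("at least two values required for a CV")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class PrecisionResult:
    label: str
    mean: float
    sd: float  # sample SD, n-1 denominator
    cv: float  # percent, 100 * sd / mean
    mode: str  # "intraday" | "interday"
    n: int
    undefined: bool = False  # mean == 0, CV meaningless


def _sd_cv(values: Sequence[float]) -> "tuple[float, float, float, bool]":
    vals = [float(v) for v in values]
    mean = statistics.fmean(vals)
    sd = statistics.stdev(vals)
    if mean == 0.0:
        return mean, sd, math.nan, True
    return mean, sd, 100.0 * sd / mean, False


def precision(groups: Sequence[ReplicateSet], mode: str) -> "list[PrecisionResult]":
    """Per-level precision.

    intraday: each group is one level's same-day replicates; SD/CV within
    the group.  interday: groups sharing a label across >= 2 distinct days
    are reduced to day means, and the SD/CV is taken across those means.
    """
    if mode not in ("intraday", "interday"):
        raise ValueError("mode must be 'intraday' or 'interday'")
    results = []
    if mode == "intraday":
        for g in groups:
            mean, sd, cv, undef = _sd_cv(g.values)
            results.append(PrecisionResult(g.label, mean, sd, cv, mode,
                                           len(g.values), undef))
        return results
    by_label: "dict[str, dict[str, list[float]]]" = {}
    for g in groups:
        if g.day is None:
            raise ValueError("interday groups need a day identifier")
        by_label.setdefault(g.label, {}).setdefault(g.day, []).extend(g.values)
    for label, days in sorted(by_label.items()):
        if len(days) < 2:
            raise ValueError(f"label {label!r} has fewer than 2 distinct days")
        day_means = [statistics.fmean(v) for _, v in sorted(days.items())]
        mean, sd, cv, undef = _sd_cv(day_means)
        n = sum(len(v) for v in days.values())
        results.append(PrecisionResult(label, mean, sd, cv, "interday", n, undef))
    return results


def summary_cv(results: Sequence[PrecisionResult]) -> float:
    """Study-level precision: mean of the per-level CVs (percent)."""
    cvs = [r.cv for r in results if not r.undefined]
    if not cvs:
        raise ValueError("no defined CVs to summarise")
    return float(statistics.fmean(cvs))


@dataclass(frozen=True)
class SuitabilityResult:
    rt_rsd: float  # percent
    area_rsd: float  # percent
    n: int
    threshold: float  # percent
    passed: bool


def system_suitability(injections: "Sequence[tuple[float, float]]",
                       rsd_threshold: float = 2.0,
                       min_injections: int = 6) -> SuitabilityResult:
    """Repeatability of retention time and area over consecutive injections.

    Default pass threshold 2.0% RSD; use 1.0% for the strict guideline
    profile.
    """
    if len(injections) < min_injections:
        raise ValueError(f"need at least {min_injections} injections")
    rts = [float(rt) for rt, _ in injections]
    areas = [float(a) for _, a in injections]
    _, _, rt_rsd, rt_undef = _sd_cv(rts)
    _, _, area_rsd, a_undef = _sd_cv(areas)
    if rt_undef or a_undef:
        raise ValueError("zero-mean injections: RSD undefined")
    passed = rt_rsd <= rsd_threshold and area_rsd <= rsd_threshold
    return SuitabilityResult(rt_rsd, area_rsd, len(injections),
                             rsd_threshold, passed)


@dataclass(frozen=True)
class DetectionLimits:
    lod: float  # ug/mL
    loq: float  # ug/mL
    method: str  # "signal-to-noise" | "residual-sd"

    def __post_init__(self) -> None:
        if not 0 < self.lod < self.loq:
            raise ValueError("require 0 < LOD < LOQ")


def detection_limits(fit: "CalibrationFit | None" = None,
                     noise_sd: "float | None" = None,
                     method: str = "signal-to-noise") -> DetectionLimits:
    """LOD/LOQ by one of the two conventional numeric methods.

    signal-to-noise needs ``noise_sd`` in area units and a fitted slope;
    residual-sd needs a fit with dispersions computed (uses s_y).
    """
    if fit is None:
        raise ValueError("a calibration fit is required")
    if fit.slope <= 0:
        raise ValueError("slope must be positive")
    if method == "signal-to-noise":
        if noise_sd is None or noise_sd <= 0:
            raise ValueError("signal-to-noise method needs a positive noise_sd")
        return DetectionLimits(3.0 * noise_sd / fit.slope,
                               10.0 * noise_sd / fit.slope, method)
    if method == "residual-sd":
        if fit.s_y is None:
            raise ValueError("residual-sd method needs dispersions (s_y)")
        if fit.s_y <= 0:
            raise ValueError("residual-sd method needs a positive s_y")
        return DetectionLimits(3.3 * fit.s_y / fit.slope,
                               10.0 * fit.s_y / fit.slope, method)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SelectivityVerdict:
    purity: float
    passed: bool


def selectivity_report(purities: "dict[str, float]",
                       threshold: float = 0.95) -> "dict[str, SelectivityVerdict]":
    """Pass/fail per analyte; the 95% boundary is inclusive."""
    out = {}
    for name, p in purities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"purity for {name!r} outside [0, 1]")
        out[name] = SelectivityVerdict(float(p), p >= threshold)
    return out


@dataclass
class ValidationReport:
    """The assembled validation record: one serialisable object per study."""

    fit: CalibrationFit
    precision: "list[PrecisionResult]"
    suitability: SuitabilityResult
    limits: DetectionLimits
    selectivity: "dict[str, SelectivityVerdict]"

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "precision": [asdict(p) for p in self.precision],
            "suitability": asdict(self.suitability),
            "limits": asdict(self.limits),
            "selectivity": {k: asdict(v) for k, v in self.selectivity.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(
            fit=CalibrationFit.from_dict(d["fit"]),
            precision=[PrecisionResult(**p) for p in d["precision"]],
            suitability=SuitabilityResult(**d["suitability"]),
            limits=DetectionLimits(**d["limits"]),
            selectivity={k: SelectivityVerdict(**v)
                         for k, v in d["selectivity"].items()},
        )

    @classmethod
    def from_json(cls, s: str) -> "ValidationReport":
        return cls.from_dict(json.loads(s))

    def to_markdown(self) -> str:
        """Human-readable validation table."""
        f = self.fit
        lines = [
            "| Parameter | Value | Verdict |",
            "|---|---|---|",
            f"| Analytical curve | y = {f.slope:.1f}x + {f.intercept:.1f} "
            f"(R2 = {f.r_squared:.4f}, n = {f.n}) | |",
            f"| Slope t test | t = {f.t_slope:.2f} vs t_crit = {f.t_critical:.3f} | "
            f"{'significant' if f.slope_significant else 'not significant'} |",
            f"| Intercept t test | t = {f.t_intercept:.2f} vs t_crit = {f.t_critical:.3f} | "
            f"{'significant' if f.intercept_significant else 'not significant'} |",
            f"| Regression F test | F = {f.f_stat:.2f} vs F_crit = {f.f_critical:.3f} | "
            f"{'significant' if f.regression_significant else 'not significant'} |",
        ]
        by_mode: "dict[str, list[PrecisionResult]]" = {}
        for p in self.precision:
            by_mode.setdefault(p.mode, []).append(p)
        for mode, results in sorted(by_mode.items()):
            cv = summary_cv(results)
            n = results[0].n if results else 0
            lines.append(f"| {mode.capitalize()} precision (n = {n}) | "
                         f"CV = {cv:.2f}% | |")
        s = self.suitability
        lines.append(
            f"| System suitability (n = {s.n}) | RT RSD {s.rt_rsd:.2f}%, "
            f"area RSD {s.area_rsd:.2f}% | {'pass' if s.passed else 'fail'} |")
        lines.append(f"| LOD ({self.limits.method}) | {self.limits.lod:.2f} ug/mL | |")
        lines.append(f"| LOQ ({self.limits.method}) | {self.limits.loq:.2f} ug/mL | |")
        for name, v in sorted(self.selectivity.items()):
            lines.append(f"| Selectivity {name} | purity {100 * v.purity:.2f}% | "
                         f"{'pass' if v.passed else 'fail'} |")
        return "\n".join(lines)


def build_report(fit: "CalibrationFit | None" = None,
                 precision_results: "Sequence[PrecisionResult] | None" = None,
                 suitability: "SuitabilityResult | None" = None,
                 limits: "DetectionLimits | None" = None,
                 selectivity: "dict[str, SelectivityVerdict] | None" = None,
                 ) -> ValidationReport:
    """Assemble the full report; rejects with the name of a missing part."""
    missing = [name for name, v in (
        ("fit", fit), ("precision_results", precision_results),
        ("suitability", suitability), ("limits", limits),
        ("selectivity", selectivity)) if v is None]
    if missing:
        raise ValueError(f"missing validation components: {', '.join(missing)}")
    return ValidationReport(fit, list(precision_results), suitability,
                            limits, dict(selectivity))
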