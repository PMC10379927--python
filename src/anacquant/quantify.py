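"""Sequential-extraction quantification and recovery.

A sample (0.5 g of freeze-dried peduncle powder by default) is extracted
repeatedly; each extract is reconstituted (3 mL by default), injected, and
the analyte peak area converted to a dry-weight amount through the
calibration line:

    concentration [ug/mL] = (area - b) / a
    amount [mg/100 g]     = concentration * V[mL] / m[g] * 0.1

Recovery per extraction step is each step's share of the summed raw peak
area over all steps,

    R%(x) = A_x / sum(A_n) * 100,

computed on raw areas of *all* records, including those censored below the
limit of quantification — censored steps still carry signal, they are just
not trusted as amounts.  Amount totals, in contrast, exclude censored
records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .calibration import CalibrationFit, invert

__all__ = [
    "ExtractionRecord",
    "ExtractionSeries",
    "RecoveryMatrix",
    "QuantReport",
    "AmountResult",
    "amount_from_area",
    "quantify_series",
    "censor",
    "recovery_matrix",
    "extractions_needed",
    "clone_totals",
]

DEFAULT_VOLUME_ML = 3.0  # reconstitution volume
DEFAULT_MASS_G = 0.5  # powder mass per extraction


@dataclass(frozen=True)
class AmountResult:
    concentration: float  # ug/mL
    amount: float  # mg/100 g dry weight
    flags: "frozenset[str]" = frozenset()


@dataclass(frozen=True)
class ExtractionRecord:
    """One extraction step of one sample x analyte."""

    sample: str
    analyte: str
    extraction_index: int  # 1-based
    area: Optional[float] = None  # raw peak area; None when only amounts known
    concentration: Optional[float] = None  # ug/mL
    amount: Optional[float] = None  # mg/100 g dry weight
    censored: bool = False  # below LOQ: excluded from amount totals
    flags: "frozenset[str]" = frozenset()

    def __post_init__(self) -> None:
        if self.extraction_index < 1:
            raise ValueError("extraction_index is 1-based")
        if self.amount is not None and self.amount < 0 and not self.censored:
            raise ValueError("negative amount on an uncensored record")


@dataclass(frozen=True)
class ExtractionSeries:
    """Ordered extraction records for one sample x analyte."""

    sample: str
    analyte: str
    records: "tuple[ExtractionRecord, ...]"
    volume: float = DEFAULT_VOLUME_ML  # mL
    mass: float = DEFAULT_MASS_G  # g

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.mass <= 0:
            raise ValueError("volume and mass must be positive")
        recs = tuple(sorted(self.records, key=lambda r: r.extraction_index))
        idx = [r.extraction_index for r in recs]
        if idx != list(range(1, len(recs) + 1)):
            raise ValueError("extraction indices must be contiguous from 1")
        object.__setattr__(self, "records", recs)

    @classmethod
    def from_areas(cls, sample: str, analyte: str, areas: Sequence[float],
                   volume: float = DEFAULT_VOLUME_ML, mass: float = DEFAULT_MASS_G,
                   ) -> "ExtractionSeries":
        recs = tuple(
            ExtractionRecord(sample, analyte, i + 1, area=float(a))
            for i, a in enumerate(areas)
        )
        return cls(sample, analyte, recs, volume, mass)

    @classmethod
    def from_amounts(cls, sample: str, analyte: str,
                     amounts: "Sequence[float | None]",
                     volume: float = DEFAULT_VOLUME_ML, mass: float = DEFAULT_MASS_G,
                     ) -> "ExtractionSeries":
        """Build from reported amounts; ``None`` marks a censored (<LOQ) step."""
        recs = tuple(
            ExtractionRecord(sample, analyte, i + 1,
                             amount=(0.0 if a is None else float(a)),
                             censored=(a is None))
            for i, a in enumerate(amounts)
        )
        return cls(sample, analyte, recs, volume, mass)

    def total_amount(self) -> float:
        """Sum of non-censored amounts, mg/100 g."""
        return float(sum(r.amount for r in self.records
                         if not r.censored and r.amount is not None))


def amount_from_area(area: float, fit: CalibrationFit,
                     volume: float = DEFAULT_VOLUME_ML,
                     mass: float = DEFAULT_MASS_G) -> AmountResult:
    """Convert a peak area to concentration and dry-weight amount.

    A negative back-calculated concentration yields amount 0 with a flag;
    concentrations outside the calibration range are flagged rather than
    silently extrapolated.
    """
    if volume <= 0 or mass <= 0:
        raise ValueError("volume and mass must be positive")
    conc, extrapolated = invert(fit, area)
    flags: "set[str]" = set()
    if conc < 0:
        flags.add("negative_concentration")
        amount = 0.0
    else:
        amount = conc * volume / mass * 0.1  # ug/g -> mg/100 g
    if extrapolated:
        flags.add("above_calibration_range" if conc > fit.x_max
                  else "below_calibration_range")
    return AmountResult(float(conc), float(amount), frozenset(flags))


def quantify_series(series: ExtractionSeries, fit: CalibrationFit) -> ExtractionSeries:
    """Fill concentration and amount on every record from its raw area."""
    recs = []
    for r in series.records:
        if r.area is None:
            raise ValueError(f"record {r.extraction_index} has no raw area")
        res = amount_from_area(r.area, fit, series.volume, series.mass)
        recs.append(replace(r, concentration=res.concentration,
                            amount=res.amount, flags=r.flags | res.flags))
    return replace(series, records=tuple(recs))


def censor(series: ExtractionSeries, limits) -> ExtractionSeries:
    """Mark records with concentration strictly below the LOQ as censored.

    A concentration exactly at the LOQ is quantifiable (inclusive boundary).
    Raw areas are retained: recovery percentages still use them.
    """
    loq = float(limits.loq)
    recs = []
    for r in series.records:
        if r.concentration is None:
            raise ValueError("quantify the series before censoring")
        recs.append(replace(r, censored=bool(r.concentration < loq)))
    return replace(series, records=tuple(recs))


@dataclass(frozen=True)
class RecoveryMatrix:
    """Per-extraction recovery percentages and their running totals."""

    per_extraction: "tuple[float, ...]"  # percent, one per extraction index
    cumulative: "tuple[float, ...]"  # percent, prefix sums

    @classmethod
    def from_percentages(cls, values: Sequence[float],
                         sum_tolerance: float = 1.5) -> "RecoveryMatrix":
        """Build directly from already-normalised recovery percentages.

        Accepts rows whose values sum to 100 within ``sum_tolerance``;
        published presentation-rounded rows can be off by as much as ~1%.
        """
        vals = tuple(float(v) for v in values)
        if not vals:
            raise ValueError("empty recovery row")
        if any(v < 0 for v in vals):
            raise ValueError("recovery percentages must be non-negative")
        total = sum(vals)
        if abs(total - 100.0) > sum_tolerance:
            raise ValueError(f"recovery row sums to {total:.2f}%, not ~100%")
        cum = tuple(float(c) for c in np.cumsum(vals))
        return cls(vals, cum)


def recovery_matrix(series: ExtractionSeries) -> RecoveryMatrix:
    """Per-step recovery from raw areas of all records (censored included)."""
    areas = []
    for r in series.records:
        if r.area is None:
            raise ValueError(f"record {r.extraction_index} has no raw area")
        areas.append(max(float(r.area), 0.0))
    total = sum(areas)
    if total <= 0:
        raise ValueError("all areas are zero; recovery undefined")
    per = tuple(a / total * 100.0 for a in areas)
    cum = tuple(float(c) for c in np.cumsum(per))
    return RecoveryMatrix(per, cum)


def extractions_needed(matrix: RecoveryMatrix, threshold: float = 90.0) -> int:
    """Minimal number of sequential extractions reaching ``threshold``%."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    for k, c in enumerate(matrix.cumulative, start=1):
        if c >= threshold:
            return k
    # printed rounding can leave the final cumulative a hair under 100
    if threshold <= 100.0 and matrix.cumulative:
        return len(matrix.cumulative)
    raise ValueError("threshold unreachable")


@dataclass(frozen=True)
class QuantReport:
    """Clone-level totals: per analyte, per clone, and the study range."""

    totals: "dict[tuple[str, str], float]"  # (sample, analyte) -> mg/100 g
    grand_totals: "dict[str, float]"  # sample -> mg/100 g
    incomplete: "frozenset[str]"  # samples missing an analyte series
    min_sample: str
    max_sample: str

    @property
    def min_total(self) -> float:
        return self.grand_totals[self.min_sample]

    @property
    def max_total(self) -> float:
        return self.grand_totals[self.max_sample]

    @classmethod
    def from_totals(cls, totals: "dict[str, dict[str, float]]") -> "QuantReport":
        """Build from per-analyte totals (e.g. a published totals column)."""
        flat = {(s, a): float(v) for s, d in totals.items() for a, v in d.items()}
        return _assemble_report(flat)


def _assemble_report(flat: "dict[tuple[str, str], float]") -> QuantReport:
    samples = sorted({s for s, _ in flat})
    analytes = sorted({a for _, a in flat})
    grand = {s: float(sum(v for (ss, _), v in flat.items() if ss == s))
             for s in samples}
    incomplete = frozenset(
        s for s in samples if any((s, a) not in flat for a in analytes)
    )
    min_sample = min(samples, key=lambda s: grand[s])
    max_sample = max(samples, key=lambda s: grand[s])
    return QuantReport(dict(flat), grand, incomplete, min_sample, max_sample)


def clone_totals(series_set: Iterable[ExtractionSeries]) -> QuantReport:
    """Totals over a study: non-censored amounts per sample x analyte.

    Samples missing an analyte present elsewhere are totalled over what they
    have and flagged incomplete.
    """
    flat: "dict[tuple[str, str], float]" = {}
    for series in series_set:
        key = (series.sample, series.analyte)
        if key in flat:
            raise ValueError(f"duplicate series for {key}")
        flat[key] = series.total_amount()
    if not flat:
        raise ValueError("no extraction series supplied")
    return _assemble_report(flat)
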