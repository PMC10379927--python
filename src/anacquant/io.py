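"""File formats and run provenance.

All artifacts are plain text: comma-separated CSV (period decimal
separator, UTF-8, header required), JSON for fitted objects and reports,
YAML for the study configuration.  Validation is strict — a malformed value
or a non-monotone time axis is an error naming the offending line, never a
guess.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .calibration import CalibrationFit, CalibrationLevel
from .chromatogram import Chromatogram
from .peaks import Peak
from .quantify import ExtractionRecord, ExtractionSeries, QuantReport
from .validation import DetectionLimits

__all__ = [
    "read_chromatogram_csv",
    "write_chromatogram_csv",
    "read_peak_table_csv",
    "write_peak_table_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_extraction_csv",
    "write_extraction_csv",
    "write_fit_json",
    "read_fit_json",
    "write_limits_json",
    "read_limits_json",
    "write_quant_report_json",
    "StudyConfig",
    "RunLog",
]


def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    """Write as ``time_min, wl_200, ..., wl_400`` with full precision."""
    cols = ["time_min"] + [f"wl_{int(w)}" for w in chrom.wavelengths]
    df = pd.DataFrame(np.column_stack([chrom.times, chrom.absorbance]),
                      columns=cols)
    # %.17g: lossless decimal round trip for float64
    df.to_csv(path, index=False, float_format="%.17g")


def read_chromatogram_csv(path, sample_id: "str | None" = None) -> Chromatogram:
    """Read and validate a chromatogram CSV.

    Rejects missing/misnamed columns, non-numeric cells and non-monotone
    time stamps, reporting the first offending data line (1-based, header
    is line 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time_min":
        raise ValueError(f"{path}: first column must be 'time_min'")
    wl_cols = list(df.columns[1:])
    bad = [c for c in wl_cols if not c.startswith("wl_")]
    if bad or not wl_cols:
        raise ValueError(f"{path}: wavelength columns must be named wl_<nm>")
    wavelengths = np.array([float(c[3:]) for c in wl_cols])
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing/non-numeric value at data line {row + 2}")
    times = df["time_min"].to_numpy(dtype=float)
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.nonzero(diffs <= 0)[0][0]) + 1
        raise ValueError(
            f"{path}: time_min not strictly increasing at data line {row + 2}")
    return Chromatogram(times, wavelengths, df[wl_cols].to_numpy(dtype=float),
                        sample_id=sample_id or Path(str(path)).stem)


PEAK_COLUMNS = ["sample", "analyte", "apex_rt_min", "start_min", "end_min",
                "height_mau", "area_mau_min", "purity"]


def write_peak_table_csv(peaks: Sequence[Peak], path, sample: str = "") -> None:
    rows = []
    for p in peaks:
        rows.append({
            "sample": sample,
            "analyte": p.assigned_analyte.name if p.assigned_analyte else "",
            "apex_rt_min": p.apex_time,
            "start_min": p.start_time,
            "end_min": p.end_time,
            "height_mau": p.height,
            "area_mau_min": p.area,
            "purity": "" if p.purity is None else p.purity,
        })
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.12g")


def read_peak_table_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_calibration_csv(levels: Sequence[CalibrationLevel], path) -> None:
    rows = [
        {"concentration_ug_ml": lv.concentration, "replicate": i + 1, "area": a}
        for lv in levels for i, a in enumerate(lv.areas)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_calibration_csv(path) -> "list[CalibrationLevel]":
    df = pd.read_csv(path)
    required = {"concentration_ug_ml", "replicate", "area"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing value at data line {row + 2}")
    out = []
    for conc, grp in df.groupby("concentration_ug_ml", sort=True):
        out.append(CalibrationLevel(float(conc), tuple(grp["area"].astype(float))))
    return out


def write_extraction_csv(series_set: Sequence[ExtractionSeries], path) -> None:
    rows = [
        {"sample": s.sample, "analyte": s.analyte,
         "extraction_index": r.extraction_index, "area": r.area}
        for s in series_set for r in s.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_extraction_csv(path, volume: float = 3.0, mass: float = 0.5,
                        ) -> "list[ExtractionSeries]":
    df = pd.read_csv(path)
    required = {"sample", "analyte", "extraction_index", "area"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    out = []
    for (sample, analyte), grp in df.groupby(["sample", "analyte"], sort=True):
        grp = grp.sort_values("extraction_index")
        records = tuple(
            ExtractionRecord(str(sample), str(analyte),
                             int(r.extraction_index), area=float(r.area))
            for r in grp.itertuples()
        )
        out.append(ExtractionSeries(str(sample), str(analyte), records,
                                    volume, mass))
    return out


def write_fit_json(fit: CalibrationFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2))


def read_fit_json(path) -> CalibrationFit:
    return CalibrationFit.from_dict(json.loads(Path(path).read_text()))


def write_limits_json(limits: DetectionLimits, path) -> None:
    Path(path).write_text(json.dumps(asdict(limits), indent=2))


def read_limits_json(path) -> DetectionLimits:
    return DetectionLimits(**json.loads(Path(path).read_text()))


def write_quant_report_json(report: QuantReport, path) -> None:
    d = {
        "totals": [{"sample": s, "analyte": a, "total_mg_per_100g": v}
                   for (s, a), v in sorted(report.totals.items())],
        "grand_totals": dict(sorted(report.grand_totals.items())),
        "incomplete": sorted(report.incomplete),
        "min_sample": report.min_sample,
        "max_sample": report.max_sample,
        "min_total": report.min_total,
        "max_total": report.max_total,
    }
    Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class StudyConfig:
    """All thresholds and constants of one study, round-trippable via YAML."""

    purity_threshold: float = 0.95
    suitability_rsd_threshold: float = 2.0  # percent
    recovery_threshold: float = 90.0  # percent
    confidence: float = 0.95
    lod_loq_method: str = "residual-sd"
    reconstitution_volume_ml: float = 3.0
    sample_mass_g: float = 0.5
    calibration_levels: "tuple[float, ...]" = (1, 5, 10, 20, 40, 60, 80, 100)
    calibration_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.purity_threshold <= 1:
            raise ValueError("purity_threshold must be in (0, 1]")
        if not 0 < self.recovery_threshold <= 100:
            raise ValueError("recovery_threshold must be in (0, 100]")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        self.calibration_levels = tuple(float(x) for x in self.calibration_levels)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["calibration_levels"] = list(d["calibration_levels"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls(**yaml.safe_load(text))

    def digest(self) -> str:
        """Stable hash of the semantic content (key order independent)."""
        d = asdict(self)
        d["calibration_levels"] = list(d["calibration_levels"])
        canon = json.dumps(d, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunLog:
    """Timestamped stage events tied to a config digest."""

    config_digest: str
    version: str = _version
    events: "list[dict]" = field(default_factory=list)

    def record(self, stage: str, **details) -> None:
        self.events.append({"stage": stage, "time": _time.time(), **details})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)
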