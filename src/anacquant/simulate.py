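"""Synthetic DAD chromatograms, calibration series and extraction series.

Everything downstream of the detector is testable against ground truth
generated here.  The signal model is deliberately simple and matches what
the analysis stages assume:

* each analyte contributes an exponentially modified Gaussian peak in time
  (pure Gaussian when the tailing constant is zero), scaled across
  wavelength by its reference UV profile so that the 280 nm trace carries
  the nominal area;
* peak area at 280 nm follows the linear response ``area = slope*conc +
  intercept`` of the external-standard calibration;
* the baseline is linear (offset + drift) and detector noise is additive
  i.i.d. Gaussian on the absorbance matrix;
* retention times jitter between injections with a normal SD.

Sequential extractions are modelled by per-step efficiencies applied to the
analyte pool *remaining* before each step, which reproduces observed
depletion profiles that are not geometric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import erfc

from .calibration import CalibrationFit, CalibrationLevel
from .catalog import AnalyteDef, default_catalog
from .chromatogram import Chromatogram
from .quantify import (DEFAULT_MASS_G, DEFAULT_VOLUME_ML, ExtractionRecord,
                       ExtractionSeries)
from .spectra import UV_MAX_NM, UV_MIN_NM

__all__ = [
    "PeakTruth",
    "SimulationRecipe",
    "DepletionProfile",
    "CalibrationSeries",
    "ExtractionTruth",
    "emg_shape",
    "simulate_chromatogram",
    "simulate_calibration_series",
    "simulate_extraction_series",
]

# printed external-standard calibration of the triene at 280 nm
DEFAULT_SLOPE = 2333.5  # area per ug/mL
DEFAULT_INTERCEPT = 2956.2  # area
DEFAULT_LEVELS = (1.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0)  # ug/mL


@dataclass(frozen=True)
class PeakTruth:
    """Ground truth for one simulated peak (areas refer to the 280 nm trace)."""

    analyte: AnalyteDef
    true_area: float  # mAU*min
    true_rt: float  # minutes, after per-injection jitter
    amplitude: float  # mAU at peak maximum
    width_sigma: float  # minutes
    tailing_tau: float = 0.0  # minutes; 0 = pure Gaussian
    overlapped: bool = False  # closer than 2*sigma to a neighbour

    def __post_init__(self) -> None:
        for name in ("true_area", "true_rt", "amplitude", "width_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tailing_tau < 0:
            raise ValueError("tailing_tau must be non-negative")
        if self.tailing_tau == 0.0:
            expect = self.amplitude * self.width_sigma * math.sqrt(2 * math.pi)
            if not math.isclose(expect, self.true_area, rel_tol=1e-9):
                raise ValueError("Gaussian identity area = A*sigma*sqrt(2*pi) violated")


@dataclass(frozen=True)
class SimulationRecipe:
    """Full description of one simulated DAD injection."""

    analytes: "tuple[AnalyteDef, ...]" = None  # type: ignore[assignment]
    concentrations: "tuple[float, ...]" = None  # type: ignore[assignment]
    response_slope: float = DEFAULT_SLOPE
    response_intercept: float = DEFAULT_INTERCEPT
    peak_sigma: Union[float, "tuple[float, ...]"] = 0.1  # minutes
    tailing_tau: Union[float, "tuple[float, ...]"] = 0.0  # minutes
    noise_sd: float = 0.0  # mAU
    baseline_offset: float = 0.0  # mAU
    baseline_drift: float = 0.0  # mAU per minute
    rt_jitter_sd: float = 0.0  # minutes
    sampling_rate: float = 100.0  # points per minute
    run_length: float = 30.0  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        analytes = tuple(self.analytes) if self.analytes is not None \
            else tuple(default_catalog())
        object.__setattr__(self, "analytes", analytes)
        concs = tuple(float(c) for c in self.concentrations) \
            if self.concentrations is not None else (40.0,) * len(analytes)
        object.__setattr__(self, "concentrations", concs)
        if len(concs) != len(analytes):
            raise ValueError("one concentration per analyte required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sampling_rate <= 0 or self.run_length <= 0:
            raise ValueError("sampling_rate and run_length must be positive")
        sig = self._per_analyte(self.peak_sigma)
        for a, s in zip(analytes, sig):
            if a.retention_time + 3 * s > self.run_length:
                raise ValueError(
                    f"run_length {self.run_length} min does not cover "
                    f"{a.name} at {a.retention_time} min + 3 sigma"
                )

    def _per_analyte(self, value) -> "tuple[float, ...]":
        if np.isscalar(value):
            return (float(value),) * len(self.analytes)
        vals = tuple(float(v) for v in value)
        if len(vals) != len(self.analytes):
            raise ValueError("per-analyte parameter length mismatch")
        return vals


def emg_shape(t: np.ndarray, rt: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-area peak shape: Gaussian (tau = 0) or exponentially modified."""
    t = np.asarray(t, dtype=float)
    if tau <= 0.0:
        return np.exp(-0.5 * ((t - rt) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    z = (sigma / tau - (t - rt) / sigma) / math.sqrt(2)
    # log-space to avoid overflow of exp(sigma^2 / 2 tau^2)
    log_pre = sigma**2 / (2 * tau**2) - (t - rt) / tau - math.log(2 * tau)
    with np.errstate(over="ignore"):
        out = np.exp(log_pre) * erfc(z)
    return np.where(np.isfinite(out), out, 0.0)


def simulate_chromatogram(recipe: SimulationRecipe,
                          sample_id: str = "synthetic",
                          ) -> "tuple[Chromatogram, list[PeakTruth]]":
    """Render one injection and its ground-truth peak manifest.

    The truth manifest is computed before noise is drawn, so two recipes
    differing only in seed share identical :class:`PeakTruth` entries (when
    retention-time jitter is off) but different noise realisations.
    """
    rng = np.random.default_rng(recipe.seed)
    n_t = int(round(recipe.run_length * recipe.sampling_rate)) + 1
    times = np.linspace(0.0, recipe.run_length, n_t)
    wavelengths = np.arange(UV_MIN_NM, UV_MAX_NM + 1.0)
    absorb = np.zeros((times.size, wavelengths.size))

    sigmas = recipe._per_analyte(recipe.peak_sigma)
    taus = recipe._per_analyte(recipe.tailing_tau)
    # jitter first so the draw order is independent of which peaks are present
    jitter = rng.normal(0.0, recipe.rt_jitter_sd, size=len(recipe.analytes)) \
        if recipe.rt_jitter_sd > 0 else np.zeros(len(recipe.analytes))

    truths: "list[PeakTruth]" = []
    active = [(a, c, s, tau, a.retention_time + j)
              for a, c, s, tau, j in zip(recipe.analytes, recipe.concentrations,
                                         sigmas, taus, jitter)
              if c > 0]
    rts = [rt for *_, rt in active]
    for (analyte, conc, sigma, tau, rt) in active:
        area = recipe.response_slope * conc + recipe.response_intercept
        shape = area * emg_shape(times, rt, sigma, tau)
        scale = analyte.uv_profile.interp(wavelengths)
        at_280 = float(np.interp(280.0, wavelengths, scale))
        if at_280 <= 0:
            raise ValueError(f"{analyte.name} UV profile is zero at 280 nm")
        absorb += shape[:, None] * (scale / at_280)[None, :]
        overlapped = any(
            0 < abs(rt - other) < 2 * sigma for other in rts if other != rt
        )
        amplitude = area / (sigma * math.sqrt(2 * math.pi)) if tau == 0.0 \
            else float(np.max(area * emg_shape(times, rt, sigma, tau)))
        truths.append(PeakTruth(analyte, float(area), float(rt),
                                float(amplitude), float(sigma), float(tau),
                                overlapped))

    absorb += (recipe.baseline_offset + recipe.baseline_drift * times)[:, None]
    if recipe.noise_sd > 0:
        absorb += rng.normal(0.0, recipe.noise_sd, size=absorb.shape)

    chrom = Chromatogram(times, wavelengths, absorb, sample_id=sample_id)
    return chrom, truths


@dataclass(frozen=True)
class CalibrationSeries:
    """Simulated calibration data plus the truth that generated it."""

    levels: "tuple[CalibrationLevel, ...]"
    true_slope: float
    true_intercept: float
    cv_target: float
    seed: int


def simulate_calibration_series(levels: Sequence[float] = DEFAULT_LEVELS,
                                replicates: int = 3,
                                slope: float = DEFAULT_SLOPE,
                                intercept: float = DEFAULT_INTERCEPT,
                                cv_target: float = 0.002,
                                seed: int = 0) -> CalibrationSeries:
    """Replicate areas on a line with multiplicative noise of relative SD
    ``cv_target`` (the order of magnitude of sub-1% injection CVs)."""
    levels = tuple(float(x) for x in levels)
    if any(x <= 0 for x in levels) or len(set(levels)) != len(levels):
        raise ValueError("levels must be positive and distinct")
    if replicates < 1:
        raise ValueError("at least one replicate required")
    if cv_target < 0:
        raise ValueError("cv_target must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for x in levels:
        mean = slope * x + intercept
        noise = rng.normal(0.0, cv_target, size=replicates) if cv_target > 0 \
            else np.zeros(replicates)
        out.append(CalibrationLevel(x, tuple(mean * (1.0 + noise))))
    return CalibrationSeries(tuple(out), slope, intercept, cv_target, seed)


@dataclass(frozen=True)
class DepletionProfile:
    """Sequential-extraction depletion: per-step efficiency on the remaining pool.

    ``step_efficiencies[i]`` is the fraction of the analyte still present
    that step ``i+1`` removes; a trailing efficiency of 1.0 makes the
    extraction exhaustive.
    """

    total_amount: float  # mg/100 g dry weight
    step_efficiencies: "tuple[float, ...]"

    def __post_init__(self) -> None:
        if self.total_amount <= 0:
            raise ValueError("total_amount must be positive")
        eff = tuple(float(e) for e in self.step_efficiencies)
        if not eff or any(not 0.0 <= e <= 1.0 for e in eff):
            raise ValueError("efficiencies must be fractions in [0, 1]")
        object.__setattr__(self, "step_efficiencies", eff)

    def step_fractions(self) -> "tuple[float, ...]":
        """Fraction of the total recovered at each step (sums to <= 1)."""
        remaining = 1.0
        out = []
        for e in self.step_efficiencies:
            out.append(remaining * e)
            remaining -= out[-1]
        return tuple(out)

    def step_amounts(self) -> "tuple[float, ...]":
        return tuple(self.total_amount * f for f in self.step_fractions())

    @classmethod
    def from_step_fractions(cls, total_amount: float,
                            fractions: Sequence[float]) -> "DepletionProfile":
        """Invert observed per-step recovered fractions into efficiencies."""
        remaining = 1.0
        eff = []
        for f in fractions:
            if f < 0 or f > remaining + 1e-12:
                raise ValueError("fractions must be non-negative and sum to <= 1")
            eff.append(min(f / remaining, 1.0) if remaining > 0 else 0.0)
            remaining -= f
        return cls(total_amount, tuple(eff))


@dataclass(frozen=True)
class ExtractionTruth:
    """Ground truth accompanying a simulated extraction series."""

    profile: DepletionProfile
    true_amounts: "tuple[float, ...]"  # mg/100 g per step
    true_concentrations: "tuple[float, ...]"  # ug/mL per step
    true_areas: "tuple[float, ...]"


def simulate_extraction_series(profile: DepletionProfile,
                               fit: "CalibrationFit | None" = None,
                               volume: float = DEFAULT_VOLUME_ML,
                               mass: float = DEFAULT_MASS_G,
                               seed: int = 0,
                               cv: float = 0.0,
                               sample: str = "synthetic",
                               analyte: str = "AnAc 15:3",
                               slope: float = DEFAULT_SLOPE,
                               intercept: float = DEFAULT_INTERCEPT,
                               ) -> "tuple[ExtractionSeries, ExtractionTruth]":
    """Back-compute per-step areas through the calibration line, plus noise.

    ``fit`` overrides ``slope``/``intercept`` when given, so the same line
    used for inverse prediction can generate the areas.
    """
    if volume <= 0 or mass <= 0:
        raise ValueError("volume and mass must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if fit is not None:
        slope, intercept = fit.slope, fit.intercept
    rng = np.random.default_rng(seed)
    amounts = profile.step_amounts()
    concs = tuple(a * mass / (0.1 * volume) for a in amounts)  # invert unit chain
    areas = tuple(slope * c + intercept for c in concs)
    noisy = tuple(a * (1.0 + (rng.normal(0.0, cv) if cv > 0 else 0.0))
                  for a in areas)
    records = tuple(
        ExtractionRecord(sample, analyte, i + 1, area=float(a))
        for i, a in enumerate(noisy)
    )
    series = ExtractionSeries(sample, analyte, records, volume, mass)
    return series, ExtractionTruth(profile, amounts, concs, areas)
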