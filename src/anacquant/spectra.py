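"""UV absorbance spectra and spectral similarity.

A diode-array detector records a full UV spectrum (here 200-400 nm) at every
time point of a chromatographic run.  Spectra are the basis of peak-purity
assessment: a peak containing a single compound shows the same (scaled)
spectrum at every point across the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "make_uv_spectrum", "cosine_similarity"]

UV_MIN_NM = 200.0
UV_MAX_NM = 400.0
#: wavelength window used for purity comparison (detector cutoff below 220 nm)
PURITY_WINDOW_NM = (220.0, 400.0)


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavelength grid.

    Values are on an arbitrary scale (similarity measures are scale free).
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Values resampled on ``grid`` by linear interpolation (0 outside)."""
        return np.interp(np.asarray(grid, dtype=float), self.wavelengths, self.values,
                         left=0.0, right=0.0)

    def restrict(self, lo: float, hi: float) -> "Spectrum":
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise ValueError(f"no wavelengths in [{lo}, {hi}]")
        return Spectrum(self.wavelengths[mask], self.values[mask])


def make_uv_spectrum(
    band_centers: "list[float]",
    band_widths: "list[float]",
    band_weights: "list[float]",
    grid: "np.ndarray | list[float] | None" = None,
) -> Spectrum:
    """Build a synthetic UV spectrum as a sum of Gaussian absorption bands.

    Parameters
    ----------
    band_centers, band_widths, band_weights
        Band positions (nm), Gaussian SDs (nm) and relative weights; equal
        length, at least one band.
    grid
        Wavelength grid in nm, strictly increasing, within 200-400 nm.
        Defaults to integers 200..400.

    Returns
    -------
    Spectrum
        Non-negative, scaled to unit maximum.
    """
    centers = np.asarray(band_centers, dtype=float)
    widths = np.asarray(band_widths, dtype=float)
    weights = np.asarray(band_weights, dtype=float)
    if centers.size == 0:
        raise ValueError("at least one band is required")
    if not (centers.size == widths.size == weights.size):
        raise ValueError("band lists must have equal length")
    if np.any(widths <= 0):
        raise ValueError("band widths must be positive")
    if grid is None:
        grid = np.arange(UV_MIN_NM, UV_MAX_NM + 1.0)
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < UV_MIN_NM or grid[-1] > UV_MAX_NM:
        raise ValueError(f"grid must lie within [{UV_MIN_NM}, {UV_MAX_NM}] nm")
    vals = np.zeros_like(grid)
    for c, w, a in zip(centers, widths, weights):
        vals += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    peak = vals.max()
    if peak > 0:
        vals = vals / peak
    return Spectrum(grid, vals)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two spectra given as aligned vectors.

    Returns 0.0 if either vector is all-zero (no meaningful direction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must be aligned on the same grid")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))
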