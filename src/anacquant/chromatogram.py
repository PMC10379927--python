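"""The raw DAD signal container: a time x wavelength absorbance matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Chromatogram"]


@dataclass
class Chromatogram:
    """A diode-array chromatogram.

    Attributes
    ----------
    times
        Acquisition times in minutes, strictly increasing.
    wavelengths
        Detector wavelengths in nm, strictly increasing.
    absorbance
        mAU matrix of shape ``(len(times), len(wavelengths))``.
    sample_id, injection_volume_ul, monitor_wavelength
        Acquisition metadata; quantification traces are taken at
        ``monitor_wavelength`` (280 nm by default).
    """

    times: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    injection_volume_ul: float = 20.0
    monitor_wavelength: float = 280.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.ndim != 1 or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if self.wavelengths.ndim != 1 or not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be 1-D and strictly increasing")
        if self.absorbance.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"({self.times.size}, {self.wavelengths.size})"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def sampling_rate(self) -> float:
        """Points per minute (median spacing)."""
        return 1.0 / float(np.median(np.diff(self.times)))

    def wavelength_index(self, wavelength: float) -> int:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return idx

    def trace(self, wavelength: "float | None" = None) -> np.ndarray:
        """Single-wavelength time series (nearest detector channel)."""
        wl = self.monitor_wavelength if wavelength is None else wavelength
        return self.absorbance[:, self.wavelength_index(wl)].copy()

    def time_index(self, time: float) -> int:
        """Index of the nearest time sample; rejects times outside the run."""
        if time < self.times[0] or time > self.times[-1]:
            raise ValueError(f"time {time} min outside run [{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - time)))
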