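"""Analyte definitions for the anacardic acid assay.

Anacardic acids (AnAc) are salicylic-acid-derived phenolic lipids with a C15
alkyl side chain; the 15:3 / 15:2 / 15:1 shorthand gives the number of C=C
unsaturations.  On a reverse-phase C18 column under isocratic elution the
more unsaturated (more polar) species elute first, so the order is
triene -> diene -> monoene.  The deprotonated-ion m/z values ([M-H]-) are
carried for reporting only; mass-spectrometric confirmation is outside this
package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, make_uv_spectrum

__all__ = ["AnalyteDef", "default_catalog"]


@dataclass(frozen=True)
class AnalyteDef:
    """One target analyte: identity, retention and reference UV spectrum."""

    name: str
    retention_time: float  # minutes
    molecular_weight: float  # g/mol
    expected_mz: float  # Da, [M-H]-, reporting only
    uv_profile: Spectrum

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError("retention_time must be positive")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        vals = self.uv_profile.values
        if np.any(vals < 0) or not np.any(vals > 0):
            raise ValueError("uv_profile must be non-negative with a positive value")


def _anac_spectrum(shift_nm: float = 0.0) -> Spectrum:
    # Salicylate-like chromophore: strong pi->pi* band near 245 nm and a
    # weaker band near 308 nm; small per-analyte shifts keep the three
    # spectra distinguishable but >95% similar, as for real homologues.
    return make_uv_spectrum(
        band_centers=[245.0 + shift_nm, 308.0 + shift_nm],
        band_widths=[16.0, 14.0],
        band_weights=[1.0, 0.35],
    )


def default_catalog() -> "list[AnalyteDef]":
    """The three anacardic acids monitored at 280 nm, in elution order."""
    return [
        AnalyteDef("AnAc 15:3", retention_time=11.0, molecular_weight=342.5,
                   expected_mz=341.2079, uv_profile=_anac_spectrum(0.0)),
        AnalyteDef("AnAc 15:2", retention_time=13.5, molecular_weight=344.5,
                   expected_mz=343.2228, uv_profile=_anac_spectrum(1.5)),
        AnalyteDef("AnAc 15:1", retention_time=17.0, molecular_weight=346.5,
                   expected_mz=345.2405, uv_profile=_anac_spectrum(3.0)),
    ]
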