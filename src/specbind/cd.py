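"""Circular dichroism: mean residue ellipticity and α-helix content.

Far-UV CD reports protein backbone conformation.  The raw machine signal
θ (mdeg) is normalised to mean residue ellipticity

    MRE = θ / (10 · C_p · n · l)        [deg cm² dmol⁻¹]

with C_p the molar protein concentration, n the residue count and l the
path length in cm.  The α-helix fraction is then estimated from the MRE at
208 nm by linear interpolation between the random-coil/β anchor
(−4000 deg cm² dmol⁻¹) and the pure-helix anchor (−33000 deg cm² dmol⁻¹):

    %α = 100 · (−MRE₂₀₈ − 4000) / (33000 − 4000)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import Spectrum, SpectrumKind

logger = logging.getLogger("specbind")

__all__ = [
    "MRE_COIL_208",
    "MRE_HELIX_208",
    "CDResult",
    "ellipticity_to_mre",
    "alpha_helix_percent",
    "analyze_cd",
    "compare_helix",
]

MRE_COIL_208 = 4000.0    # |MRE| of random coil / beta at 208 nm
MRE_HELIX_208 = 33000.0  # |MRE| of pure alpha-helix at 208 nm


@dataclass(frozen=True)
class CDResult:
    """MRE trace plus the 208-nm helix estimate for one CD spectrum."""

    mre: Spectrum
    mre_208: float
    alpha_helix_percent: float
    label: str = ""


def ellipticity_to_mre(theta_mdeg: float | np.ndarray, protein_conc_M: float,
                       n_residues: int, path_cm: float) -> float | np.ndarray:
    """Observed ellipticity (mdeg) → mean residue ellipticity (deg cm² dmol⁻¹)."""
    if protein_conc_M <= 0:
        raise ValueError("protein concentration must be > 0")
    if n_residues <= 0:
        raise ValueError("residue count must be > 0")
    if path_cm <= 0:
        raise ValueError("path length must be > 0")
    return theta_mdeg / (10.0 * protein_conc_M * n_residues * path_cm)


def alpha_helix_percent(mre_208: float) -> float:
    """α-helix percentage from the MRE at 208 nm, clipped to [0, 100]."""
    if not np.isfinite(mre_208):
        raise ValueError("MRE at 208 nm must be finite")
    pct = 100.0 * (-mre_208 - MRE_COIL_208) / (MRE_HELIX_208 - MRE_COIL_208)
    if pct < 0 or pct > 100:
        logger.warning("alpha-helix estimate %.2f%% outside [0, 100]; clipped", pct)
        pct = float(np.clip(pct, 0.0, 100.0))
    return pct


def analyze_cd(spectrum: Spectrum, protein_conc_M: float, n_residues: int,
               path_cm: float) -> CDResult:
    """Full CD analysis of one ellipticity spectrum (mdeg vs nm).

    Converts to MRE, interpolates the value at 208 nm on the wavelength
    grid, and returns the α-helix estimate.
    """
    if spectrum.kind is not SpectrumKind.ELLIPTICITY:
        raise ValueError("CD analysis requires an ellipticity spectrum")
    mre_values = ellipticity_to_mre(spectrum.values, protein_conc_M,
                                    n_residues, path_cm)
    mre = Spectrum(spectrum.wavelengths_nm, mre_values,
                   SpectrumKind.ELLIPTICITY, label=spectrum.label)
    mre_208 = mre.value_at(208.0)
    return CDResult(mre, mre_208, alpha_helix_percent(mre_208),
                    label=spectrum.label)


def compare_helix(native: CDResult, complexed: Sequence[CDResult]) -> list[dict]:
    """Per-complex table of α-helix content and its change versus native."""
    if not complexed:
        raise ValueError("need at least one complexed CD result")
    rows = []
    for c in complexed:
        rows.append({
            "label": c.label,
            "alpha_helix_percent": c.alpha_helix_percent,
            "delta_vs_native": c.alpha_helix_percent - native.alpha_helix_percent,
        })
    return rows
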