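"""Förster resonance energy transfer: overlap integral, R0, E and r.

The degree of spectral overlap between the donor emission F(λ) and the
acceptor molar absorptivity ε(λ) is

    J = ∫ F(λ) ε(λ) λ⁴ dλ / ∫ F(λ) dλ     [M⁻¹ cm³, λ in cm]

and sets the Förster critical distance through

    R0⁶ = 8.79 × 10⁻²⁵ · κ² · n⁻⁴ · φ · J   [cm⁶]

with κ² the dipole orientation factor, n the refractive index of the
medium and φ the donor quantum yield.  The transfer efficiency measured
from donor quenching, E = 1 − F/F0, then yields the donor–acceptor
distance r = R0 · ((1 − E)/E)^(1/6); E = 1/2 at r = R0 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

logger = logging.getLogger("specbind")

__all__ = [
    "FORSTER_PREFACTOR",
    "FretResult",
    "overlap_integral",
    "forster_radius",
    "fret_efficiency",
    "donor_acceptor_distance",
    "analyze_fret",
    "absorbance_to_molar_absorptivity",
]

#: Prefactor of the R0^6 relation when J is in M^-1 cm^3 and R0 in cm.
FORSTER_PREFACTOR = 8.79e-25

NM_PER_CM = 1e7


@dataclass(frozen=True)
class FretResult:
    """Self-consistent FRET triple (E, R0, r) plus the constants used."""

    J_M_cm3: float
    R0_nm: float
    E: float
    r_nm: float
    kappa2: float
    refractive_index: float
    quantum_yield: float


def overlap_integral(donor_emission: Spectrum,
                     acceptor_absorptivity: Spectrum) -> float:
    """Spectral overlap integral J in M⁻¹ cm³.

    The acceptor molar absorptivity (M⁻¹ cm⁻¹ vs nm) is linearly
    interpolated onto the donor wavelength grid restricted to the
    intersection of the two supports (no extrapolation of either
    spectrum), λ is converted to cm inside the λ⁴ weight, and both
    integrals are evaluated by the trapezoidal rule.
    """
    if np.any(acceptor_absorptivity.values < 0):
        raise ValueError("molar absorptivity must be >= 0 everywhere")
    d_wl = donor_emission.wavelengths_nm
    a_wl = acceptor_absorptivity.wavelengths_nm
    lo = max(d_wl[0], a_wl[0])
    hi = min(d_wl[-1], a_wl[-1])
    if lo >= hi:
        raise ValueError("disjoint wavelength ranges: donor and acceptor do not overlap")
    mask = (d_wl >= lo) & (d_wl <= hi)
    wl = d_wl[mask]
    if wl.size < 2:
        raise ValueError("overlap range contains fewer than 2 donor grid points")
    F = donor_emission.values[mask]
    eps = np.interp(wl, a_wl, acceptor_absorptivity.values)
    lam_cm = wl / NM_PER_CM
    # both integrals over lambda in cm: the d(lambda) measure cancels in
    # the ratio, leaving J in M^-1 cm^3 from epsilon * lambda^4
    denom = float(np.trapezoid(F, lam_cm))
    if denom <= 0:
        raise ValueError("donor intensity is zero on the overlap range")
    num = float(np.trapezoid(F * eps * lam_cm**4, lam_cm))
    J = num / denom
    logger.info("overlap integral J = %.6g M^-1 cm^3 over [%.1f, %.1f] nm", J, lo, hi)
    return J


def forster_radius(J_M_cm3: float, kappa2: float = 2.0 / 3.0,
                   refractive_index: float = 1.336,
                   quantum_yield: float = 0.118) -> float:
    """Förster critical distance R0 in nm from the overlap integral."""
    if J_M_cm3 <= 0:
        raise ValueError("overlap integral must be > 0")
    if kappa2 <= 0 or refractive_index <= 0 or quantum_yield <= 0:
        raise ValueError("kappa2, refractive index and quantum yield must be > 0")
    r0_6_cm6 = (FORSTER_PREFACTOR * kappa2 * refractive_index**-4
                * quantum_yield * J_M_cm3)
    r0_cm = r0_6_cm6 ** (1.0 / 6.0)
    return r0_cm * NM_PER_CM


def fret_efficiency(F0: float, F: float) -> float:
    """Energy-transfer efficiency E = 1 − F/F0 from donor quenching."""
    if F0 <= 0:
        raise ValueError("F0 must be > 0")
    if F < 0 or F > F0:
        raise ValueError("F must satisfy 0 <= F <= F0 (negative efficiency otherwise)")
    return 1.0 - F / F0


def donor_acceptor_distance(E: float, R0_nm: float) -> float:
    """Donor–acceptor distance r (nm) from efficiency and Förster radius.

    Inverts E = R0⁶/(R0⁶ + r⁶); undefined at E = 0 (infinite separation)
    and E = 1 (zero separation).
    """
    if not (0.0 < E < 1.0):
        raise ValueError("E must lie strictly between 0 and 1")
    if R0_nm <= 0:
        raise ValueError("R0 must be > 0")
    return R0_nm * ((1.0 - E) / E) ** (1.0 / 6.0)


def absorbance_to_molar_absorptivity(absorbance: Spectrum, conc_M: float,
                                     path_cm: float = 1.0) -> Spectrum:
    """Beer–Lambert conversion of an absorbance spectrum to ε(λ) in M⁻¹ cm⁻¹."""
    if conc_M <= 0 or path_cm <= 0:
        raise ValueError("concentration and path length must be > 0")
    return Spectrum(absorbance.wavelengths_nm,
                    absorbance.values / (conc_M * path_cm),
                    absorbance.kind, label=absorbance.label)


def analyze_fret(donor_emission: Spectrum, acceptor_absorptivity: Spectrum,
                 F0: float, F: float, kappa2: float = 2.0 / 3.0,
                 refractive_index: float = 1.336,
                 quantum_yield: float = 0.118) -> FretResult:
    """Full FRET chain: J → R0, E from intensities, r from (E, R0)."""
    J = overlap_integral(donor_emission, acceptor_absorptivity)
    R0 = forster_radius(J, kappa2, refractive_index, quantum_yield)
    E = fret_efficiency(F0, F)
    r = donor_acceptor_distance(E, R0)
    logger.info("FRET: J=%.4g, R0=%.4g nm, E=%.4f, r=%.4g nm", J, R0, E, r)
    return FretResult(J, R0, E, r, kappa2, refractive_index, quantum_yield)
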