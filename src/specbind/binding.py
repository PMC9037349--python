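"""Binding constants and thermodynamics from quenching titrations.

For static quenching by complex formation, the double-logarithmic
(modified Stern–Volmer) plot

    log10[(F0 − F)/F] = log10(K_a) + n · log10[Q]

is linear: its slope is the number of equivalent binding sites n and its
intercept the base-10 log of the association constant K_a (M⁻¹).

K_a measured at several temperatures feeds a van't Hoff analysis,

    ln K_a = −ΔH/(R T) + ΔS/R,

an OLS line of ln K_a on 1/T whose slope and intercept give the binding
enthalpy ΔH and entropy ΔS.  ΔG = ΔH − TΔS then follows at each
temperature, and the signs of ΔH and ΔS classify the dominant
intermolecular force (hydrophobic, electrostatic, or hydrogen-bond /
van der Waals).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .quenching import series_intensities
from .spectra import PipelineConfig, TitrationSeries

logger = logging.getLogger("specbind")

__all__ = [
    "BindingResult",
    "ThermoResult",
    "fit_modified_stern_volmer",
    "vant_hoff",
    "gibbs",
    "classify_force",
    "energy_to_affinity",
]

R_CAL = 1.987          # gas constant, cal mol^-1 K^-1
R_KCAL = 1.987e-3      # gas constant, kcal mol^-1 K^-1


@dataclass(frozen=True)
class BindingResult:
    """Association constant and site count at one temperature."""

    temperature_K: float
    Ka_per_M: float
    n_sites: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.Ka_per_M <= 0 or self.n_sites <= 0:
            raise ValueError("Ka and n must both be > 0 in a reported result")


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff thermodynamics over the fitted temperature range.

    ``dH_kcal_mol`` and ``dS_cal_mol_K`` follow calorimetric convention
    (kcal mol⁻¹ and cal mol⁻¹ K⁻¹); each ``per_T`` entry satisfies
    ΔG = ΔH − TΔS identically.
    """

    dH_kcal_mol: float
    dS_cal_mol_K: float
    fit_r_squared: float
    per_T: tuple[dict, ...]
    force_type: Literal["hydrophobic", "electrostatic", "hbond_vdw"]

    def __post_init__(self) -> None:
        for row in self.per_T:
            if row["dG_kcal_mol"] != self.dH_kcal_mol - row["TdS_kcal_mol"]:
                raise ValueError("per_T entry violates dG = dH - T*dS")


def fit_modified_stern_volmer(series: TitrationSeries,
                              config: PipelineConfig | None = None
                              ) -> BindingResult:
    """Fit K_a and n from the double-logarithmic quenching plot.

    Uses the same scalar intensities (fixed reference wavelength,
    inner-filter corrected where absorbances are present) as the
    Stern–Volmer stage.  Points with F ≥ F0 have no quenched fraction and
    are excluded with a warning; at least three usable points at distinct
    concentrations are required.
    """
    concs, F = series_intensities(series, config)
    F0 = F[0]
    mask = (concs > 0) & (F < F0)
    n_excluded = int(np.sum((concs > 0) & (F >= F0)))
    if n_excluded:
        logger.warning(
            "%d point(s) with F >= F0 excluded from modified Stern-Volmer fit",
            n_excluded,
        )
    x = np.log10(concs[mask])
    y = np.log10((F0 - F[mask]) / F[mask])
    if len(x) < 3:
        raise ValueError("need >= 3 nonzero points with F < F0 for the binding fit")
    if np.unique(x).size < 2:
        raise ValueError("all usable points at a single concentration")
    fit = stats.linregress(x, y)
    n_sites = float(fit.slope)
    Ka = float(10.0 ** fit.intercept)
    r2 = float(fit.rvalue**2)
    logger.info(
        "modified Stern-Volmer @ %.1f K: Ka=%.6g 1/M, n=%.4f, R2=%.6f",
        series.temperature_K, Ka, n_sites, r2,
    )
    return BindingResult(series.temperature_K, Ka, n_sites, r2)


def vant_hoff(binding: Sequence[BindingResult],
              R_cal: float = R_CAL) -> ThermoResult:
    """van't Hoff OLS of ln K_a on 1/T → ΔH, ΔS, and per-temperature ΔG.

    Requires K_a at three or more distinct temperatures.  ΔH = −slope·R
    (reported in kcal mol⁻¹), ΔS = intercept·R (cal mol⁻¹ K⁻¹); the fit is
    unweighted.  Each input temperature gets a ΔG = ΔH − TΔS entry and the
    dominant force is classified from the signs of ΔH and ΔS.
    """
    temps = [b.temperature_K for b in binding]
    if len(set(temps)) < 3:
        raise ValueError("van't Hoff analysis needs >= 3 distinct temperatures")
    ordered = sorted(binding, key=lambda b: b.temperature_K)
    T = np.array([b.temperature_K for b in ordered])
    lnK = np.log([b.Ka_per_M for b in ordered])
    if np.allclose(lnK, lnK[0]):
        slope, intercept, r2 = 0.0, float(lnK[0]), 1.0
    else:
        fit = stats.linregress(1.0 / T, lnK)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    dH_kcal = -slope * R_cal / 1000.0
    dS_cal = intercept * R_cal
    per_T = []
    for b in ordered:
        g = gibbs(dH_kcal, dS_cal, b.temperature_K)
        per_T.append({"temperature_K": b.temperature_K, **g})
    force = classify_force(dH_kcal, dS_cal)
    logger.info(
        "van't Hoff fit: dH=%.4g kcal/mol, dS=%.4g cal/(mol K), R2=%.6f, force=%s",
        dH_kcal, dS_cal, r2, force,
    )
    return ThermoResult(dH_kcal, dS_cal, r2, tuple(per_T), force)


def gibbs(dH_kcal_mol: float, dS_cal_mol_K: float,
          temperature_K: float) -> dict:
    """ΔG = ΔH − TΔS at one temperature, in kcal mol⁻¹."""
    if temperature_K <= 0:
        raise ValueError("temperature must be > 0 K")
    TdS = temperature_K * dS_cal_mol_K / 1000.0
    return {"TdS_kcal_mol": TdS, "dG_kcal_mol": dH_kcal_mol - TdS}


def classify_force(dH_kcal_mol: float, dS_cal_mol_K: float
                   ) -> Literal["hydrophobic", "electrostatic", "hbond_vdw"]:
    """Dominant interaction force from the signs of ΔH and ΔS.

    (+, +) hydrophobic; (−, +) electrostatic; (−, −) hydrogen bonding and
    van der Waals.  A zero is treated as positive (logged); the (+, −)
    combination has no assignment under this sign-rule scheme and raises.
    """
    if dH_kcal_mol == 0 or dS_cal_mol_K == 0:
        logger.warning("zero dH or dS treated as positive for force classification")
    h_pos = dH_kcal_mol >= 0
    s_pos = dS_cal_mol_K >= 0
    if h_pos and s_pos:
        return "hydrophobic"
    if (not h_pos) and s_pos:
        return "electrostatic"
    if (not h_pos) and (not s_pos):
        return "hbond_vdw"
    raise ValueError(
        "dH > 0 with dS < 0 is unclassified under the sign-rule scheme"
    )


def energy_to_affinity(dG_kcal_mol: float, temperature_K: float = 298.0,
                       R_kcal: float = R_KCAL) -> float:
    """Convert a (docking) binding energy to an affinity via ΔG = −RT ln K.

    Returns K = exp(−ΔG/(RT)); a more negative ΔG gives a larger affinity.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be > 0 K")
    return math.exp(-dG_kcal_mol / (R_kcal * temperature_K))
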