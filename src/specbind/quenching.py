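"""Fluorescence quenching analysis.

The observed drop in donor fluorescence as a quencher is titrated in is
quantified by the Stern–Volmer relation

    F0/F = 1 + K_SV [Q]

whose slope K_SV (M⁻¹), divided by the unquenched fluorophore lifetime τ0,
gives the bimolecular quenching rate constant k_q = K_SV/τ0.  A k_q far
above the diffusion-controlled collisional limit (~2×10¹⁰ M⁻¹ s⁻¹),
together with K_SV decreasing as temperature rises, indicates static
quenching: the quencher forms a non-fluorescent ground-state complex with
the protein rather than colliding with the excited state.

Measured intensities are first corrected for the inner-filter effect —
attenuation of the excitation and emission beams by sample absorbance —
via  F_c = F_obs · base^((A_ex + A_em)/2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .spectra import PipelineConfig, Spectrum, TitrationSeries

logger = logging.getLogger("specbind")

__all__ = [
    "QuenchingResult",
    "AnsResult",
    "DIFFUSION_LIMIT_KQ",
    "inner_filter_correct",
    "peak_intensity",
    "series_intensities",
    "fit_stern_volmer",
    "classify_quench_mode",
    "summarize_ans",
]

#: Maximum diffusion-limited (scatter collision) quenching rate constant,
#: M^-1 s^-1; k_q above this cannot be purely collisional.
DIFFUSION_LIMIT_KQ = 2e10


@dataclass(frozen=True)
class QuenchingResult:
    """Stern–Volmer fit for one temperature."""

    temperature_K: float
    Ksv_per_M: float
    intercept: float
    r_squared: float
    kq_per_M_s: float
    tau0_s: float
    mode: Literal["static", "dynamic", "inconclusive"] = "inconclusive"
    mode_evidence: str = ""
    flagged: bool = False


@dataclass(frozen=True)
class AnsResult:
    """Relative ANS fluorescence over a displacement titration."""

    concentrations_M: tuple[float, ...]
    relative_intensity: tuple[float, ...]
    saturation_conc_M: float | None


def inner_filter_correct(F_obs: float, a_ex: float, a_em: float,
                         base: str = "e") -> float:
    """Undo inner-filter attenuation of a measured fluorescence intensity.

    Returns ``F_obs * base**((a_ex + a_em) / 2)`` with ``base`` either
    Euler's e or 10 (two conventions in common use for the same correction).
    With both absorbances zero the intensity is returned unchanged.
    """
    if a_ex < 0 or a_em < 0:
        raise ValueError("absorbances must be >= 0")
    if base == "e":
        b = math.e
    elif base == "ten":
        b = 10.0
    else:
        raise ValueError(f"inner-filter base must be 'e' or 'ten', got {base!r}")
    return F_obs * b ** ((a_ex + a_em) / 2.0)


def peak_intensity(spectrum: Spectrum,
                   at_nm: float | None = None) -> float:
    """Scalar fluorescence reading from an emission spectrum.

    With ``at_nm`` given, the intensity is interpolated at that fixed
    wavelength (the convention for titrations: every point is read at the
    wavelength of the unquenched peak).  Without it, the global maximum is
    returned.
    """
    if at_nm is None:
        return float(np.max(spectrum.values))
    return spectrum.value_at(at_nm)


def series_intensities(series: TitrationSeries, config: PipelineConfig | None = None,
                       apply_inner_filter: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-point scalar intensities for a titration series.

    Quenching leaves the emission band shape unchanged, so each point's
    spectrum is (up to noise) a scalar multiple of the zero-concentration
    reference.  In the default ``band`` mode that scalar is estimated by
    least squares of the whole spectrum on the reference band, which
    averages instrument noise over the full wavelength grid; ``peak`` mode
    instead reads the single wavelength of the reference emission maximum.
    Both coincide exactly on noise-free data.  Inner-filter correction is
    applied wherever a point carries both absorbances.  Returns
    ``(concentrations_M, intensities)``.
    """
    config = config or PipelineConfig()
    ref = series.reference.spectrum
    ref_peak_nm = ref.peak_wavelength_nm
    ref_peak = peak_intensity(ref, at_nm=ref_peak_nm)
    ref_norm = float(np.dot(ref.values, ref.values))
    concs, F = [], []
    for p in series.points:
        if config.intensity_mode == "band" and ref_norm > 0:
            scale = float(np.dot(p.spectrum.values, ref.values)) / ref_norm
            f = scale * ref_peak
        else:
            f = peak_intensity(p.spectrum, at_nm=ref_peak_nm)
        if apply_inner_filter and p.has_absorbances:
            f = inner_filter_correct(f, p.a_ex, p.a_em, config.inner_filter_base)
        concs.append(p.quencher_conc_M)
        F.append(f)
    return np.array(concs), np.array(F)


def fit_stern_volmer(series: TitrationSeries,
                     config: PipelineConfig | None = None) -> QuenchingResult:
    """Ordinary least squares of F0/F against [Q]; slope is K_SV.

    The default fit leaves the intercept free (its deviation from 1 is a
    quality check for residual inner-filter or dilution artifacts);
    ``config.sv_intercept = "fixed"`` constrains the line through (0, 1).
    ``k_q = K_SV / tau0`` always.  A non-positive fitted slope is reported
    but flagged; the quenching mode is left "inconclusive" here because a
    single temperature cannot distinguish static from dynamic quenching.
    """
    config = config or PipelineConfig()
    concs, F = series_intensities(series, config)
    F0 = F[0]
    if F0 <= 0:
        raise ValueError("reference intensity F0 must be > 0")
    if np.any(F <= 0):
        raise ValueError("non-positive intensity in series; cannot form F0/F")
    y = F0 / F
    x = concs
    if np.allclose(F, F0):
        logger.warning("no quenching detected (constant F); Ksv = 0 flagged")
        return QuenchingResult(series.temperature_K, 0.0, 1.0, 1.0, 0.0,
                               config.tau0_s, "inconclusive",
                               "constant intensity: no quenching", flagged=True)
    if config.sv_intercept == "fixed":
        # regression through (0, 1): slope = sum(x(y-1))/sum(x^2)
        slope = float(np.sum(x * (y - 1.0)) / np.sum(x * x))
        intercept = 1.0
        resid = y - (1.0 + slope * x)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    flagged = slope <= 0
    if flagged:
        logger.warning("fitted Ksv = %.4g <= 0; result flagged", slope)
    kq = slope / config.tau0_s
    logger.info(
        "Stern-Volmer fit @ %.1f K: Ksv=%.6g 1/M, intercept=%.6g, R2=%.6f, kq=%.6g",
        series.temperature_K, slope, intercept, r2, kq,
    )
    return QuenchingResult(
        temperature_K=series.temperature_K,
        Ksv_per_M=slope,
        intercept=intercept,
        r_squared=r2,
        kq_per_M_s=kq,
        tau0_s=config.tau0_s,
        mode="inconclusive",
        mode_evidence="single-temperature fit: mode requires multi-T comparison",
        flagged=flagged,
    )


def classify_quench_mode(results: Sequence[QuenchingResult]
                         ) -> tuple[Literal["static", "dynamic", "inconclusive"], str]:
    """Static/dynamic verdict from per-temperature Stern–Volmer results.

    static  : every k_q exceeds the collisional limit (2×10¹⁰ M⁻¹ s⁻¹)
              and K_SV strictly decreases with temperature (ground-state
              complexes dissociate on heating);
    dynamic : every k_q is at or below the limit and K_SV strictly
              increases with temperature (faster diffusion on heating);
    inconclusive otherwise.  The temperature trend is only assessable with
    at least two temperatures.  The verdict is independent of the order in
    which results are supplied.
    """
    if not results:
        raise ValueError("need at least one quenching result")
    ordered = sorted(results, key=lambda r: r.temperature_K)
    kq = np.array([r.kq_per_M_s for r in ordered])
    ksv = np.array([r.Ksv_per_M for r in ordered])
    all_above = bool(np.all(kq > DIFFUSION_LIMIT_KQ))
    all_below = bool(np.all(kq <= DIFFUSION_LIMIT_KQ))
    have_trend = len(ordered) >= 2
    decreasing = have_trend and bool(np.all(np.diff(ksv) < 0))
    increasing = have_trend and bool(np.all(np.diff(ksv) > 0))
    kq_min, kq_max = kq.min(), kq.max()
    trend_txt = (
        "Ksv strictly decreasing with T" if decreasing
        else "Ksv strictly increasing with T" if increasing
        else "Ksv non-monotone in T" if have_trend
        else "single temperature: no Ksv trend available"
    )
    evidence = (
        f"kq in [{kq_min:.3g}, {kq_max:.3g}] 1/(M*s) vs collisional limit "
        f"{DIFFUSION_LIMIT_KQ:.1g}; {trend_txt}"
    )
    if all_above and (decreasing or not have_trend):
        return "static", evidence
    if all_below and (increasing or not have_trend):
        return "dynamic", evidence
    return "inconclusive", evidence


def summarize_ans(series: TitrationSeries, tolerance: float = 0.01) -> AnsResult:
    """Relative ANS fluorescence F/F0 per titration point and its saturation.

    ANS fluoresces strongly only when bound to hydrophobic protein surface;
    a ligand that buries or competes for those patches displaces ANS and
    the signal falls until it saturates.  Saturation is reported as the
    concentration closing the first titration step whose change
    |ΔF|/F0 falls below ``tolerance`` and stays below it for every later
    step; ``None`` if the signal never settles.
    """
    if len(series.points) < 3:
        raise ValueError("ANS summary needs >= 3 titration points")
    concs, F = series_intensities(series, apply_inner_filter=False)
    F0 = F[0]
    rel = F / F0
    saturation = None
    steps = np.abs(np.diff(F)) / F0
    for i in range(len(steps)):
        if np.all(steps[i:] < tolerance):
            saturation = float(concs[i + 1])
            break
    return AnsResult(
        concentrations_M=tuple(float(c) for c in concs),
        relative_intensity=tuple(float(v) for v in rel),
        saturation_conc_M=saturation,
    )
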