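"""Synthetic spectra and titrations with the structure the analysis assumes.

The generator emulates a tryptophan-fluorescence protein–ligand titration:
a Gaussian emission band centred near 335 nm recorded from 290–450 nm,
quenched point-by-point either by the static-binding isotherm

    F = F0 / (1 + K_a [Q]^n)

(under which the double-log binding plot is exactly linear) or by the
linear Stern–Volmer law F0/F = 1 + K_SV[Q].  When a (ΔH, ΔS) pair is
supplied, K_a(T) follows the van't Hoff relation exactly, so the
downstream thermodynamic fit has a known ground truth.  The companion
generators produce overlapping Gaussian donor/acceptor spectra for FRET
and two-minimum (208/222 nm) CD traces anchored so that the 208-nm mean
residue ellipticity encodes a chosen α-helix percentage.

Noise is multiplicative Gaussian with a chosen coefficient of variation,
mimicking shot-dominated photomultiplier statistics; a fixed seed makes
every generator bit-reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np

from .binding import R_CAL
from .cd import MRE_COIL_208, MRE_HELIX_208
from .spectra import Spectrum, SpectrumKind, TitrationPoint, TitrationSeries

logger = logging.getLogger("specbind")

__all__ = [
    "GeneratorSpec",
    "generate_titration",
    "generate_thermo_family",
    "generate_fret_pair",
    "generate_cd",
]

DEFAULT_CONCS_UM = (0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth parameters for synthetic data generation.

    Defaults mirror the study design the analysis targets: 5 μM protein
    excited at 280 nm, emission recorded 290–450 nm with a band at 335 nm,
    ligand titrated 0–15 μM at 298/303/308 K, static-binding quenching
    with K_a ≈ 4.28×10⁴ M⁻¹ and n ≈ 0.95 at the reference temperature.
    """

    seed: int = 0
    temperatures_K: tuple[float, ...] = (298.0, 303.0, 308.0)
    quencher_concs_M: tuple[float, ...] = tuple(c * 1e-6 for c in DEFAULT_CONCS_UM)
    quench_model: str = "static_binding"  # or "linear_sv"
    Ka_ref_per_M: float = 4.28e4
    n_sites: float = 0.9538
    Ksv_per_M: float = 7.16e4
    # optional van't Hoff ground truth generating Ka(T); (dH kcal/mol, dS cal/mol/K)
    dH_kcal_mol: float | None = None
    dS_cal_mol_K: float | None = None
    emission_center_nm: float = 335.0
    emission_width_nm: float = 25.0
    emission_amplitude: float = 1000.0
    emission_grid_nm: tuple[float, float, float] = (290.0, 450.0, 1.0)
    acceptor_center_nm: float = 370.0
    acceptor_width_nm: float = 40.0
    # peak epsilon calibrated so the default donor/acceptor pair yields an
    # overlap integral J ~ 1.2e-14 M^-1 cm^3 (R0 ~ 2.5 nm)
    acceptor_peak_absorptivity: float = 1.245e4
    # inner-filter ramp: absorbance added per molar quencher at ex/em wavelengths
    inner_filter_a_per_M: float | None = None
    inner_filter_base: str = "e"
    alpha_helix_percent: float = 32.04
    protein_conc_M: float = 5e-6
    n_residues: int = 689
    path_length_cm: float = 0.1
    excitation_nm: float = 280.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if 0.0 not in self.quencher_concs_M:
            raise ValueError("quencher concentrations must include 0 (the F0 point)")
        if not (0.0 <= self.alpha_helix_percent <= 100.0):
            raise ValueError("alpha_helix_percent must lie in [0, 100]")
        if self.quench_model not in ("static_binding", "linear_sv"):
            raise ValueError(f"unknown quench model {self.quench_model!r}")

    def wavelength_grid(self) -> np.ndarray:
        lo, hi, step = self.emission_grid_nm
        return np.arange(lo, hi + step / 2, step)

    def ka_at(self, temperature_K: float) -> float:
        """K_a at a temperature: van't Hoff when (ΔH, ΔS) are set, else K_a_ref."""
        if self.dH_kcal_mol is None or self.dS_cal_mol_K is None:
            return self.Ka_ref_per_M
        dH_cal = self.dH_kcal_mol * 1000.0
        lnK = -dH_cal / (R_CAL * temperature_K) + self.dS_cal_mol_K / R_CAL
        return float(np.exp(lnK))


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _rng_for(spec: GeneratorSpec, stream: str) -> np.random.Generator:
    # one independent stream per generated object, all derived from spec.seed;
    # crc32 keyed by the stream name is stable across processes
    ss = np.random.SeedSequence([spec.seed, zlib.crc32(stream.encode())])
    return np.random.default_rng(ss)


def generate_titration(spec: GeneratorSpec, temperature_K: float) -> TitrationSeries:
    """One synthetic titration series at ``temperature_K``.

    The emission band is scaled per point by the chosen quench model.
    When an inner-filter ramp is enabled, the emitted ("measured")
    intensities are attenuated by base^(−(A_ex+A_em)/2) and the
    absorbances stored on each point, so the analysis-side correction must
    undo the attenuation to recover the model parameters.
    """
    if temperature_K not in spec.temperatures_K:
        raise ValueError(f"{temperature_K} K not among spec.temperatures_K")
    wl = spec.wavelength_grid()
    band = spec.emission_amplitude * _gaussian(wl, spec.emission_center_nm,
                                               spec.emission_width_nm)
    rng = _rng_for(spec, f"titration@{temperature_K}")
    base = np.e if spec.inner_filter_base == "e" else 10.0
    points = []
    for q in sorted(spec.quencher_concs_M):
        if spec.quench_model == "static_binding":
            ka = spec.ka_at(temperature_K)
            scale = 1.0 / (1.0 + ka * q**spec.n_sites) if q > 0 else 1.0
        else:  # linear_sv
            scale = 1.0 / (1.0 + spec.Ksv_per_M * q)
        values = band * scale
        a_ex = a_em = None
        if spec.inner_filter_a_per_M is not None:
            a_ex = spec.inner_filter_a_per_M * q
            a_em = 0.5 * spec.inner_filter_a_per_M * q
            values = values * base ** (-(a_ex + a_em) / 2.0)
        if spec.noise_cv > 0:
            values = values * (1.0 + spec.noise_cv * rng.standard_normal(values.size))
            values = np.clip(values, 0.0, None)
        points.append(TitrationPoint(
            quencher_conc_M=q,
            spectrum=Spectrum(wl, values, SpectrumKind.EMISSION,
                              label=f"[Q]={q * 1e6:g}uM@{temperature_K:g}K"),
            a_ex=a_ex, a_em=a_em,
        ))
    return TitrationSeries(points=tuple(points), temperature_K=temperature_K,
                           excitation_nm=spec.excitation_nm,
                           protein_conc_M=spec.protein_conc_M,
                           label=f"synthetic@{temperature_K:g}K")


def generate_thermo_family(spec: GeneratorSpec) -> list[TitrationSeries]:
    """One series per temperature with K_a(T) on an exact van't Hoff line."""
    if spec.dH_kcal_mol is None or spec.dS_cal_mol_K is None:
        raise ValueError("thermo generation requires dH_kcal_mol and dS_cal_mol_K")
    if len(set(spec.temperatures_K)) < 3:
        raise ValueError("thermo generation needs >= 3 distinct temperatures")
    return [generate_titration(spec, T) for T in spec.temperatures_K]


def generate_fret_pair(spec: GeneratorSpec, rectangular: bool = False,
                       disjoint: bool = False,
                       n_points: int = 2001) -> dict[str, Spectrum]:
    """Donor emission and acceptor molar-absorptivity spectra.

    Gaussian bands on the shared emission grid by default;
    ``rectangular=True`` produces flat donor (unit) and acceptor (peak ε)
    bands on [400, 500] nm, for which the overlap integral has the closed
    form ε·(b⁵−a⁵)/(5(b−a)) against which the numerical integrator can be
    checked.  ``disjoint=True`` places the acceptor on a wavelength range
    beyond the donor's, a degenerate pair with no spectral overlap.
    """
    if disjoint:
        wl = spec.wavelength_grid()
        donor = Spectrum(wl, spec.emission_amplitude
                         * _gaussian(wl, spec.emission_center_nm,
                                     spec.emission_width_nm),
                         SpectrumKind.EMISSION, label="synthetic donor emission")
        a_wl = wl + (wl[-1] - wl[0]) + 10.0
        acceptor = Spectrum(a_wl, spec.acceptor_peak_absorptivity
                            * _gaussian(a_wl, a_wl.mean(), spec.acceptor_width_nm),
                            SpectrumKind.ABSORBANCE, label="disjoint acceptor")
        return {"donor": donor, "acceptor": acceptor}
    if rectangular:
        wl = np.linspace(400.0, 500.0, n_points)
        donor = Spectrum(wl, np.ones_like(wl), SpectrumKind.EMISSION,
                         label="rect donor")
        acceptor = Spectrum(wl, np.full_like(wl, spec.acceptor_peak_absorptivity),
                            SpectrumKind.ABSORBANCE, label="rect acceptor")
        return {"donor": donor, "acceptor": acceptor}
    wl = spec.wavelength_grid()
    donor = Spectrum(wl, spec.emission_amplitude
                     * _gaussian(wl, spec.emission_center_nm, spec.emission_width_nm),
                     SpectrumKind.EMISSION, label="synthetic donor emission")
    acceptor = Spectrum(wl, spec.acceptor_peak_absorptivity
                        * _gaussian(wl, spec.acceptor_center_nm, spec.acceptor_width_nm),
                        SpectrumKind.ABSORBANCE, label="synthetic acceptor absorptivity")
    return {"donor": donor, "acceptor": acceptor}


def generate_cd(spec: GeneratorSpec) -> Spectrum:
    """Synthetic far-UV CD trace (mdeg) encoding a target α-helix fraction.

    Two negative Gaussian bands at 208 and 222 nm are scaled so that the
    linearly interpolated mean residue ellipticity at 208 nm equals the
    inversion of the helix estimator at the target percentage, then
    converted back to machine units (mdeg) with the spec's concentration,
    residue count and path length.
    """
    wl = np.arange(200.0, 250.0 + 0.5, 0.5)
    shape = -(_gaussian(wl, 208.0, 6.0) + 0.9 * _gaussian(wl, 222.0, 7.0))
    target_mre_208 = -(MRE_COIL_208 + spec.alpha_helix_percent / 100.0
                       * (MRE_HELIX_208 - MRE_COIL_208))
    shape_at_208 = float(np.interp(208.0, wl, shape))
    mre = shape * (target_mre_208 / shape_at_208)
    theta_mdeg = mre * 10.0 * spec.protein_conc_M * spec.n_residues * spec.path_length_cm
    if spec.noise_cv > 0:
        rng = _rng_for(spec, "cd")
        theta_mdeg = theta_mdeg * (1.0 + spec.noise_cv
                                   * rng.standard_normal(theta_mdeg.size))
    return Spectrum(wl, theta_mdeg, SpectrumKind.ELLIPTICITY,
                    label=f"synthetic CD {spec.alpha_helix_percent:g}% helix")
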