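"""Core containers for spectral and titration data.

A :class:`Spectrum` is a single wavelength-indexed trace — fluorescence
emission (arbitrary units), absorbance (dimensionless), molar absorptivity
(M⁻¹ cm⁻¹) or CD ellipticity (mdeg).  A :class:`TitrationSeries` collects
the emission spectra recorded while a quencher/ligand is titrated into a
protein solution at one temperature; it is the input to every fluorescence
fit in the package.

All wavelengths are stored in nanometres and all concentrations in mol L⁻¹.
Unit conversions (e.g. nm → cm inside the FRET overlap integral) happen
only inside the computation that needs them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

logger = logging.getLogger("specbind")

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "TitrationPoint",
    "TitrationSeries",
    "PipelineConfig",
]


class SpectrumKind(str, Enum):
    EMISSION = "emission"
    ABSORBANCE = "absorbance"
    ELLIPTICITY = "ellipticity"


@dataclass(frozen=True)
class Spectrum:
    """One wavelength-indexed trace.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nm, at least two points.
    values
        Trace values, same length as ``wavelengths_nm``.  Emission
        intensities must be non-negative; absorbance and ellipticity may
        take any sign (baseline noise can dip below zero).
    kind
        One of ``emission``, ``absorbance``, ``ellipticity``.
    label
        Free-text identifier used in logs and reports.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = SpectrumKind.EMISSION
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectrum needs at least 2 wavelength points")
        if vals.shape != wl.shape:
            raise ValueError(
                f"values length {vals.size} != wavelengths length {wl.size}"
            )
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("non-finite entries in spectrum")
        d = np.diff(wl)
        if np.any(d == 0):
            dup = wl[:-1][d == 0][0]
            raise ValueError(f"duplicate wavelength {dup:g} nm")
        if np.any(d < 0):
            raise ValueError("wavelengths must be strictly increasing")
        kind = SpectrumKind(self.kind)
        if kind is SpectrumKind.EMISSION and np.any(vals < 0):
            raise ValueError("emission intensities must be >= 0")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", kind)

    # -- convenience -------------------------------------------------------
    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at ``wavelength_nm`` (no extrapolation)."""
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"{wavelength_nm:g} nm outside spectrum range "
                f"[{wl[0]:g}, {wl[-1]:g}] nm"
            )
        return float(np.interp(wavelength_nm, wl, self.values))

    @property
    def peak_wavelength_nm(self) -> float:
        """Wavelength of the global maximum value."""
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths_nm.shape == other.wavelengths_nm.shape
            and bool(np.array_equal(self.wavelengths_nm, other.wavelengths_nm))
        )


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: quencher concentration plus the emission spectrum.

    ``a_ex``/``a_em`` are the optional sample absorbances at the excitation
    and emission wavelengths, used for inner-filter correction.
    """

    quencher_conc_M: float
    spectrum: Spectrum
    a_ex: float | None = None
    a_em: float | None = None

    def __post_init__(self) -> None:
        if self.quencher_conc_M < 0:
            raise ValueError("quencher concentration must be >= 0")
        for name in ("a_ex", "a_em"):
            a = getattr(self, name)
            if a is not None and a < 0:
                raise ValueError(f"{name} must be >= 0, got {a:g}")
        if self.spectrum.kind is not SpectrumKind.EMISSION:
            raise ValueError("titration point spectrum must be an emission spectrum")

    @property
    def has_absorbances(self) -> bool:
        return self.a_ex is not None and self.a_em is not None


@dataclass(frozen=True)
class TitrationSeries:
    """Emission spectra over quencher concentrations at one temperature.

    Invariants: points sorted ascending by concentration with exactly one
    zero-concentration reference (the unquenched F₀ spectrum), at least
    three distinct concentrations, and a single shared wavelength grid.
    """

    points: tuple[TitrationPoint, ...]
    temperature_K: float
    excitation_nm: float
    protein_conc_M: float
    label: str = ""

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.quencher_conc_M))
        if self.temperature_K <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.protein_conc_M <= 0:
            raise ValueError("protein concentration must be > 0")
        concs = [p.quencher_conc_M for p in pts]
        if len(set(concs)) < 3:
            raise ValueError("titration needs >= 3 points with distinct concentrations")
        n_zero = sum(1 for c in concs if c == 0)
        if n_zero != 1:
            raise ValueError(
                f"exactly one zero-concentration reference point required, got {n_zero}"
            )
        ref = pts[0].spectrum
        for p in pts[1:]:
            if not ref.same_grid(p.spectrum):
                raise ValueError(
                    "all spectra in a series must share one wavelength grid; "
                    f"grid of {p.spectrum.label or p.quencher_conc_M} differs"
                )
        object.__setattr__(self, "points", pts)

    @property
    def reference(self) -> TitrationPoint:
        """The zero-concentration (F₀) point."""
        return self.points[0]

    @property
    def concentrations_M(self) -> np.ndarray:
        return np.array([p.quencher_conc_M for p in self.points])


@dataclass(frozen=True)
class PipelineConfig:
    """Physical constants and numerical conventions for one pipeline run.

    Defaults reflect a tryptophan-fluorescence protein–ligand study:
    lifetime ``tau0_s`` of the unquenched donor, Förster orientation factor
    ``kappa2`` = 2/3 (isotropic dynamic averaging), aqueous-buffer
    refractive index, and a donor quantum yield of 0.118.
    """

    tau0_s: float = 5.78e-9
    R_cal: float = 1.987  # gas constant, cal mol^-1 K^-1
    kappa2: float = 2.0 / 3.0
    refractive_index: float = 1.336
    quantum_yield: float = 0.118
    n_residues: int = 689
    path_length_cm: float = 0.1
    inner_filter_base: str = "e"  # {"e", "ten"}
    sv_intercept: str = "free"  # {"free", "fixed"}
    # scalar-intensity reading: "band" regresses each spectrum on the
    # reference band shape (averages wavelength noise), "peak" reads the
    # single fixed wavelength of the unquenched emission maximum
    intensity_mode: str = "band"

    def __post_init__(self) -> None:
        for name in ("tau0_s", "R_cal", "refractive_index", "quantum_yield",
                     "path_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.kappa2 <= 4):
            raise ValueError("kappa2 must lie in (0, 4]")
        if self.n_residues <= 0:
            raise ValueError("n_residues must be > 0")
        if self.inner_filter_base not in ("e", "ten"):
            raise ValueError("inner_filter_base must be 'e' or 'ten'")
        if self.sv_intercept not in ("free", "fixed"):
            raise ValueError("sv_intercept must be 'free' or 'fixed'")
        if self.intensity_mode not in ("band", "peak"):
            raise ValueError("intensity_mode must be 'band' or 'peak'")
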