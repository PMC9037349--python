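"""Shared fixtures: small hand-built series and derandomised hypothesis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from specbind import Spectrum, SpectrumKind, TitrationPoint, TitrationSeries

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_emission(intensity: float, peak_nm: float = 335.0) -> Spectrum:
    """Minimal 3-point emission spectrum peaking at ``peak_nm``."""
    wl = np.array([290.0, peak_nm, 450.0])
    return Spectrum(wl, np.array([0.1 * intensity, intensity, 0.1 * intensity]),
                    SpectrumKind.EMISSION)


def series_from_intensities(concs_M, intensities, temperature_K=298.0,
                            absorbances=None) -> TitrationSeries:
    """Series whose fixed-wavelength readings equal ``intensities`` exactly."""
    points = []
    for i, (c, f) in enumerate(zip(concs_M, intensities)):
        a_ex = a_em = None
        if absorbances is not None:
            a_ex, a_em = absorbances[i]
        points.append(TitrationPoint(c, make_emission(f), a_ex=a_ex, a_em=a_em))
    return TitrationSeries(points=tuple(points), temperature_K=temperature_K,
                           excitation_nm=280.0, protein_conc_M=5e-6)


@pytest.fixture
def sv_series():
    """Noise-free linear Stern-Volmer series: F0/F = 1 + 7.16e4 [Q]."""
    ksv = 7.16e4
    concs = np.array([0.0, 2.5e-6, 5e-6, 7.5e-6, 1e-5, 1.25e-5, 1.5e-5])
    F = 1000.0 / (1.0 + ksv * concs)
    return series_from_intensities(concs, F), ksv


@pytest.fixture
def binding_series():
    """Noise-free static-binding series: F = F0/(1 + Ka [Q]^n)."""
    ka, n = 4.28e4, 0.9538
    concs = np.array([0.0, 2.5e-6, 5e-6, 7.5e-6, 1e-5, 1.25e-5, 1.5e-5])
    F = 1000.0 / (1.0 + ka * concs**n)
    return series_from_intensities(concs, F), ka, n
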