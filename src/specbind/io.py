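"""Reading and writing spectra and titration manifests.

Spectrum files are two-column delimited text (``wavelength_nm,value``),
comma- or tab-separated with an optional header line.  A titration series
is described by a YAML manifest::

    temperature_K: 298
    excitation_nm: 280
    protein_conc_M: 5e-6
    conc_unit: uM          # optional; M (default) or uM
    points:
      - {conc: 0, file: q00.csv}
      - {conc: 5, file: q05.csv, a_ex: 0.02, a_em: 0.01}

Spectrum file paths are resolved relative to the manifest location.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import Spectrum, SpectrumKind, TitrationPoint, TitrationSeries

logger = logging.getLogger("specbind")

__all__ = ["read_spectrum", "write_spectrum", "read_titration", "write_titration"]

# divisors: dividing by an exactly-representable power of ten keeps round
# numbers like 5 uM == 5e-6 M bit-exact
_CONC_DIVISORS = {"M": 1.0, "mM": 1e3, "uM": 1e6, "µM": 1e6, "nM": 1e9}


def read_spectrum(path: str | Path, kind: str | SpectrumKind = SpectrumKind.EMISSION,
                  label: str | None = None) -> Spectrum:
    """Read a two-column (wavelength, value) text file into a :class:`Spectrum`.

    The delimiter (comma or tab/whitespace) is auto-detected and a single
    non-numeric header line is skipped.  Rows arriving out of wavelength
    order are sorted with a logged warning; duplicated wavelengths are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         header=None, skip_blank_lines=True, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error paths vary
        raise ValueError(f"cannot parse spectrum file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, value)")

    def _to_float(cell: str) -> float:
        # Python's float() is correctly rounded, so repr-written values
        # round-trip bit-exactly (pandas' numeric parser can be 1 ulp off)
        try:
            return float(cell)
        except (TypeError, ValueError):
            return float("nan")

    num = df.iloc[:, :2].map(_to_float)
    # drop a header row if the first row is non-numeric
    if num.iloc[0].isna().any():
        df, num = df.iloc[1:], num.iloc[1:]
    bad = num.isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"{path}: non-numeric rows at lines {list(num.index[bad])}"
        )
    wl = num.iloc[:, 0].to_numpy(float)
    vals = num.iloc[:, 1].to_numpy(float)
    if wl.size < 2:
        raise ValueError(f"{path}: fewer than 2 usable rows")
    if np.any(np.diff(wl) < 0):
        logger.warning("%s: wavelengths not monotone; sorting", path)
        order = np.argsort(wl, kind="stable")
        wl, vals = wl[order], vals[order]
    return Spectrum(wl, vals, SpectrumKind(kind), label or path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as ``wavelength_nm,value`` CSV with full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("wavelength_nm,value\n")
        for w, v in zip(spectrum.wavelengths_nm, spectrum.values):
            fh.write(f"{float(w)!r},{float(v)!r}\n")
    return path


def read_titration(path: str | Path) -> TitrationSeries:
    """Read a YAML titration manifest (see module docstring) into a series."""
    path = Path(path)
    if path.is_dir():
        candidates = sorted(path.glob("*.y*ml"))
        if not candidates:
            raise FileNotFoundError(f"no manifest (*.yaml) found in {path}")
        path = candidates[0]
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: manifest must be a mapping")
    for key in ("temperature_K", "excitation_nm", "protein_conc_M", "points"):
        if key not in doc:
            raise ValueError(f"{path}: manifest missing required key '{key}'")
    unit = str(doc.get("conc_unit", "M"))
    if unit not in _CONC_DIVISORS:
        raise ValueError(f"{path}: unknown conc_unit '{unit}'")
    divisor = _CONC_DIVISORS[unit]
    base = path.parent
    points = []
    for entry in doc["points"]:
        spec_path = base / str(entry["file"])
        spectrum = read_spectrum(spec_path, SpectrumKind.EMISSION)
        points.append(
            TitrationPoint(
                quencher_conc_M=float(entry["conc"]) / divisor,
                spectrum=spectrum,
                a_ex=None if entry.get("a_ex") is None else float(entry["a_ex"]),
                a_em=None if entry.get("a_em") is None else float(entry["a_em"]),
            )
        )
    # name the offending file in the shared-grid check before the series
    # constructor re-raises a generic message
    ref = min(points, key=lambda p: p.quencher_conc_M)
    for p, entry in zip(points, doc["points"]):
        if not ref.spectrum.same_grid(p.spectrum):
            raise ValueError(
                f"{path}: wavelength grid of '{entry['file']}' differs from "
                "the zero-concentration reference"
            )
    return TitrationSeries(
        points=tuple(points),
        temperature_K=float(doc["temperature_K"]),
        excitation_nm=float(doc["excitation_nm"]),
        protein_conc_M=float(doc["protein_conc_M"]),
        label=str(doc.get("label", path.stem)),
    )


def write_titration(series: TitrationSeries, directory: str | Path,
                    name: str = "series") -> Path:
    """Write a series as per-point spectrum CSVs plus a YAML manifest.

    Returns the manifest path; ``read_titration`` on it round-trips the
    series to full float precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, p in enumerate(series.points):
        fname = f"{name}_point{i:02d}.csv"
        write_spectrum(p.spectrum, directory / fname)
        entry: dict = {"conc": float(p.quencher_conc_M), "file": fname}
        if p.a_ex is not None:
            entry["a_ex"] = float(p.a_ex)
        if p.a_em is not None:
            entry["a_em"] = float(p.a_em)
        entries.append(entry)
    manifest = {
        "label": series.label or name,
        "temperature_K": float(series.temperature_K),
        "excitation_nm": float(series.excitation_nm),
        "protein_conc_M": float(series.protein_conc_M),
        "conc_unit": "M",
        "points": entries,
    }
    manifest_path = directory / f"{name}.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
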