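"""Pipeline orchestration: quenching → binding → thermodynamics → CD → FRET.

``run_pipeline`` executes every analysis stage whose preconditions are
met, collects the fitted coefficients with their goodness-of-fit, and
returns a report whose tables mirror the usual summary layout of a
spectroscopic binding study: per-temperature quenching/binding constants,
van't Hoff thermodynamics, and the FRET parameter set.  Stages with unmet
preconditions (e.g. fewer than three temperatures for van't Hoff) are
recorded as skipped with the reason, never dropped silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import binding as _binding
from . import cd as _cd
from . import fret as _fret
from . import quenching as _quenching
from .spectra import PipelineConfig, Spectrum, TitrationSeries

logger = logging.getLogger("specbind")

__all__ = ["PipelineReport", "run_pipeline", "write_report"]


@dataclass
class PipelineReport:
    """Collected results of one pipeline run."""

    table_quenching: pd.DataFrame | None = None
    table_thermo: pd.DataFrame | None = None
    table_fret: pd.DataFrame | None = None
    table_cd: pd.DataFrame | None = None
    quench_mode: str | None = None
    quench_evidence: str | None = None
    skipped: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"skipped": self.skipped,
                     "quench_mode": self.quench_mode,
                     "quench_evidence": self.quench_evidence}
        for name in ("table_quenching", "table_thermo", "table_fret", "table_cd"):
            df = getattr(self, name)
            out[name] = None if df is None else df.to_dict(orient="records")
        return out


def run_pipeline(config: PipelineConfig,
                 series_by_temperature: Sequence[TitrationSeries],
                 donor_emission: Spectrum | None = None,
                 acceptor_absorptivity: Spectrum | None = None,
                 cd_spectra: Sequence[Spectrum] | None = None,
                 fret_point_index: int | None = None) -> PipelineReport:
    """Run every applicable stage over the supplied data.

    Parameters
    ----------
    config
        Physical constants and fit conventions.
    series_by_temperature
        One titration series per temperature (at least one).
    donor_emission, acceptor_absorptivity
        Spectra for the FRET stage; the acceptor trace must already be in
        molar absorptivity units (M⁻¹ cm⁻¹).  Stage skipped when absent.
    cd_spectra
        Ellipticity spectra (mdeg); the first is taken as the native
        protein, later ones as ligand complexes.  Stage skipped when absent.
    fret_point_index
        Index of the titration point whose intensity serves as the
        acceptor-present donor intensity F.  Default: the point whose
        ligand concentration is closest to the protein concentration
        (equimolar).
    """
    if not series_by_temperature:
        raise ValueError("pipeline needs at least one titration series")
    report = PipelineReport()

    # -- quenching + binding per temperature -------------------------------
    qrows, quench_results, binding_results = [], [], []
    for series in sorted(series_by_temperature, key=lambda s: s.temperature_K):
        try:
            q = _quenching.fit_stern_volmer(series, config)
            quench_results.append(q)
        except Exception as exc:
            raise RuntimeError(f"quenching stage failed at "
                               f"{series.temperature_K} K: {exc}") from exc
        row = {"temperature_K": series.temperature_K,
               "Ksv_per_M": q.Ksv_per_M, "sv_intercept": q.intercept,
               "sv_r_squared": q.r_squared, "kq_per_M_s": q.kq_per_M_s}
        try:
            b = _binding.fit_modified_stern_volmer(series, config)
            binding_results.append(b)
            row.update({"Ka_per_M": b.Ka_per_M, "n_sites": b.n_sites,
                        "binding_r_squared": b.r_squared})
        except Exception as exc:
            raise RuntimeError(f"binding stage failed at "
                               f"{series.temperature_K} K: {exc}") from exc
        qrows.append(row)
    report.table_quenching = pd.DataFrame(qrows)
    mode, evidence = _quenching.classify_quench_mode(quench_results)
    report.quench_mode, report.quench_evidence = mode, evidence

    # -- van't Hoff thermodynamics ----------------------------------------
    temps = {s.temperature_K for s in series_by_temperature}
    if len(temps) >= 3:
        thermo = _binding.vant_hoff(binding_results, config.R_cal)
        trows = [{"temperature_K": row["temperature_K"],
                  "dH_kcal_mol": thermo.dH_kcal_mol,
                  "dS_cal_mol_K": thermo.dS_cal_mol_K,
                  "TdS_kcal_mol": row["TdS_kcal_mol"],
                  "dG_kcal_mol": row["dG_kcal_mol"],
                  "force_type": thermo.force_type}
                 for row in thermo.per_T]
        report.table_thermo = pd.DataFrame(trows)
    else:
        report.skipped["thermodynamics"] = (
            f"skipped: needs >=3 temperatures, got {len(temps)}"
        )
        logger.warning(report.skipped["thermodynamics"])

    # -- CD ----------------------------------------------------------------
    if cd_spectra:
        results = [_cd.analyze_cd(s, series_by_temperature[0].protein_conc_M,
                                  config.n_residues, config.path_length_cm)
                   for s in cd_spectra]
        rows = [{"label": r.label or f"spectrum_{i}",
                 "mre_208": r.mre_208,
                 "alpha_helix_percent": r.alpha_helix_percent,
                 "delta_vs_native": r.alpha_helix_percent
                 - results[0].alpha_helix_percent}
                for i, r in enumerate(results)]
        report.table_cd = pd.DataFrame(rows)
    else:
        report.skipped["cd"] = "skipped: no CD spectra supplied"

    # -- FRET ---------------------------------------------------------------
    if donor_emission is not None and acceptor_absorptivity is not None:
        series = min(series_by_temperature, key=lambda s: s.temperature_K)
        concs, F = _quenching.series_intensities(series, config)
        if fret_point_index is None:
            # default acceptor-present point: ligand ~ equimolar with protein
            nonzero = [i for i, c in enumerate(concs) if c > 0]
            fret_point_index = min(
                nonzero, key=lambda i: abs(concs[i] - series.protein_conc_M))
        try:
            fr = _fret.analyze_fret(donor_emission, acceptor_absorptivity,
                                    F0=F[0], F=F[fret_point_index],
                                    kappa2=config.kappa2,
                                    refractive_index=config.refractive_index,
                                    quantum_yield=config.quantum_yield)
        except Exception as exc:
            raise RuntimeError(f"FRET stage failed: {exc}") from exc
        report.table_fret = pd.DataFrame([{
            "J_M_cm3": fr.J_M_cm3, "R0_nm": fr.R0_nm,
            "r_nm": fr.r_nm, "E_percent": 100.0 * fr.E,
        }])
    else:
        report.skipped["fret"] = "skipped: donor/acceptor spectra not supplied"

    return report


def write_report(report: PipelineReport, out_dir: str | Path) -> Path:
    """Write report tables as CSV plus a JSON summary; returns the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("table_quenching", "table_thermo", "table_fret", "table_cd"):
        df = getattr(report, name)
        if df is not None:
            df.to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=float))
    return out_dir
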