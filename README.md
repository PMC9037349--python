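# specbind

Spectroscopic protein–ligand binding analysis in Python: fluorescence
quenching, binding constants and thermodynamics, circular-dichroism
secondary structure, and FRET distance determination — with a
synthetic-data generator so every stage is testable end to end without
instrument data.

The package targets the standard steady-state workflow for characterising
how a small molecule binds a fluorescent protein (the built-in defaults
describe a tryptophan-emitting ~80 kDa milk protein, lactoferrin, titrated
with a tea polyphenol):

- **Stern–Volmer quenching** — F₀/F = 1 + K_SV[Q]; the bimolecular rate
  constant k_q = K_SV/τ₀ and the temperature trend of K_SV together
  classify quenching as static (ground-state complex) or dynamic
  (collisional). Inner-filter correction F_c = F·b^((A_ex+A_em)/2) is
  applied when absorbances are supplied.
- **Modified Stern–Volmer** — log₁₀[(F₀−F)/F] = log₁₀K_a + n·log₁₀[Q]
  gives the association constant K_a and binding-site count n.
- **van't Hoff thermodynamics** — ln K_a vs 1/T yields ΔH and ΔS;
  ΔG = ΔH − TΔS per temperature; the (ΔH, ΔS) sign pattern labels the
  dominant force (hydrophobic / electrostatic / H-bond + van der Waals).
- **CD** — mean residue ellipticity MRE = θ/(10·C_p·n·l) and the 208-nm
  α-helix estimator %α = 100·(−MRE₂₀₈ − 4000)/29000.
- **FRET** — overlap integral J = ∫Fελ⁴dλ/∫Fdλ, Förster radius
  R0⁶ = 8.79×10⁻²⁵κ²n⁻⁴φJ, efficiency E = 1 − F/F₀ and distance
  r = R0((1−E)/E)^(1/6).

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

```python
from specbind import (GeneratorSpec, QuenchingResult, BindingResult,
                      classify_quench_mode, fit_stern_volmer,
                      generate_titration, vant_hoff, forster_radius,
                      fret_efficiency, donor_acceptor_distance)

# fit a synthetic noise-free titration (7 points, 0-15 uM quencher)
q = fit_stern_volmer(generate_titration(
    GeneratorSpec(quench_model="linear_sv", Ksv_per_M=7.16e4), 298.0))
print(f"Ksv = {q.Ksv_per_M:.3e} 1/M, kq = {q.kq_per_M_s:.3e} 1/(M s)")

# classify quenching mode from per-temperature constants
results = [QuenchingResult(T, k, 1.0, 1.0, k / 5.78e-9, 5.78e-9)
           for T, k in [(298, 7.16e4), (303, 5.54e4), (308, 4.06e4)]]
print("mode:", classify_quench_mode(results)[0])

# van't Hoff analysis of Ka(T)
th = vant_hoff([BindingResult(T, ka, 1.0, 1.0)
                for T, ka in [(298, 4.28e4), (303, 7.58e4), (308, 12.97e4)]])
print(f"dH = {th.dH_kcal_mol:.2f} kcal/mol, dS = {th.dS_cal_mol_K:.2f} "
      f"cal/(mol K), force = {th.force_type}")

# FRET distance from the overlap integral and donor quenching
R0 = forster_radius(1.20e-14)          # kappa2=2/3, n=1.336, phi=0.118
E = fret_efficiency(100.0, 50.4)
print(f"R0 = {R0:.3f} nm, E = {E:.3f}, r = {donor_acceptor_distance(E, R0):.3f} nm")
```

prints

```
Ksv = 7.160e+04 1/M, kq = 1.239e+13 1/(M s)
mode: static
dH = 20.22 kcal/mol, dS = 89.05 cal/(mol K), force = hydrophobic
R0 = 2.527 nm, E = 0.496, r = 2.534 nm
```

Reading: K_SV ≈ 7.2×10⁴ M⁻¹ with k_q three orders of magnitude above the
diffusion limit (2×10¹⁰ M⁻¹ s⁻¹) and K_SV falling with temperature means
the ligand quenches by forming a non-fluorescent ground-state complex
(static quenching). The positive ΔH and ΔS mark an entropy-driven,
hydrophobically stabilised association (ΔG ≈ −6.3 kcal/mol at 298 K), and
the donor–acceptor pair sits ~2.5 nm apart — comfortably inside the
<10 nm range where resonance energy transfer operates.

## Command line

Each stage is also a CLI subcommand operating on plain-text spectra
(`wavelength_nm,value` CSV/TSV) and YAML titration manifests:

```sh
specbind simulate --out data/ --seed 1        # synthetic dataset
specbind quench --series data/titration_298K.yaml \
                --series data/titration_303K.yaml \
                --series data/titration_308K.yaml
specbind thermo --ka 4.28e4@298 --ka 7.58e4@303 --ka 12.97e4@308
specbind report --series data/titration_298K.yaml ... --out report/
```

`report` writes `table_quenching.csv`, `table_thermo.csv`,
`table_fret.csv`, `table_cd.csv` and a JSON summary.

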