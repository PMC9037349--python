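# Methods

specbind analyses steady-state spectroscopic titrations of a protein with
a small-molecule ligand. The pipeline was built around a concrete system —
camel-milk lactoferrin (a ~80 kDa, 689-residue iron-binding glycoprotein
whose tryptophans emit near 335 nm) titrated with the black-tea polyphenol
theaflavin monogallate — but every stage is parameterised and applies to
any single-site quenching titration.

## Fluorescence quenching

The scalar intensity F for each titration point is obtained from the full
emission spectrum (see *Intensity reading* below), optionally corrected
for the inner-filter effect,

    F_c = F_obs · b^((A_ex + A_em)/2),

where A_ex and A_em are the sample absorbances at the excitation and
emission wavelengths. Both conventions for the base b (e and 10) exist in
the literature; the default is b = e, switchable via
`PipelineConfig.inner_filter_base`.

The Stern–Volmer constant K_SV is the OLS slope of F0/F against quencher
concentration [Q] (molar). The intercept is left free by default as a
quality check — it should be 1, and deviations expose residual
inner-filter or dilution artifacts — with `sv_intercept="fixed"`
constraining the line through (0, 1). The bimolecular quenching rate
constant is always the exact quotient k_q = K_SV/τ0, with the unquenched
donor lifetime τ0 a supplied constant (default 5.78 × 10⁻⁹ s, a typical
tryptophan value; no lifetime fitting is performed).

Quenching-mode classification combines two criteria over the
per-temperature results: static quenching requires every k_q to exceed
the maximum diffusion-limited collisional rate constant
(2 × 10¹⁰ M⁻¹ s⁻¹, strict inequality) *and* K_SV to decrease strictly
with temperature (heating dissociates weak ground-state complexes);
dynamic quenching requires the mirror-image pattern (k_q at or below the
limit, K_SV rising with faster diffusion). Anything else — including a
high k_q with a rising K_SV — is reported as inconclusive, with an
evidence string citing both criteria. The verdict is invariant to the
order in which temperatures are supplied. A single-temperature fit alone
is always labelled inconclusive.

## Intensity reading

Quenching by ground-state complexation scales the emission band without
shifting or reshaping it, so each point's spectrum is (up to noise) a
scalar multiple of the zero-concentration reference. The default
`intensity_mode="band"` estimates that scalar by least squares of the
whole spectrum on the reference band and multiplies it by the reference
peak intensity. This choice is deliberate: the binding constant comes from
the *intercept* of the double-log plot, an extrapolation over roughly five
decades of concentration that amplifies intensity noise about thirty-fold,
and the band reading averages multiplicative instrument noise over the
full wavelength grid (~160 points) instead of committing to one noisy
sample. `intensity_mode="peak"` reads the single fixed wavelength of the
reference emission maximum instead; the two are identical on noise-free
data and the fixed-λ mode remains useful when band shapes do shift.

## Binding constant and stoichiometry

For static quenching the quenched fraction obeys

    log10[(F0 − F)/F] = log10(K_a) + n·log10[Q],

fit by OLS: slope n (binding sites), intercept log10 of the association
constant K_a (M⁻¹). Free ligand is approximated by total ligand, as the
double-log method assumes. Points with F ≥ F0 carry no quenching
information and are excluded with a warning; at least three usable points
are required. The fit is exactly scale-invariant in F.

## Thermodynamics

K_a at three or more temperatures feeds an unweighted van't Hoff OLS of
ln K_a on 1/T:

    ΔH = −slope·R,  ΔS = intercept·R   (R = 1.987 cal mol⁻¹ K⁻¹),

with ΔH reported in kcal mol⁻¹ and ΔS in cal mol⁻¹ K⁻¹ (calorimetric
convention). ΔG = ΔH − TΔS is evaluated at each input temperature and the
identity holds bit-exactly in the result object. The dominant interaction
force follows the standard sign rules: ΔH > 0, ΔS > 0 hydrophobic;
ΔH < 0, ΔS > 0 electrostatic; ΔH < 0, ΔS < 0 hydrogen bond / van der
Waals. Zeros are treated as positive (logged); ΔH > 0 with ΔS < 0 has no
assignment under this scheme and raises. No heat-capacity term is
modelled.

`energy_to_affinity` converts a docking energy via K = exp(−ΔG/RT),
defaulting to 298 K. Note for the lactoferrin–theaflavin system: the
published docking energy of −9.7 kcal mol⁻¹ converts to ≈1.30 × 10⁷ M⁻¹
at 298 K, not the 2.03 × 10⁶ M⁻¹ printed alongside it; the package
implements the equation as stated and flags the discrepancy here rather
than reproducing it.

## Circular dichroism

Raw ellipticity θ (mdeg) is converted to mean residue ellipticity
MRE = θ/(10·C_p·n·l) with C_p the molar protein concentration, n the
residue count and l the path length in cm. The α-helix percentage is the
linear estimator at 208 nm,

    %α = 100·(−MRE₂₀₈ − 4000)/(33000 − 4000),

between the random-coil/β anchor (−4000) and the pure-helix anchor
(−33000 deg cm² dmol⁻¹). MRE at exactly 208 nm is linearly interpolated
on the wavelength grid. Noise can push the linear estimator out of
[0, 100]; such values clip with a warning instead of erroring. No
multi-basis deconvolution is attempted.

## FRET

The overlap integral J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ is evaluated by the
trapezoidal rule on the intersection of the donor and acceptor supports
(no extrapolation — extrapolated tails would silently inflate J), with
ε interpolated onto the donor grid and λ in cm, giving J in M⁻¹ cm³.
Acceptor spectra may be supplied directly as molar absorptivity or as
absorbance plus concentration (Beer–Lambert). The Förster radius follows
R0⁶ = 8.79 × 10⁻²⁵·κ²·n⁻⁴·φ·J (cm⁶), reported in nm; defaults
κ² = 2/3 (isotropic averaging), n = 1.336, φ = 0.118. Transfer efficiency
is E = 1 − F/F0 and the donor–acceptor distance
r = R0·((1 − E)/E)^(1/6), so E, R0 and r returned together always satisfy
E = R0⁶/(R0⁶ + r⁶). For the lactoferrin–theaflavin constants
(J = 1.20 × 10⁻¹⁴, printed R0 = 2.54 nm) the direct evaluation gives
2.527 nm (≈0.5% below the printed value, consistent with rounding of J);
the printed distance r = 2.44 nm is not mutually consistent with the
printed E = 49.6% and R0 (which imply r ≈ 2.55 nm) — the package reports
self-consistent triples only.

## Synthetic data generator

The generator emulates the study design: 5 μM protein excited at 280 nm,
emission on a 290–450 nm grid at 1 nm steps with a Gaussian band at
335 nm (width 25 nm), ligand titrated at 0–15 μM in 2.5 μM steps, at
298/303/308 K. Two quench models are available: `static_binding`
(F = F0/(1 + K_a[Q]^n), default, exact under the double-log fit; defaults
K_a = 4.28 × 10⁴ M⁻¹, n = 0.9538) and `linear_sv`
(F0/F = 1 + K_SV[Q], default K_SV = 7.16 × 10⁴ M⁻¹). When (ΔH, ΔS) are
set, K_a(T) lies exactly on the van't Hoff line before noise. An optional
inner-filter ramp stores per-point absorbances proportional to [Q] and
attenuates the emitted intensities accordingly, so the analysis-side
correction must undo it. Noise is multiplicative Gaussian
(CV-parameterised, one RNG stream per generated object, derived from a
single seed via stable CRC-keyed SeedSequences; fixed seed ⇒ byte-identical
output). Negative noisy intensities clip at zero.

The FRET generator pairs the donor band with a Gaussian acceptor
absorptivity band (centre 370 nm, width 40 nm, peak ε calibrated to
1.245 × 10⁴ M⁻¹ cm⁻¹ so the default pair yields J ≈ 1.2 × 10⁻¹⁴ M⁻¹ cm³,
i.e. R0 ≈ 2.5 nm); rectangular bands with a closed-form J and deliberately
disjoint bands are available for oracle and error-path tests. The CD
generator draws two negative Gaussian bands (208/222 nm) scaled so the
interpolated 208-nm MRE inverts the helix estimator at the target
percentage exactly.

What the generator does *not* emulate: asymmetric real band shapes,
wavelength-correlated noise, baseline drift, ligand depletion (free ≈
total ligand, matching the analysed model rather than binding physics),
and emission-maximum shifts. Passing round-trip tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to every instrument artifact.

## Problem sizes and numerics

Default test and simulation sizes are deliberately small — 7-point
titrations at 3 temperatures on a 161-point grid, 100-seed Monte-Carlo
repeats — matching the scale of a real titration experiment; all fits are
closed-form OLS so the full pipeline runs in well under a second.
Trapezoidal J converges quadratically (halving a 1-nm grid moves J by
<0.1% on Gaussian bands; a 2001-point rectangular grid agrees with the
closed form to ~1e-8 relative). Degenerate inputs (constant intensity,
zero acceptor, zero donor on the overlap range, E at 0 or 1) are either
flagged results or explicit errors, never silent NaNs.
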