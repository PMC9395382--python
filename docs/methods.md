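# Methods

## Scope and data model

The package analyzes the standard quantitative read-outs of a
DNA-staining dye characterization: absorption/emission spectra
(`Spectrum`: a strictly increasing wavelength grid with values and
metadata), fluorescence titrations at fixed dye concentration
(`TitrationSeries`), NaCl quench series (`QuenchSeries`), solvatochromic
wavelength tables, and linear calibration series. All concentrations are
carried internally in SI molar units; the CLI accepts µM (titrations),
mM (NaCl) and ng/mL (calibrations) and converts at the boundary. DNA
concentrations are per base pair throughout.

## Spectral descriptors

`lambda_max` is the raw argmax on the native grid — no peak fitting or
smoothing — with exact ties broken to the *longest* wavelength, because
the red-most band of these charge-transfer dyes is the analytically
useful one. `bathochromic_shift` is λmax(bound) − λmax(free), positive
for a red shift. Band areas (`integrate_band`) use trapezoidal
integration on the native grid without resampling; the bands handled
here are smooth and densely sampled, so higher-order quadrature buys
nothing. Beer–Lambert fits use a free intercept as a baseline
diagnostic, but ε comes from the slope alone. Baseline correction,
smoothing and band deconvolution are out of scope.

## Relative quantum yield

The slope-ratio method compares the slope (grad) of integrated emission
versus absorbance at the excitation wavelength between sample and
standard: Φ = Φ_ref·(grad/grad_ref)·(η²/η_ref²). The grad fit is
constrained through the origin — zero absorbance physically implies zero
emission — with the free-intercept R² reported as a diagnostic. A
warning (not an error) fires for absorbances above 0.15, where
inner-filter attenuation biases the slope, and for Φ > 1, which can only
arise from slope or reference misuse. The packaged standards are
fluorescein (Φ 0.95, λ_ex 470–490 nm), rhodamine 6G (0.95, 470–510 nm)
and cresyl violet (0.54, 540–590 nm). Inner-filter correction and
absolute (integrating-sphere) yields are out of scope.

## Lippert–Mataga analysis

The Stokes shift in wavenumbers is regressed on the orientation
polarizability Δf = (ε−1)/(2ε+1) − (n²−1)/(2n²+1). The slope equals
2(μ_E−μ_G)²/(hca³); the dipole conversion is done in CGS units (h in
erg·s, c in cm/s, cavity radius in cm, dipole in esu·cm, 1 D = 10⁻¹⁸
esu·cm) so the slope stays in cm⁻¹ per unit Δf. A negative fitted slope
(anomalous solvatochromism) raises rather than silently rooting a
negative number. Solvent constants (ε, n, E_T(30)) for the nine packaged
solvents are handbook values (CRC / Reichardt) — implementation data,
not fitted quantities. The symbol clash between the refractive index and
the binding site size (both conventionally *n*) is resolved by the field
names `refractive_index` and `site_size` throughout.

## Binding isotherm

The neighbor-exclusion isotherm in fluorescence form is fitted as Y on
X with Y = F and X = F·C_dye/C_DNA(bp):

    Y = F_max − (X/(C_dye·K_b))·(1 − (n−1)X/F_max)^(n−1) / (1 − nX/F_max)^n

**Forward simulation.** Both axes derive from the measured F, so
generating a titration point means solving F = Y(F·C_dye/C_DNA)
implicitly. The solver brackets F in (0, F_upper) with
F_upper = min(F_max, F_max·C_DNA/(n·C_dye))·(1−10⁻⁹) — the second term
is the pole of the isotherm at X = F_max/n — and runs Brent's method to
machine tolerance. The returned root's residual is verified against the
contract |residual| < 10⁻¹⁰·F_max; a bracket without a sign change (a
parameter regime where the dye is effectively fully bound) raises with
full diagnostics rather than returning a guess.

**Fitting.** Constrained nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) over
θ = (log₁₀K_b, n, F_max/max(F)), with bounds K_b ∈ [10², 10¹⁰] M⁻¹,
n ∈ [1, 20] bp, F_max ∈ [max(F), 100·max(F)]. Parametrizing F_max in
units of the largest observed intensity makes the fit exactly
gauge-invariant under uniform rescaling of the fluorescence axis.
Trial points beyond the pole get a smooth, steeply growing penalty
instead of an exception. A deterministic multistart — three heuristic
starts spanning intercalative and groove-scale site sizes plus a
16-point Latin hypercube with fixed seed 20240822 — guards against the
shallow K_b–F_max valley; the loop exits early only when a start reaches
an RSS at the rounding level of the data (no better solution exists),
and the winner is polished at tight tolerance. Plain (unweighted) least
squares is used; no weighting scheme is assumed. The fitter accepts an
explicit point-range mask for restricting to a linear-response range;
automatic range detection is deliberately not implemented, since any
such rule would be an undocumented analysis choice. F_max can be fixed
or floated; floating is the default.

**Mode heuristic.** `classify_binding_mode` maps site size < 3 bp to
"intercalation-leaning" and ≥ 3 bp to "groove-leaning" (boundary
inclusive to groove), always tagged `heuristic`: a footprint is
suggestive, not structural evidence.

**Identifiability.** On noiseless self-generated data the fitter
recovers all reference parameter sets to ~10⁻¹¹ relative; that round
trip is the accuracy standard. Under realistic noise the picture
changes: with 2% proportional noise on a 10-point titration over
0.3–3 µM DNA(bp) at 2 µM dye, a 200-replicate Monte-Carlo study gives a
median relative K_b error of ≈ 0.7 with F_max floating and ≈ 0.2 with
F_max fixed at truth — yet the fitted RSS beats the truth's RSS in every
replicate. K_b simply trades off against F_max when the titration stops
well short of saturation, a known weakness of this isotherm form. The
tests freeze these empirically measured thresholds (median < 1.0 free,
< 0.4 fixed); users wanting tight K_b values from noisy data should
titrate closer to saturation or fix F_max independently.

## Stern–Volmer quenching

(F₀/F − 1) is regressed on [Q] through the origin, matching the
equation's fixed unit intercept; the free-intercept line is reported as
a diagnostic for baseline drift or static-quenching curvature. Negative
K_SV is reported with a warning, not rejected. Quencher concentrations
enter the CLI in mM and are converted to M, so K_SV prints in M⁻¹.
Dynamic-versus-static discrimination and temperature dependence are out
of scope.

## Detection limits and DNA quantitation

LOD = 3·SD/slope. SD defaults to the residual standard deviation of the
calibration fit (dof-corrected, n−2); a blank-replicate SD can be
substituted. Calibrations require ≥ 5 concentration points. The
absorbance-ratio mode uses A(λ_f)/A(λ_i) — bound-band over free-band
absorbance, nearest grid point within 1 nm.

Duplex molecular weight is the residue-mass sum (dAMP 313.21, dCMP
289.18, dGMP 329.21, dTMP 304.20 g/mol) minus 61.96 per strand — the
5′-OH free-acid convention; synthesized-oligo suppliers quote the same
convention. Non-complementary strands warn rather than fail so
mismatched duplexes can still be weighed. ε₂₆₀ uses the standard
nearest-neighbor (Cantor–Warshaw–Shapiro) sum
Σε(doublets) − Σε(internal monomers); duplex ε₂₆₀ is reported as the sum
of the two single-strand values with an optional two-state
hypochromicity factor that defaults to 1.0 (no correction), since no
duplex-specific coefficient set is assumed.

## Synthetic data

Each generator produces data with exactly the structure its fitter
assumes: titrations via the implicit isotherm solver, quench series via
F = F₀/(1 + K_SV[Q]), Gaussian absorption/emission bands, Stokes-shift
series on the packaged solvent table, and linear calibrations. Defaults
mirror the characterization conditions: 2 µM dye, DNA(bp) 0.3–3 µM
(10 points), NaCl 50–200 mM (4 points), and 1% proportional Gaussian
noise when noise is enabled — a typical plate-reader reproducibility.
A single integer seed is split into fixed per-generator substreams
(`numpy` `SeedSequence` spawn keys), so adding a call to one generator
never shifts the noise another draws, and identical configurations give
identical output.

What the generators do *not* emulate: lamp drift, Raman/scatter bands,
inner-filter attenuation, baseline offsets, pipetting error in the
concentration axis, or specific solvent–dye interactions (H-bonding)
that bend a real Lippert plot. Passing round-trip tests therefore show
that the estimators are correct *for the assumed models*, not that real
spectra are free of these artifacts.

## Numerical choices

- λmax ties → longest wavelength; boundary site size 3.0 bp → groove.
- Brent root search: xtol 10⁻¹⁴·F_max, rtol at machine precision,
  verified residual < 10⁻¹⁰·F_max.
- Multistart least squares: first pass at 10⁻¹² tolerances capped at 600
  function evaluations per start; winner polished at 10⁻¹⁵.
- Origin-constrained slopes computed in closed form (Σxy/Σx²); all
  free-intercept lines via ordinary least squares.
- CODATA 2018 h and c; CGS bookkeeping for the Lippert slope→Debye
  conversion.
- Degenerate designs (all-equal predictors, fewer points than
  parameters) raise immediately with a named reason.

## Known limitations

- K_b is weakly identified from sub-saturating noisy titrations (see
  above); report F_max-fixed fits alongside free fits when precision
  matters.
- The mode heuristic ignores sequence specificity, cooperativity (no ω
  parameter) and mixed binding modes.
- The LOD follows the 3×SD/slope convention only; IUPAC alternatives and
  limits of quantification are not implemented.
- ε₂₆₀ hypochromicity is left to the user; the default duplex value is
  the plain single-strand sum.
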