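# dyedna

Quantitative analysis of fluorogenic DNA-binding dyes: spectral
characterization, relative quantum yields, solvatochromism, salt-induced
quenching, binding-isotherm fitting, and detection-limit calibration —
with seeded synthetic-data generators so the whole pipeline can be
exercised and validated without any measured spectra.

## Who this is for

Groups characterizing cationic (e.g. styryl) dyes as nucleic-acid
stains routinely produce the same small set of numbers from titration
and spectral data: the red shift of the absorption band on DNA binding,
the fluorescence enhancement F/F₀ and quantum yield Φ_F, the binding
constant and site size from a fluorescence titration, the Stern–Volmer
constant from a NaCl quench series, and the detection limit of a
calibration curve. `dyedna` implements each of these as a small, tested
operation with an explicit CSV/JSON interface, plus a CLI for running
them from a shell.

## The models

**Binding isotherm.** A dye occupying *n* contiguous base pairs on a
DNA lattice with binding constant *K*\_b follows the neighbor-exclusion
(McGhee–von Hippel) isotherm in its fluorescence form

    Y = F_max − (X / (C_dye·K_b)) · (1 − (n−1)X/F_max)^(n−1) / (1 − nX/F_max)^n

with Y = F, the fluorescence at the emission maximum, and
X = F·C_dye/C_DNA(bp). Fitting Y on X over a titration at fixed dye
concentration yields *K*\_b (M⁻¹), the site size *n* (bp per bound
dye), and the saturation intensity *F*\_max. Small *n* (< 3 bp) leans
toward intercalation, larger *n* toward groove binding — a heuristic
the package tags as such. Because both axes derive from the measured F,
*simulating* a titration requires solving the isotherm implicitly;
`forward_fluorescence` does this with a bracketed root search bounded
by the pole at X = F_max/n.

**Stern–Volmer quenching.** F₀/F = 1 + K_SV·[Q]; K_SV is fitted with
the intercept fixed at the equation's value of 1 (a free-intercept line
is reported as a diagnostic).

**Relative quantum yield.** Φ = Φ_ref · (grad/grad_ref) · (η²/η_ref²),
where each grad is the slope of integrated emission versus absorbance
at the excitation wavelength; reference standards (fluorescein 0.95,
rhodamine 6G 0.95, cresyl violet 0.54) ship with the package.
Brightness = ε·Φ.

**Lippert–Mataga.** The Stokes shift Δν̄ (cm⁻¹) is regressed on the
solvent orientation polarizability
Δf = (ε−1)/(2ε+1) − (n²−1)/(2n²+1); the slope 2(μ_E−μ_G)²/(hca³)
converts to the ground→excited dipole change given an Onsager cavity
radius.

**Detection limit.** LOD = 3·SD/slope of a linear calibration, in
fluorescence or A_f/A_i absorbance-ratio mode; duplex molecular weight
(from residue masses) and nearest-neighbor ε₂₆₀ convert between ng/mL
and molar units.

## Worked example

Simulate a noiseless titration of a 2 µM dye (K_b = 2.45×10⁵ M⁻¹,
n = 2.1, F_max = 100) over 0.3–3 µM DNA(bp) and refit it:

```sh
dyedna simulate titration --k-b 245000 --site-size 2.1 --f-max 100 --out titration.csv
dyedna fit-binding titration.csv
```

```json
{
  "command": "fit-binding",
  "estimates": {
    "k_b_per_M": 245000.0000007737,
    "site_size_bp": 2.1000000000007453,
    "f_max": 99.99999999988202
  },
  "diagnostics": {
    "rss": 6.63926341255605e-24,
    "n_starts_used": 1,
    "binding_mode": "intercalation_leaning",
    "mode_basis": "heuristic"
  }
}
```

(record abridged). The fit recovers the generating parameters to
~10⁻¹¹ relative — the generator is an exact fixed point of the fitter —
and the site size of 2.1 bp is classified as intercalation-leaning.
The same pattern works for every stage: `simulate quench` →
`fit-quench`, `simulate calibration` → `lod`, `simulate spectrum` →
`spectra`, and `qy`/`lippert` on (absorbance, intensity) or
(solvent, λ_abs, λ_em) tables.

The library surface mirrors the CLI: see `dyedna.binding.fit_binding`,
`dyedna.quenching.stern_volmer_fit`, `dyedna.quantum_yield`,
`dyedna.solvatochromism`, `dyedna.detection`, and
`dyedna.synthetic` for the generators.

## Documentation

`docs/methods.md` describes the models, their assumptions, the
numerical choices (root-bracketing, multistart fitting, tie-breaks),
what the synthetic generators do and do not emulate, and known
limitations — in particular the weak identifiability of K_b under
noise when F_max floats.
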