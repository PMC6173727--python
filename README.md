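# nanorodmech

Quantitative nanomechanics of self-assembled peptide nanorods — thin, stiff
filaments built from stacked, hydrogen-bonded cyclic peptide rings and imaged
by AFM or pulled apart in steered molecular dynamics.

The package implements the full analysis chain such a study needs, as a
tested, reusable library with a small CLI:

1. **Chain statistics** (`chain_statistics`): pool all internal point pairs
   of traced fibril contours into binned profiles and estimate the
   persistence length λ with three planar (2D) worm-like-chain estimators —
   the mean-squared end-to-end distance model

   ⟨R²⟩(l) = 4λ [ l − 2λ (1 − e^(−l/2λ)) ],

   the bond-correlation function ⟨cos θ⟩(l) = e^(−l/2λ), and the
   mean-squared midpoint displacement ⟨u²⟩(l) = l³/48λ.
2. **Rod mechanics** (`rod_mechanics`): propagate λ to the bending rigidity
   C_B = λ·k_B·T, the second moment of area I₀ = πd⁴/64 of a solid circular
   rod, and the elastic modulus E = C_B/I₀, with SD propagation.
3. **Tensile analysis** (`tensile_analysis`): normalize force–extension
   traces into engineering stress–strain curves and extract the initial
   modulus, tensile strength, strain to failure, toughness
   (∫σ dε, in GJ m⁻³), and the stick-slip rupture events left by
   hydrogen-bonded interfaces failing one at a time.
4. **Titration** (`titration`): compute protonated-amine fractions from
   N 1s component areas and fit the four-parameter sigmoid
   f(pH) = A·10^(B(pK−pH))/(1+10^(B(pK−pH))) + C to determine the pK.
5. **Synthetic data** (`synthetic_data`): generators for all three input
   kinds — planar worm-like chains with tracing noise, saw-tooth pulling
   traces with exact analytic areas, and noisy titration tables — so every
   stage is testable against known ground truth without any instrument data.

## Worked example

The demo pipeline simulates a traced nanorod population, fits λ, propagates
it to a modulus, analyzes a seven-interface saw-tooth pulling trace, and
fits a titration pK:

```sh
nanorodmech run-all --outdir demo --seed 0 --n-fibers 418
```

```
rod mechanics summary
  persistence length  = 8.6e-06 m +/- 8e-07 m
  temperature         = 298 K
  bending rigidity    = 3.5e-26 N m^2 +/- 3e-27 N m^2
  moment of inertia   = 7.85e-37 m^4  (solid circle, d = 2 nm)
  elastic modulus     = 45 GPa +/- 4 GPa
reference chain: I0 = 7.85e-37 m^4, E = 50.9 +/- 6.4 GPa
tensile: E_init = 0.3183 GPa, sigma_max = 0.1464 GPa, eps_max = 152.5 %, U = 0.1258 GJ/m^3, 7 ruptures
titration: pK = 7.989 +/- 0.016 (truth 8.0)
```

Reading the output: the simulated population (418 fibers of 150–300 nm, true
λ = 9.72 µm) is far stiffer than it is long, so the fitted λ carries a known
downward bias (see `docs/methods.md`); the "reference chain" line is the
fixed arithmetic C_B = 4.0 × 10⁻²⁶ N m² → I₀ = 7.85 × 10⁻³⁷ m⁴ →
E = 51 ± 6 GPa for a 2.0 nm rod. The tensile line shows the seven programmed
stick-slip ruptures recovered by the detector, and the titration pK is
recovered to 0.01 pH units at realistic noise.

Each stage is also available separately (`simulate-chains`,
`fit-persistence --model {wlc,bcf,msmd}`, `mechanics`, `simulate-trace`,
`tensile`, `simulate-titration`, `titrate`); every run writes a JSON run
report echoing the full configuration, and every stochastic stage takes
`--seed` and is bit-reproducible.

Library use mirrors the CLI:

```python
import nanorodmech as nm

params = nm.WlcParams(persistence_length=200.0, contour_length=500.0, step=2.0, seed=1)
ens = nm.generate_contour_ensemble(params, n_fibers=2000, length_range=(500, 500), noise_sd=0.0, seed=1)
fit = nm.fit_persistence_wlc(nm.ms_end_to_end_profile(ens, n_bins=100))
summary = nm.mechanical_summary(fit, nm.RodGeometry(diameter_nm=2.0), temperature=298.0)
print(fit.lam, summary.elastic_modulus / 1e9)  # nm, GPa
```

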