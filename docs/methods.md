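# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `nanorodmech`.

## Planar worm-like-chain conventions

Traced fibril contours come from filaments adsorbed and equilibrated on a
flat substrate, so all chain statistics are treated in two dimensions. The
three persistence-length estimators use the mutually consistent 2D forms:

- mean-squared end-to-end distance of an inner segment of arc length l:
  ⟨R²⟩ = 4λ[l − 2λ(1 − e^(−l/2λ))]; the large-l limit is 4λl and the
  small-l limit is l²;
- tangent correlation: ⟨cos θ⟩(l) = e^(−l/2λ) (the factor 2 in the decay
  length is the 2D convention);
- mean-squared midpoint displacement: ⟨u²⟩(l) = l³/48λ, valid in the
  weak-bending window l ≲ λ/2, where u is the perpendicular deviation of a
  segment's arc midpoint from its chord.

Profiles pool **all** internal point pairs (i < j) of every fiber — not a
sliding window — into equal-width arc-length bins (default 100 bins over
[0, longest fiber]). Bins with fewer than 5 pairs are dropped before
fitting (configurable); sparse large-l bins otherwise dominate an
unweighted fit. The default fit weighting is by per-bin pair count, with a
uniform option.

The ⟨R²⟩ model is evaluated with `expm1`, switching to the series
l²(1 − x/3 + x²/12 − x³/60 + x⁴/360), x = l/2λ, for x < 10⁻², where the
closed form loses the λ-dependence to floating-point cancellation. Fits are
single-parameter least squares initialized at λ₀ = ⟨R²⟩_max/(4 l_max)
(the flexible-limit inversion), clipped to [1, 10⁶] nm, with tolerances
10⁻¹² on parameter and cost change. λ uncertainty is reported from the fit
covariance; a fiber-bootstrap (resampling contours with replacement,
default 200 seeded replicates) is provided as an alternative SD because a
reported "mean ± SD over N fibers" is ambiguous between the two
constructions.

The midpoint-displacement fit chooses its validity window
self-consistently: fit on all bins, restrict to l ≤ λ̂/2, refit (two
iterations, deterministic). On stiff ensembles this estimator carries a
+8–11% residual bias from the truncation of the cubic law, comfortably
inside the 15% cross-estimator agreement band observed on 2000-chain
ensembles.

Fiber selection mirrors AFM practice: contours shorter than a minimum
length (default 50 nm) are removed before analysis, and an emptied ensemble
raises an error rather than letting a fit proceed silently.

## Synthetic contours

The generator samples the tangent angle as a Gaussian random walk with
variance Δs/λ per step of length Δs, giving ⟨cos θ(s)⟩ = e^(−s/2λ) exactly
on the sampled grid and the 2D WLC end-to-end law to O(Δs/λ). Defaults:
Δs = 2 nm (the rod-diameter scale, finer than a typical AFM pixel), fiber
lengths uniform on 150–300 nm (a typical nanorod population), isotropic
Gaussian tracing noise of SD 0.5 nm per point (sub-pixel tracing accuracy;
the true tracing noise of fiber-tracking software is not published, so this
is an explicit, configurable stand-in). Each fiber draws from its own
`SeedSequence`-spawned stream, so ensembles are bit-reproducible and the
noiseless counterpart of a noisy ensemble is recoverable from the same
seed.

What the generator does *not* emulate: excluded volume, tip convolution,
fiber crossings and bundling, non-equilibrium adsorption (trapped 3D
configurations), and curvature-correlated tracing error. Parameter-recovery
tests therefore demonstrate estimator correctness on ideal equilibrated 2D
chains, not robustness to every AFM artifact.

Known regime limitation, deliberately kept visible: when λ greatly exceeds
the longest fiber (λ/L ≳ 30, as for micron-scale persistence lengths
measured on 150–300 nm fibers), the ⟨R²⟩ profile is nearly the straight-line
limit and the fitted λ is biased low with large relative uncertainty —
tracing noise and binning push ⟨R²⟩ below l² only weakly. The fit still
converges and reports its SD; the demo pipeline shows the effect (λ̂ ≈ 8.6 µm
for a true 9.72 µm).

## Rigidity and modulus chain

C_B = λ·k_B·T with the exact SI Boltzmann constant; T defaults to 298 K
(room-temperature deposition and a common thermostat setpoint) and is
configurable — the temperature used alongside a published rigidity is often
unstated, so it is always echoed in output. The cross-section is a solid
circle of diameter d (the conservative choice when side chains make the
true boundary ambiguous; d is taken from the AFM height), giving
I₀ = πd⁴/64 and E = C_B/I₀. By default geometry is treated as exact, so
SD_E = SD_CB/I₀; an optional mode adds the quartic diameter sensitivity
4·SD_d/d in quadrature. Displayed values are rounded to 2 significant
figures (central) and 1 (SD); stored values keep full precision. The
reference arithmetic — d = 2.0 nm → I₀ = 7.85 × 10⁻³⁷ m⁴, and
C_B = 4.0 × 10⁻²⁶ ± 5 × 10⁻²⁷ N m² → E = 51 ± 6 GPa — is asserted in the
test suite at printed precision.

## Tensile analysis

Engineering strain ε = Δx/L₀ and stress σ = F/(π(d/2)²) (1 pN nm⁻² =
10⁻³ GPa); strains are reported as percentages and may far exceed 100%.
L₀ is the initial fixed-ring-to-pulled-ring distance and must accompany the
trace (file header or explicit argument).

- **Rupture detection**: a rupture is a local stress maximum followed, before
  the next rise, by a drop of at least `drop_fraction` (default 0.2) of the
  peak and at least an absolute floor (default 2% of the global maximum,
  separating thermal jitter from interface failures). Plateau ties report
  the first index. Both thresholds are configurable and echoed in output.
- **Initial modulus**: through-origin least squares on the window from 0 to
  min(half the first-rupture strain, 0.05). Published stress–strain analyses
  rarely define their "linear region"; this rule is deterministic and the
  window bounds are recorded with the result.
- **Strain to failure**: the strain of the last rupture event; for a curve
  with no ruptures, the strain at the global stress maximum. When a stop
  force (e.g. a 500 pN protocol cap applied once all interfaces have failed)
  terminates the trace, the cap strain is reported separately as censoring
  information, never as the metric.
- **Toughness**: trapezoidal ∫σ dε from 0 to the failure strain, in GJ m⁻³
  (numerically GPa × unit strain); the endpoint is interpolated if it falls
  between samples.

The saw-tooth generator builds piecewise-linear traces with instantaneous
drops (zero displacement width — fast relative to pulling, and it keeps the
analytic area exact as a sum of trapezoids). The stored area gives the
exact-identity test U = area/(A·L₀) to 10⁻⁹ relative tolerance, and the
programmed interface count gives the detector-completeness test for 1–10
interfaces. Replicate traces are summarized as mean ± SD per metric (SD
omitted for a single trace).

## Titration

f(pH) = A·10^(B(pK−pH))/(1+10^(B(pK−pH))) + C, evaluated through the
logistic function of (ln 10)·B·(pK−pH) so it is overflow-safe arbitrarily
far from the pK. Fractions from component areas are
f = a₊/(a₊ + a₀); upstream spectral deconvolution is out of scope. The fit
is four-parameter bounded least squares (A ∈ [0,2], B ∈ (0,100], C ∈ [0,1],
pK within the data range ± 5) with the deterministic initialization
C₀ = min f, A₀ = range of f, B₀ = 1, pK₀ = pH of the datum nearest the
mid-fraction. Replicates (default triplicate) are fit as individual points;
a flag averages them first. SDs come from the fit covariance.

The generator clips noisy fractions to [0, 1], as a real fraction
measurement would be. Clipping slightly inflates the apparent baseline near
f = 0 (by E[max(0, N(0, σ))] = σ/√2π ≈ 0.008 at σ = 0.02), so an individual
fitted baseline can sit near 0.01 even when the true C = 0; across
replicates the mean fitted curve above pH 11.5 stays below 0.01, and pK
recovery is unaffected (mean |error| ≈ 0.015 pH units at triplicate,
σ = 0.02 conditions).

## Problem sizes

Parameter-recovery runs use 2000 chains of 500 nm at λ = 200 nm
(≈ 63 million pooled pairs), chosen so Monte-Carlo scatter of the fitted λ
is a few percent — well inside the 10–15% agreement bands — while a full
run of the suite or the acceptance script completes in well under a minute.
pK recovery uses 100 seeded triplicate titrations.

## File formats

Contours: multi-fiber XY text (nm), blank-line- or id-column-separated,
`#` comments, `# units nm` and `# key = value` metadata. Traces: two-column
displacement/force text tolerating `@`/`#` comment lines (xvg-dialect), with
geometry in `# L0 = …`, `# d = …`, `# force_cap = …` headers. All numbers
are written with 10 significant digits; a write–read round trip reproduces
values to that precision and is exactly idempotent thereafter. Non-monotone
displacement is stably sorted with a recorded warning; malformed rows fail
with the offending line number.
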