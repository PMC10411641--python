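# Methods

`skinbis` answers one question from surface bioimpedance spectra: *which skin
layer changed its conductivity?* It does so with a fully synthetic pipeline —
a layered-tissue forward model generates the spectra, a relaxation-time
analysis chooses the measurement frequencies, ratiometric features isolate the
tissue change, and a shallow neural network names the layer. This note
documents the models, the defaults and why, and what the synthetic setting
does and does not demonstrate.

## Tissue model

Skin is modelled as four planar layers — stratum corneum (S, 50 µm),
epidermis (E, 0.45 mm), dermis (D, 2.5 mm) and fat (F, 5 mm), total 8 mm —
each with a frequency-dependent conductivity σ(f) [S/m] and relative
permittivity εr(f). At frequency f the layer behaves as the quasi-static
complex admittivity σ\* = σ + j·2πf·ε₀·εr. Dispersion tables are sampled on
a log-frequency grid and interpolated linearly in log₁₀(f), with constant
extrapolation outside the table; linear-in-log interpolation is smooth,
monotone between samples, and the standard choice for dispersion data.

The shipped per-layer tables are **declared configuration, not measured
data**. Published per-layer skin dielectric curves are available only as
plots spanning wide ranges, so the defaults were chosen once inside those
ranges with the qualitative ordering every source agrees on: the stratum
corneum is by far the least conductive (σ ≈ 2·10⁻⁴–2.5·10⁻³ S/m in-band) and
strongly dispersive, the dermis the most conductive (σ ≈ 0.4–0.64 S/m), the
viable epidermis intermediate, and fat poorly conductive with weak
dispersion. Any quantitative result of the pipeline (in particular the
classification accuracies) is conditional on these tables; swapping in a
different YAML stack changes the numbers, which is why accuracies from other
dielectric inputs are not comparable figure-for-figure.

A conductivity change is applied multiplicatively, σ → σ·(1 + Δσ/100), to
one of ten layer combinations ψ₁..ψ₁₀ (the four single layers, S+E, E+D,
D+F, S+E+D, E+D+F, and all four); permittivity is held fixed. The change is
exactly invertible and never mutates the input stack.

## Forward problem

The measurement is modelled with the complete electrode model (CEM):
∇·(σ\*∇φ) = 0 in the domain, a Robin coupling φ + z_l σ\*∂φ/∂n = U_l under
each electrode, a prescribed total current per electrode (+I on the source,
−I on the sink, 0 on passive pads), and a no-flux condition elsewhere. The
gauge is fixed by grounding the current sink (U = 0). The lumped contact
impedance Z_c (default 50 Ω per electrode) is converted to the distributed
coefficient z_l = Z_c·|e_l|, so a uniform current density drops Z_c·I across
the contact. The Z_c = 0 limit is handled exactly by tying electrode nodes
to the electrode potential (shunt model) instead of letting the Robin
coefficient blow up.

The electrode array is four colinear pads, diameter d_e ∈ {1, 2, 3} mm, gap
d_g = 1 mm, drive current 1 mA. Bipolar measurements use the two central
pads for both drive and sense.
The choice of the central pair is a package convention (it matches the
electrode-length definition D = d_g + d_e spanning one gap and one diameter)
and is configurable. Tetrapolar drives the outer pads (e1 source, e4 ground)
and senses the inner pair (e2 high, e3 low). The three electrode sizes carry the categorical
penetration-depth labels D/H<1, D/H=1, D/H>1. With the stack summing to
H = 8 mm the arithmetic D/H never exceeds 1 for these diameters, so the
labels are treated as enumeration labels attached to d_e, not as verified
ratios.

**Discretization.** Structured tensor-product grids with bilinear (2-D) or
trilinear (3-D) elements. Because each layer's admittivity is spatially
constant, the stiffness matrix is assembled once per layer with unit
admittivity; a frequency sweep only recombines the four cached blocks and
pays one sparse direct factorization per frequency (deterministic). The
vertical grading gives every layer at least two element rows — the 50 µm
stratum corneum included — and lateral margins extend five array-lengths
with geometrically growing elements, so domain truncation is folded into the
mesh-convergence check. The default is a 2-D per-unit-depth section through
the array axis (default grid ≈ 1 800 nodes, ~15 ms per solve), accurate
enough that a 2× refinement moves |Z| by well under 1 %; a 3-D grid with
circular electrode footprints (top faces within d_e/2 of the pad center) is
available via `MeshResolution(dim=3)` and satisfies the same conservation
and reciprocity invariants. Solver correctness rests on exact discrete
properties: per-electrode current balance to ~10⁻¹⁵·I, drive/sense
reciprocity to ~10⁻¹², and Z(c·σ\*) = Z(σ\*)/c exactly by linearity.

## Distribution of relaxation times

A spectrum is deconvolved as Z(f) = R∞ + ∫ γ(ln τ)/(1 + j2πfτ) d ln τ with
γ ≥ 0. γ is expanded in Gaussian RBFs g_m(ln τ) = exp(−(µ|ln τ − ln τ_m|)²)
on a log-spaced τ grid (10 points/decade spanning [1/(2πf_max), 1/(2πf_min)]
extended one decade each side); µ is set so the RBF FWHM equals the grid
spacing times a configurable factor (default 1). The kernel integrals are
evaluated with 32-point Gauss–Legendre quadrature on ±4/µ around each
center; doubling the order changes the matrices by < 10⁻⁸ relative, and the
entries match dense trapezoid quadrature to the same level.

The amplitudes Θ and R∞ (one extra non-negative unknown, since R∞ is not
separately observable in the stacked objective) are found by active-set
non-negative least squares on the stacked real/imaginary system with a
Tikhonov ridge √λ on Θ only. λ defaults to 10⁻³: small enough to resolve
modes two decades apart, large enough to keep the noise-free fixtures free
of spurious structure; residual is non-decreasing in λ, and the default sits
on the flat part of that curve for the fixtures used here. On a noise-free
single-Debye fixture the solver recovers the peak τ within one grid step,
the polarization mass within 5 % and R∞ within 2 %.

Peaks and valleys of γ are detected on a 10×-dense ln τ grid after a
3-point moving average, keeping only extrema with prominence above 2 % of
max γ — non-negative deconvolution leaves sub-percent ripple around genuine
modes, and a prominence threshold separates the two cleanly (observed ripple
≲ 0.6 %, genuine modes ≥ 65 %). Frequency pairs (f_low < f_high) from the
candidate set {2, 10, 35, 100, 225} kHz are then ranked: pairs whose members
straddle at least one valley (mapped to f = 1/(2πτ_valley)) probe different
relaxation regions and rank first, ties break toward wider log-frequency
span, then lexicographically. The straddle-count rule is this package's
formalization of the otherwise qualitative idea that a useful pair should
probe two different relaxation regions.

## Features

For a pair (f_low, f_high): Z′ = |Z_l|/|Z_h|, θ′ = arg Z_l − arg Z_h (in
degrees at the API boundary, radians internally), R′ = Re Z_l/|Z_h|,
X′ = Im Z_l/|Z_h|; the classifier inputs are the relative changes
α = (x_t − x_t0)/x_t0 against the standard-conductivity baseline of the same
configuration. Common instrument gain and common phase offset cancel
exactly — asserted to machine precision in the tests. If a baseline quantity
is smaller than 10⁻⁹ (its natural units) the relative change is undefined;
that component falls back to the absolute difference and the record is
flagged rather than dropped. The threshold is a package convention; the
simulated grid never triggers it.

The 14-entry profile catalogue (4 single-input, 6 two-input, 3 three-input,
1 four-input) deliberately omits Z′+R′+X′ from the three-input family; an
opt-in flag adds the missing combination for completeness.

## Study grid and labels

The full grid crosses 2 patterns × 3 electrode sizes × 10 selectors × 17
change levels (−20..+20 % in 2.5 % steps, 0 = standard) × 10 pairs = 10 200
cases, each with the canonical id `phi_deltab_psi_dsigma_flow&fhigh` (e.g.
`I_D/H<1_S_-20_2&10`), formatted and parsed losslessly. Spectra are cached
per unique physics configuration: all pairs share one five-frequency
spectrum, all selectors and levels share the baseline, so the full grid
costs 5 100 × 2 solves ≈ 70 s on one core rather than 10 200 × 10.

Labels collapse combinations containing the dermis onto the dermis class
(its response dominates the others), yielding five classes (S, E, D, F,
S+E) with a 1:1:6:1:1 skew per grid cell. Some balancing mechanism is needed
for honest training on that skew; the default here is
inverse-frequency class weights (keeps every physics run; weights normalized
to sum to the class count), with seeded stratified subsampling to the
minority count available for a strictly balanced design.

## Classifier

One hidden layer of 100 ReLU neurons, five linear outputs, argmax prediction
(ties to the lowest class index). The package declares its own training
recipe: softmax
cross-entropy minimized by mini-batch gradient descent with momentum 0.9,
learning rate 0.05, batch 64, 200 epochs, seeded He-scaled initialization,
and per-feature z-scoring fitted on training folds only (the α components
span orders of magnitude). Validation is stratified 5-fold with a seeded
shuffle; accuracy is 100·T_predict/T_samples and the 5×5 confusion matrix is
row-normalized to percent, with absent-class rows flagged as undefined
rather than zero-filled. Every random choice flows from one seed; identical
inputs give identical reports. One model is trained per (pattern, frequency
pair), so accuracy can be reported pair-by-pair the way the frequency-pair
selection question demands; pooling pairs into one model is a trivial
extension (concatenate before training).

## What the synthetic study shows — and does not

The generator reproduces the *structure* of the measurement campaign
(geometry, patterns, frequencies, change levels, labels) with noise-free,
deterministic spectra. Passing tests therefore demonstrate that the method
separates the five classes when the forward physics is the only source of
variation. They do not demonstrate robustness to electrode placement error,
electrode polarization drift, temperature/hydration parasitics, or
biological variability — the ratiometric features cancel the *common-mode*
part of such errors exactly, but nothing here measures the non-common-mode
residue. Accuracies obtained elsewhere with different dielectric inputs,
different solvers, or wet-tissue measurements are consequently not
figure-for-figure comparable; the package's own accuracies (≈ 93 %
bipolar, ≈ 83 % tetrapolar at the top-ranked pair on the full default grid,
seed 1) are reproduced exactly by `scripts/acceptance.py`.

## Numerical choices and degenerate inputs

- Sparse complex direct solve (SuperLU); no iterative tolerance to tune.
- All-insulating admittivity raises a solver error; a layer thinner than two
  element rows raises a configuration error with guidance.
- Spectra must be strictly increasing in frequency with finite nonzero Z.
- DC queries (f = 0) use the lowest tabulated dispersion sample and a
  vanishing reactive part.
- NNLS is deterministic; its iteration cap scales with the grid size and a
  failure surfaces the residual rather than returning silently.
- Problem sizes: the default test and acceptance runs use the 2-D default
  mesh (≈ 1 800 nodes) and the full 10 200-case grid; the 3-D path runs at
  reduced resolution to exercise geometry handling rather than accuracy.

## Known limitations

- Planar 2-D default geometry: absolute impedance levels differ from a 3-D
  disc-electrode array by a geometry factor; ratiometric features absorb
  most, but not all, of the difference.
- No Cole–Cole fitting; dispersion is whatever the tables say.
- No electrode polarization electrochemistry; contact impedance is a real
  constant per electrode.
- Anisotropic conductivity, muscle backing, and sensitivity maps are out of
  scope.
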