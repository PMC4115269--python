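# Methods

This document defines the model implemented by `scosfire`, the parameter
conventions, the synthetic stimulus generators, and the numerical choices
that make the implementation exact and reproducible.

## Coordinate conventions

All arrays are indexed `img[iy, ix]` in a **math frame**: x increases
rightward, y increases upward, and angles are measured counterclockwise from
the +x axis in radians. The vertical flip to and from raster image order
happens only in `scosfire.io`. Distances are in pixels. Serialized filters
record the frame tag `math-y-up`.

## Layer 1: Gabor energy

`build_gabor_bank(wavelengths, n_orientations)` builds quadrature Gabor
pairs (even and odd phase) for every wavelength λ and orientation
θ = kπ/n, k = 0 … n−1. Kernel shape follows the standard contour-operator
parameterization: envelope bandwidth 1 octave and spatial aspect ratio 0.5
(`GaborParams`). The even kernel is mean-subtracted and both kernels are
L2-normalized, so the response is invariant to additive intensity offsets.

`gabor_energy` convolves (via FFT) and returns the quadrature energy
√(even² + odd²), which is invariant to contrast polarity. Each channel is
calibrated so that an ideal straight line of the preferred orientation and
matching width yields energy ≈ 1; responses are clipped to [0, 1]. Energies
below `ENERGY_FLOOR = 1e-12` are set to exactly zero: this is the FFT
round-off scale, and flooring it guarantees that a constant image produces
an exactly zero stack (which the AND-combination downstream relies on).

`surround_suppress(stack, coefficient)` subtracts, per channel, a
difference-of-Gaussians surround average of the energy, half-wave rectified.
It attenuates texture (many parallel contours) more than isolated contours.

## The COSFIRE combination (both upper layers)

A COSFIRE filter is a set of tuples; each tuple names a subunit and a polar
position (ρ, φ) relative to the filter center. Evaluation is identical at
both layers:

1. **Threshold** the subunit's response map at fraction t₁ of its global
   maximum (values below become 0).
2. **Blur**: grayscale dilation with a peak-normalized Gaussian weight of
   std σ = σ₀ + αρ, i.e. a weighted maximum over the window
   |x′|, |y′| ≤ ⌈3σ⌉. Positional tolerance grows with eccentricity.
3. **Shift** by (−ρ cos φ, −ρ sin φ), rounded to integer pixels, so the
   subunit's expected position maps onto the filter center.
4. **Combine** all tuple maps by a weighted geometric mean with weights
   ω = exp(−ρ²/2σ′²). By default σ′ = ρ_max / √(2 ln 2), which makes
   ω(0) = 1 and ω(ρ_max) = 1/2 exactly (half-response radius); when
   ρ_max = 0 all weights are 1. The output may finally be thresholded at
   fraction t₃ of its maximum.

The geometric mean is an AND-gate: the response is exactly zero wherever
any tuple's (thresholded, blurred, shifted) map is zero, and it never
exceeds the weakest part by much. This is what makes the filters selective
for the *arrangement* of parts rather than their sum.

## Layer 2: the vertex-filter bank

A V-COSFIRE filter takes Gabor channels as subunits. `configure_v_cosfire`
applies the bank to a prototype corner image and samples local maxima of
the orientation-summed energy on concentric circles (default radii 8, 12,
16, 20 px) around the point of interest, keeping orientations that respond
above a gate of 0.3× the circle maximum; each kept point contributes a
tuple ((λ, θ), ρ, φ).

`build_vertex_bank()` renders synthetic two-arm corner stimuli and
configures one filter per stimulus: 12 corner orientations β in steps of
π/6 (offset so that the grid contains the corners of an apex-up equilateral
triangle) × 5 aperture angles γ ∈ {π/6, π/3, π/2, 2π/3, 5π/6} = **60
filters**, each selective for a corner whose arms point at β ± γ/2.

Bank filters evaluate with an internal subunit threshold `response_t1`
(default 0.1; the clutter preset uses 0.3) applied to their Gabor inputs.
This is distinct from the shape-level t₁, which thresholds the *vertex
filter responses*. Without the internal threshold, sub-threshold Gabor
tails of nearby contours keep the vertex response — and hence the shape
response — from ever reaching exact zero, which would destroy the AND
property.

## Layer 3: shape filters

An S-COSFIRE filter takes V-COSFIRE filters as subunits.
`configure_s_cosfire` applies all 60 bank filters to the prototype, takes
the per-pixel maximum over the bank, finds its strict 8-neighbor local
maxima, keeps those above t₂ (default 0.75) of the global maximum, and at
each kept point creates one tuple per bank filter within t₂ of the local
best. Configuration is run on the prototype shape alone; the configured
filter is then applied to arbitrary scenes.

Tolerance to geometric transforms is by tuple-set algebra, not image
resampling: `rotate_s` adds ψ to every φ and rotates every vertex filter
(which in turn rotates its Gabor channels and tuple angles); `scale_s`
multiplies ρ and wavelengths by υ and rescales σ′; `reflect_s` mirrors
about the y axis. `invariant_response` evaluates a grid of transformed
filters (`InvarianceSpec`) on a shared response context and returns the
pixelwise maximum plus the transform label achieving it.

## Detection and serialization

`local_maxima` extracts strict 8-neighbor maxima (plateaus contribute their
lexicographically smallest pixel; values below 1e-9 of the map maximum are
treated as numerical noise), thresholds at t₃ of the global maximum,
applies greedy non-maximum suppression with a minimum separation (default
ρ_max/2 in the CLI), and optionally truncates to the top k. Filters
round-trip losslessly through versioned JSON (`scosfire-filter`, version 1):
loading a saved filter reproduces byte-identical response maps.

## Parameter summary

| Symbol | Meaning | Default |
|---|---|---|
| λ | Gabor wavelength (px) | 4 |
| n | orientations per wavelength | 12 |
| bandwidth | Gabor envelope bandwidth (octaves) | 1 |
| aspect ratio | Gabor envelope elongation | 0.5 |
| σ₀, α | blur std σ = σ₀ + αρ | 0.1, 0.0853 |
| t₁ | subunit-response threshold fraction | 0 (shape level) |
| `v_t1` | vertex filters' internal Gabor threshold | 0.1 |
| t₂ | configuration selection fraction | 0.75 |
| t₃ | output threshold fraction | 0.1 |
| σ′ | geometric-mean weight std | ρ_max/√(2 ln 2) |
| bank radii | vertex-configuration circles (px) | 8, 12, 16, 20 |

Named bundles for the worked examples (`preset`): `fig4-triangle` (values
above), `keyword-3.1` (σ₀ = 0.67, α = 0.1, t₁ = t₃ = 0.1), and `shoes-3.2`
(16 orientations, surround suppression 1.0, t₁ = 0.3, α = 0.67, top-2
detections, reflection invariance over scales {¾, 1, 1¼} and rotations
{−π/8, 0, π/8}).

## Synthetic stimuli

`scosfire.fixtures` renders all test stimuli deterministically
(anti-aliased, butt-capped strokes; white on black; [0, 1] float):
outlined equilateral triangles and squares (with an `orientation`
parameter), Kanizsa-style inducer discs (a filled disc per triangle vertex
with an interior-facing π/3 wedge removed, supersampled 4×, no connecting
contours), and square variants for perceptual-ranking experiments —
`partial` (25% of the contour, kept as corner stubs), `polygon` (shares the
square's bottom half, different top), `scrambled` (the contour cut into
eight parts, displaced to seeded random positions). `make_scene` composites
items by pixelwise maximum and returns a ground-truth table.

## Numerical choices

- **Separable dilation.** The Gaussian-weighted maximum factors over axes
  (the weight is a product of 1-D Gaussians), so the 2-D window of
  (2⌈3σ⌉+1)² terms is computed as two 1-D passes — identical result, linear
  cost.
- **Border-exact shift.** Dilation is evaluated on a frame zero-padded by
  ⌈3σ⌉ and the shift reads out of the padded frame. Dilating the unpadded
  map and translating afterward would drop window terms whose source lies
  off-grid after the shift; the padded evaluation equals the literal
  max-window definition at every pixel, borders included. The test suite
  verifies this against a brute-force term-by-term oracle.
- **Exact zeros.** The energy floor, the internal vertex threshold, and the
  zero-fill shift conventions guarantee that the geometric mean is exactly
  0.0 (not merely tiny) where a configured part is absent.
- **Determinism.** No unseeded randomness anywhere: fixtures are rendered
  from closed-form geometry (scrambled variants take an explicit seed), and
  filter evaluation is pure array arithmetic. Repeated runs are
  byte-identical.
- **Caching.** A `ResponseContext` caches the Gabor stack, thresholded
  channels, padded dilations, and vertex-filter responses per image, so a
  transform grid or a 60-filter configuration pass computes each shared
  intermediate once.

## Limitations

- Corner localization has a sub-pixel inward bias: tuples configured on the
  50 px triangle sit at ρ ≈ 49.1–49.5 px. Tests use a ±2 px tolerance.
- Configured angles are quantized by the bank's orientation grid (π/6) and
  by integer-pixel maxima; shapes whose corner bisectors fall between grid
  orientations (e.g. an axis-aligned square) are represented less crisply
  than shapes aligned with the grid, because side responses then compete
  with corner responses.
- Rotation/scale tolerance is sampled, not continuous: responses are
  equivariant only on the transform grid supplied in `InvarianceSpec`
  (within ~15% between grid points in our tests).
- Single-wavelength defaults suit the 3 px stroke width of the fixtures;
  other stroke widths need matching wavelengths.
- The pipeline operates on grayscale intensity only.
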