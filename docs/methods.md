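# Methods

## The degradation model

A reconstructed CT slice does not sample a plane: it integrates tissue over
an axial slab, weighted by the scanner's slice sensitivity profile (SSP).
`ctsim` models the SSP of a slice of thickness *t* centred at *p* as a
triangle of half-width *t*,

    g(p, l, t) = max(0, 1 − |p − l| / t),

so a thick slice synthesized from thin slices at positions *l₁ … lₙ* (mm,
patient coordinate frame) is the convex combination

    I(p) = Σᵢ g(p, lᵢ, t) · Iᵢ  /  Σᵢ g(p, lᵢ, t).

The triangular form follows the axial distance weighting of weighted
filtered back projection in helical CT; its support of ±t (rather than
±t/2) reflects that sinogram data up to a full thickness away still
contributes to a reconstructed slice. Because the weights are nonnegative
and normalized, every output voxel lies in the [min, max] envelope of its
contributing thin voxels, constants are preserved exactly, and an input
affine in z is reproduced exactly at any target position whose kernel
support is covered symmetrically — these conservation laws are enforced in
the test suite at 1e-9.

Thick-slice centres are computed in physical mm: starting from the thin
series' first slice position *s* (overridable), locations are *s + k·d* for
all *k* with *s + k·d ≤ e*, generated in closed form to avoid accumulation
drift, with a 1e-6 mm endpoint tolerance so *e* is included when (e−s)/d is
integral. Thickness *t* and interval *d* are independent parameters;
*t > d* yields overlapping slices.

### Assumptions

- Axial, non-tilted acquisitions: slice planes orthogonal to the patient z
  axis. Tilted/oblique series are rejected at load, not resampled.
- The thin slices are treated as point measurements of the anatomy at their
  centre positions when the weighted sum is formed; their own slab width is
  not deconvolved. The approximation error this causes is quantified by the
  convergence experiment below.
- All simulation happens in HU after rescale; in-plane geometry is never
  touched.

## Baselines

The three conventional simulators are deliberately index-based, including
their position misplacement, because they exist to be compared against:

- **direct downsampling** keeps slices 0, f, 2f, …;
- **simple averaging** averages non-overlapping groups of f slices and
  places the result at the group-mean position (for even f there is no
  middle index; the mean is the documented choice);
- **Gaussian averaging** applies a discrete 1-D Gaussian along the slice
  axis (kernel truncated at 4σ and renormalized; σ defaults to f/2 indices,
  a choice the cited practice leaves unstated) and then decimates by f.

None of them can place a slice at a non-integer multiple of the thin
spacing, and none can represent t ≠ d; the test suite asserts these
documented discrepancies exist for the baselines and not for the proposed
method.

## Metrics

PSNR = 20·log₁₀(MAX_I / RMSE), MSE the per-pixel mean squared difference,
RMSE its square root, SSIM the standard mean local form (11×11 Gaussian
window, σ = 1.5, K₁ = 0.01, K₂ = 0.03). Slices are matched between volumes
by physical position (greedy nearest-neighbour within a tolerance, default
0.5 mm), both volumes are clipped to an HU window — default the full
[−1024, 3071] range — and mapped to [0, 1], so MAX_I = 1; the window used
is always recorded in the report. Aggregation is per matched slice pair,
reported as mean ± sd. Identical pairs are flagged as infinite PSNR rather
than an error. A volume-level 3D SSIM is deliberately not used, and FID is
out of scope (it needs a pretrained feature extractor); the report schema
reserves an optional field for externally computed values.

One caveat: SSIM with fixed stabilizing constants is *not* invariant to the
choice of normalization window (halving the normalized intensities changes
the constants' relative size; measured effect ~1e-2 on noisy pairs). The
property that does hold, and is tested, is exact invariance when the inputs
and the window are transformed by the same affine map.

## Phantoms and the oracle

Phantom scenes are analytic HU fields — background, hard ellipsoids, smooth
Gaussian blobs, z-slabs, and an optional affine-in-z ramp — evaluable at
any continuous point, so ground truth is available at machine precision.
Four presets span the relevant content: `blobs` (smooth, for convergence),
`step_wedge` (edge-dominated z-profile), `ramp` (pure gradient),
`shepp_like` (hard-edged nested ellipsoids).

Two different forward models are used on purpose:

- **thin rendering** integrates the scene over a *boxcar* slab of width t
  (11-point uniform quadrature by default; 1 point degenerates to plane
  sampling);
- **the thick oracle** integrates the scene against the *triangular*
  profile over ±t (101-point quadrature by default, an order of magnitude
  denser than what it judges).

The simulator under test therefore has to approximate a continuous profile
it does not trivially share with the renderer. Gaussian noise is seeded and
added in HU; with thickness scaling enabled the effective σ is
σ·√(1 mm / t), modelling the higher noise of thinner slices.

### Experiment design

The fidelity and convergence experiments render the thin series with one
slice-thickness of axial padding beyond the thick-slice grid (thin extent
[s − t, e + t]). Without padding the first and last thick slices compare a
one-sided discrete sum against a two-sided continuous integral, and that
boundary bias — an artifact of the experiment, not of the method —
dominates the volume RMSE. Padding mirrors practice: acquisitions cover
slightly more anatomy than the grid being evaluated.

Problem sizes: the standard experiments use 32×32 in-plane grids at 2 mm
pixels over a 40 mm axial span (21 thick slices at d = 2 mm, t = 3 mm from
1 mm thin slices), 10 noise seeds at 15 HU thin-slice noise — small enough
to run in seconds while leaving the method ranking stable to the third
significant figure across seed choices. The convergence sweep uses thin
spacings of 1, 0.5 and 0.25 mm on the smooth `blobs` preset; the RMSE
against the oracle falls roughly fourfold per halving, consistent with the
O(h²) accuracy of the triangular weights as a trapezoid-type quadrature of
the SSP integral.

What passing these tests shows — and what it does not: the phantoms
establish that the geometry, weighting and normalization are correct and
that the method ranking holds under additive Gaussian noise on piecewise-
smooth anatomy. Real CT adds reconstruction-kernel texture, correlated
noise, motion and contrast dynamics that no analytic phantom reproduces;
absolute PSNR/RMSE values on phantoms are therefore not comparable to
values measured on clinical data, only the ordering and the convergence
behaviour are.

## Numerical choices and degenerate inputs

- Slice locations in closed form (no repeated-addition drift); endpoint
  tolerance 1e-6 mm; the literal repeated-addition loop is kept as a test
  oracle.
- Weights and accumulation in double precision; normalization once, after
  accumulation.
- A target location with zero total weight (gap in thin coverage wider than
  t) is a hard error naming the location — silently skipping would corrupt
  the output grid.
- Slice positions closer than 1e-3 mm are duplicates and rejected at load;
  overlapping reconstructions must be disambiguated upstream.
- NIfTI stores spacing, not thickness, so loading NIfTI requires the
  thickness from the caller; negative affine z-spacing is flipped to
  ascending order with the voxel data flipped consistently.
- DICOM output quantizes to signed int16 HU (slope 1, intercept 0) and
  carries thickness as Slice Thickness and the interval as Spacing Between
  Slices.

## Known limitations

- The triangular SSP is an idealization; real SSPs depend on collimation,
  pitch and reconstruction kernel and are typically bell-shaped.
- The thin slices' own slab width is not deconvolved before re-integration,
  so simulated thick slices are very slightly over-smoothed axially
  (vanishing as the thin spacing shrinks).
- In-plane resolution and noise texture are untouched: this is an axial
  degradation model only.
- Multi-frame enhanced DICOM, non-CT modalities and tilted gantries are not
  supported.
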