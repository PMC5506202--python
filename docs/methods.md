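# Methods

## Geometry and conventions

All modules share one raster frame: `x` is the column index, `y` the row
index, and angles are measured from +x toward +y. (This is the mirror image
of the usual mathematical frame; since every producer and consumer in the
package uses the same frame, all invariants — shift-twist invariance,
symmetries, fits — are unaffected, and only on-screen interpretation of
angle signs differs.) Absolute line orientations are π-periodic and
discretized as θ_k = −π/2 + kπ/n_θ, k = 0..n_θ−1. Relative-orientation axes
of kernels store layer j = relative angle jπ/n_θ, so layer 0 always means
"aligned". Kernel arrays are indexed `[Δx + d, Δy + d, layer]`.

## Orientation scores

Cake wavelets are built in the Fourier domain: 2n_θ angular wedges (a
periodized cardinal B-spline of configurable order, default 3, whose integer
shifts form an exact partition of unity) times a radial pass band —
1 minus a Gaussian DC notch (σ_dc, default 0.02 cycles/px) times an
erf-style roll-off starting at `nyquist_taper`×Nyquist. Antipodal wedges are
summed, so the filters are bi-directional (π-periodic), real and zero-mean:
a constant image produces no directional response. Because the B-spline
wedges tile the circle, the summed spectra equal 1 on the pass annulus
[8σ_dc, taper onset] to ~1e−8.

Filters are mutually rotated copies of one another up to the anisotropy of
sampling a polar construction on a square frequency grid; with the default
taper this sampling error is ~2×10⁻³ of the peak and drops below 10⁻³ when
the spectrum is resolved more generously (taper onset 0.6, σ_dc 0.03), which
is the configuration the rotation test uses.

Scores are correlations with the conjugated filters (FFT-based, reflective
padding). Vessels are darker than their background, so the dominant
orientation is the argmax over θ of the *negated* real part (a ridge
detector); ties break toward the lowest bin.

## Co-occurrence kernels

Interest points are centerline pixels (morphological thinning of the
segmentation; scikit-image `skeletonize`) carrying their dominant
orientation bin. For every ordered pair within Chebyshev distance `d`
(|Δx| ≤ d and |Δy| ≤ d — chosen so the (2d+1)² grid is exactly fillable),
the offset is rotated by −θ_ref and rounded to the nearest pixel; the
relative orientation is the bin difference mod n_θ. Because centerlines
carry no polarity, the antipodal representative (θ_ref + π ⇒ point-reflected
offset, same relative bin) is accumulated too, each at weight 1/2 — making
every accumulated kernel exactly symmetric under spatial point reflection.
Rotated offsets that leave the window are dropped, so the stored histogram
respects its bounds; this makes the pre-rotation cut the only
non-rotation-invariant ingredient (boundary pairs only, < 1% of the mass for
compact point sets). Interest-point sets may carry continuous orientations
(e.g. true tangents of synthetic paths); these are then used for the
rotation and for binning the angle *difference* directly, avoiding the
double-binning smear of bin-valued orientations.

Normalization is ℓ₁ (probability kernel). The comparison metric
`kernel_distance` is the relative ℓ₂ difference in percent,
100·‖k₁−k₂‖₂/‖k₁‖₂ (a symmetric variant normalizes by the larger norm, and
the raw ℓ₂ is exposed as `kernel_l2`); relative normalization makes the
number scale-invariant across kernels of different supports.

The intensity-similarity factor in grouping uses the normalized Gaussian
G_σ; its 1/(σ√2π) prefactor rescales the whole affinity matrix and is
irrelevant to spectral clustering, but it means raw affinity entries are not
monotone in σ_int — the σ-monotonicity property holds for the descaled
similarity exp(−ΔI²/2σ²).

## The direction process and its resolvent

The model for contour continuation is Mumford's direction process: unit
speed along the current orientation, Brownian orientation with diffusion
D33 = σ²/2 (rad²/px), exponential lifetime with decay rate α (1/px). Its
stopped law is the resolvent R_α = α(αI − A)⁻¹δ_e with
A = −cosθ∂x − sinθ∂y + D33∂θ². (As printed in some sources the stationary
PDE mixes signs; the package implements the probabilistically consistent
form, whose solution is a nonnegative probability kernel.)

**Spectral solver** (`fp_resolvent_numeric`). Fourier transform in (x, y)
makes transport diagonal per frequency; orientation is discretized with a
periodic second-difference Laplacian, giving one cyclic tridiagonal system
per spatial frequency, solved in O(n_θ) by a Thomas sweep with a
Sherman–Morrison corner correction (strictly diagonally dominant, hence
stable). Numerical choices, each load-bearing:

- *Auto-padding.* The periodic domain covers max(2 windows, 2 windows +
  6/α px) so that paths longer than the domain cannot wrap around and
  deposit spurious mass in the window (for α = 0.01 wrap-around would
  otherwise inflate the window mass by ~45%). The fine grid is capped at
  4096 points/axis; a warning is logged if the cap forces residual wrap.
- *Spatial supersampling (4×).* The resolvent contains a near-δ component at
  the origin; on a 1-px grid its truncated Fourier series rings negative at
  ~10⁻⁵ of the peak. Supersampling pushes the ringing below the 10⁻⁸
  nonnegativity floor, which the solver enforces (entries below −10⁻⁸ raise;
  anything between −10⁻⁸ and 0 is clipped).
- *Orientation oversampling (3×, box-aggregated).* With n_θ = 16 the
  sub-bin orientations inside the aligned bin carry lateral drift that a
  16-sample grid cannot represent, over-concentrating the forward ridge by
  ~2× at moderate range. The solver uses 3 samples per output bin and sums
  them — the same box binning the Monte-Carlo oracle applies to continuous
  angles. (Bin-exact symmetry identities hold exactly at
  `theta_oversample=1` and to ~10⁻³ with oversampling, since sub-bin angles
  have no grid-exact rotations.)
- *Blur.* A Gaussian of σ = `blur_s` (default 0.5 px) is applied in the
  frequency domain, standing in for the one-pixel binning of the measured
  statistics.
- Total mass on the padded domain is exactly 1 by construction (the
  transport and diffusion terms are conservative); the mass cropped away by
  the window is reported, and the kernel optionally renormalized.

**Time-domain engine** (`fp_resolvent_series`). For grid fits the cost of
padding ∝ 1/α is prohibitive. Instead K_t is evolved by Strang splitting
(exact per-frequency transport phase; the exact exponential of the same
discrete θ-Laplacian, diagonalized by the θ-DFT), a sponge near the periodic
boundary absorbs mass before it can wrap, and all requested α values
accumulate α·Σ K_t e^{−αt}Δt in a single pass, with the exponential weight
integrated exactly over each sampling window and the integration stopped
when every α's remaining tail is below 10⁻³ of its accumulated mass. K_t is
a sharp expanding front, so the time integral is sampled every step (Δt =
0.5 px default, 0.75 px in fits); coarser sampling leaves radial rings. The
engine agrees with the spectral solver to well under 2% relative ℓ₂ at the
fit settings, and its per-α cost is independent of 1/α.

**Monte-Carlo oracle** (`mc_resolvent`). Euler simulation (dt = 0.1 px) of
the process with the exact exponential lifetime (final partial step
included), endpoints binned to the pixel/orientation grid; deterministic
given the seed. For validating the PDE solver bin-for-bin,
`mc_resolvent_blurred` histograms endpoints on a 4× finer grid, applies the
same Gaussian blur as the solver, and reads the density at integer pixels —
so both routes estimate the same smoothed quantity and the comparison is not
dominated by binning mismatch. At (α = 0.01, D33 = 0.002, d = 32) the
measured relative ℓ₂ distance is ≈3.9% at 10⁶ paths, of which ≈2% is Monte-
Carlo noise.

**Projective symmetrization.** The direction process satisfies an exact
time-reversal identity: the law of the reversed process is the forward law
with velocity negated, which on kernels reads R(g⁻¹) = R(−x, −y, θ). The
four-term forward/backward + π-shift symmetrization therefore reduces to a
spatial point reflection plus a π bin-roll — both exact on the grid, mass
preserving, and the reason the symmetrized kernel's bin-level symmetries
(point symmetry, π-periodicity, inversion symmetry at grid-exact angles) are
exact rather than approximate. The π-periodic result is stored on the full
2n_θ circle; `fold()` collapses it to n_θ projective layers.

## Fitting (α, D33)

`fit_kernel` grid-searches (α, D33), building each candidate kernel with the
time-domain engine on the statistical kernel's grid, and minimizing the
percent ℓ₂ distance between the ℓ₁-normalized kernels (ties break toward
smaller α then smaller D33). Two deliberate choices:

- *Origin masking.* A statistical kernel is structurally zero at
  (Δx, Δy) = (0, 0) — two distinct pixels never produce a zero offset —
  while the model kernel's origin voxel is its single largest bin (the
  short-lifetime spike, mass ≈ α·const). Comparing a structural zero against
  the largest model bin would dominate the least-squares surface with an
  artifact, so the model's spatial-origin voxel is zeroed and the kernel
  renormalized before every comparison.
- *Default grids.* The package defaults keep the conventional endpoints
  (α ∈ [10⁻⁵, 10⁻²] ×50, D33 ∈ [10⁻⁶, 5·10⁻³] ×100, log-spaced); the
  acceptance runs use 9×9 log grids bracketing the generating values by
  ~1.8× steps, which keeps the desk-scale fit under ~4 minutes.

The recovery loop (paths → rasterized centerlines → co-occurrences → fit)
lands within one log-grid step of the generating (α, D33) with a residual
error of ≈11% relative ℓ₂. The residual is not noise (the estimator's
sampling noise at 10⁴ paths is ≈0.4%): it is the rasterization physics the
continuum model does not describe — three quantization steps of ~1/12 px²
lateral variance each (two pixel centers and the rotated-offset rounding,
emulated by blur_s = 0.5), plus the direction-dependent density of pixels
along a rasterized line (between 1 and √2 per unit length). Under a raw-ℓ₂
reading (‖ΔK‖₂×100 between ℓ₁-normalized kernels) the same residual is
≈0.4%, which is the scale on which such fits are conventionally reported.

## Synthetic data

`sample_direction_paths` draws trajectories with the same dynamics as the
Monte-Carlo oracle and rasterizes them at **unit arc spacing** before
rounding. Sampling the Euler micro-steps directly would emit boundary-
flicker duplicates (two laterally adjacent pixels where the path skims a
pixel edge) that a morphologically thinned skeleton never contains, and
which measurably fatten the co-occurrence ridge. The loop closure rests on
memorylessness: along a path with Exp(α) lifetime, the expected number of
ordered pairs at arc gap t is proportional to e^{−αt} — exactly the
resolvent's time weighting — so intra-path co-occurrences are draws from the
symmetrized resolvent.

Phantoms render anti-aliased bands (width 3 px default) of configurable mean
intensity on a bright background (0.85), with arc-length gap intervals
removed and Gaussian noise (σ = 0.02) added. Ground-truth labels partition
the foreground; overlap pixels go to the first-listed curve and are excluded
from agreement scoring. The four presets (crossing, bifurcation, parallel,
interrupted) use intensities (0.3, 0.7) so that both the orientation and the
intensity channel are informative, mirroring the situations the grouping
pipeline targets. What the phantoms do **not** emulate: realistic vessel
width variation, caliber-dependent contrast, central light reflexes, optic
disc or pathology — passing the phantom suite shows the pipeline resolves
the four junction topologies under clean conditions, not that it matches
human performance on fundus images.

## Grouping

Affinity: A(i,j) = ½(k(i→j)+k(j→i)) · G_{σ_int}(ΔI). The average of the two
lookup directions makes A exactly symmetric (a single directed lookup
already is, whenever the kernel is inversion-symmetric); the diagonal is
zero; pairs outside the kernel's spatial support get zero. Intensities are
the locally normalized values ((I−μ)/σ with Gaussian window, default scale
15 px, robust percentile rescale to [0,1]) — flat-field invariant to < 2%
under smooth bias fields at patch scale.

Self-tuning spectral clustering: symmetric normalization, top `max_groups`
eigenvectors, and per candidate count C a deterministic L-BFGS minimization
of the sparsity cost Σᵢ Σ_c Z²/max_c Z² over Givens rotation angles
(warm-started from C−1, plus fixed alternative starts; rows with no energy
in the candidate subspace are charged the worst per-row cost, so degenerate
eigenbases cannot make an under-segmented candidate look ideal). C = 1 is
included at the ideal cost; the chosen C is the largest whose cost is within
1% of the minimum, so structureless affinities collapse to one group while
exact block structure selects the block count. Zero-affinity points are
pre-assigned noise; groups below `min_size` (default max(10, 1% of m)) are
pruned.

Defaults: σ_int = 0.2, n_θ = 16, d = 65 for learned kernels (desk-scale
tests use d = 20–32), max_groups = 10.

## Problem sizes

The test-suite and acceptance runs use: 131-px wavelets; 500-point
brute-force oracles; d = 32, 10⁶ Monte-Carlo paths for solver validation;
10⁴ paths and 9×9 grids for parameter recovery; 101×101 phantoms with
~300–650 lifted pixels for grouping. These sizes were chosen so the entire
validation runs on a laptop-class single core in minutes while every
statistical tolerance retains a safety margin over its measured noise level.

## Known limitations

- The kernel comparison is plain ℓ₂ on the full grid; a weighting that
  down-weights the near-origin bins would sharpen α identifiability on
  small windows (the radial mass profile carries the α information).
- The orientation estimate is the per-pixel argmax; no sub-bin refinement,
  no multi-orientation handling at junction pixels (their affinities are
  simply noisier, which the clustering absorbs).
- The self-tuning rotation optimization is nonconvex; the deterministic
  multi-start makes it reproducible but not provably optimal.
- Artery/vein labels are consumed, never produced; segmentation quality is
  taken as given.
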