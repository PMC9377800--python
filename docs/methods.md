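# Methods

This note documents the models and procedures implemented in `myoscale`,
the parameter choices that matter, what the synthetic generators emulate,
and the numerical decisions taken where the underlying procedure admits
more than one reasonable reading.

## Orientation fields and nematic statistics

**Model.** Fiber orientation is nematic: an axis, not a vector — θ and
θ + π are the same orientation. All statistics therefore work on the
doubled angle 2θ.

**Structure tensor.** Gradients are Gaussian derivatives at an inner scale
of 1 px; the tensor components ⟨g²ₓ⟩, ⟨gₓg_y⟩, ⟨g²_y⟩ are averaged with a
Gaussian window of σ = 10 px (the scale of one fiber width at ×10
magnification) and sampled at the center of each 100 px grid block (one
orientation per block, matching the coarse vector-field grids used for
culture-scale maps). The reported angle is the eigenvector of the smaller
eigenvalue — along the texture ridges, perpendicular to the dominant
gradient. Cells whose tensor trace falls below 10⁻³ of the image-wide mean
trace carry no orientation signal and are masked invalid; all pair
statistics are restricted to valid cells. Angle convention: 0 along the
image x-axis, counter-clockwise positive with y up, range [−π/2, π/2).

**C(d) and η_L.** Distances between grid cells are exact Euclidean
distance classes (rounded at 10⁻⁶ grid units — on a regular grid the
realised distances are a discrete set, so no binning is needed), up to
half the grid diagonal by default.
`C(d) = 2⟨cos²Δθ⟩ − 1 ≡ ⟨cos 2Δθ⟩`; the implementation uses the
doubled-angle unit-vector dot product and the test suite checks the
identity to 10⁻¹². η_L fits an ordinary-least-squares line to the leading
points with C ≥ 0.5 (minimum two points) and returns its x-intercept.
"Initial linear decay" is not otherwise operationalised; the 0.5 floor
keeps the fit in the near-linear regime and is exposed in configuration.
η_L is undefined (None) when the curve never falls below the floor (a
uniform field) or the fitted slope is non-negative.

**S and disorder.** S is computed over non-overlapping 4×4-cell windows
from the valid cells only; trailing cells that do not fill a window are
dropped. The disorder fraction counts unmasked windows with S < 0.5. For n
i.i.d. uniform nematic angles E[S²] = 1/n, which the suite verifies by
Monte Carlo at n = 16.

## Bundle clustering

The symmetric Hausdorff distance
`max(h(A→B), h(B→A))`, `h(A→B) = max_{a∈A} min_{b∈B} |a−b|`, is computed
after resampling each polyline to uniform 1 µm arc-length spacing, so the
distance measures geometry rather than hand-tracing vertex density (raw
mode is available). Grouping is single linkage at a hard threshold: the
connected components of the graph with edges at distance < t. This is the
unique transitive closure of the pairwise rule "below threshold ⇒ same
bundle". Thresholds are dataset-specific (tuned per time point against
visual inspection in the original workflow) and therefore required
configuration; the CLI offers a threshold sweep to support that tuning.
Bundle area is the convex-hull area (shapely) of the union of member
points; hulls of fewer than three distinct points have area 0. Labels are
deterministic, ordered by each bundle's smallest member trace id.

## Straightening and periodicity

**Straightening.** Stage 1 resamples the volume along the manual xy path
at one-pixel arc-length steps with transverse sampling lines (bilinear
interpolation, width 2·half_width + 1), giving an (s, w, z) block. Stage
2, when an xz path is supplied, refines depth: the block is resampled
along the (s, z) spline with transverse samples strictly along z, so the
stage-1 arc-length axis is preserved. The profile is the arithmetic mean
over all transverse axes at uniform spacing equal to the xy pixel size. A
path that leaves the (widened) volume is an error, not clamped.

**ACF.** Mean-subtracted, biased (1/N) estimator normalised at lag 0, so
acf(0) = 1 and values taper with lag; an unbiased variant is switchable.
The secondary peak is the most prominent local maximum at lag ≥ 1 µm
(configurable) — "most prominent" rather than "first" avoids half-period
harmonics and tiny-lag noise; prominence is the standard topographic
definition (scipy). Constant windows have no ACF and are flagged, never
periodic.

**Local map and regions.** Windows of 10 µm (~5 sarcomeres) advance by the
whole-sample step nearest 0.083 µm (one sample at the ×100 pixel size);
a window is periodic when its secondary-peak prominence exceeds 0.6.
Runs of periodic windows span first to last window center. Regions are
merged first (gaps < 10 µm connected) and discarded second (< 6 µm
dropped): merging first lets fragments combine into a region long enough
to survive, which matches the stated intent of discarding noise while
connecting neighbouring regions; the opposite order is implemented and
selectable. The rules are idempotent on their own output. The classifier's
domain is the span of window centers: the first and last half-window of a
profile contain no window center and are not classified; evaluation
against ground truth is restricted to that domain.

**Metrics.** Proportion periodic = total region length / fiber length;
regions per 100 µm; mean region length; homogeneity = standard deviation
(population) of periodic-window center positions, reported both raw (µm)
and divided by fiber length, since it is unstated whether the original
score was length-normalised. With no periodic window the homogeneity is
NaN, not 0.

## Recoil mechanics

v₀ is the OLS slope of L against t over t ≤ 1 s. The viscoelastic fit is
bounded nonlinear least squares (scipy trf) over (L0, ΔL = Lmax − L0 ≥ 0,
τ > 0) with deterministic data-driven initialisation: L0 from the first
sample, Lmax from the last, τ from the 63%-rise crossing time (fallback:
half the record). Reported per track: parameters, residual sum of squares,
model-implied initial velocity ΔL/τ, a convergence flag and a reliability
flag (τ within the record duration — a longer τ means no plateau was
observed and the asymptote is extrapolated). Fitting applies per track by
default; a mean-curve mode (tracks interpolated to a common time base and
averaged before fitting) is provided because noisy individual curves are
sometimes summarised that way. Exclusion of actively contracting fibers is
the caller's responsibility via the `exclude` metadata flag. Category
summaries report mean ± sd and median ± IQR.

## Morphometrics

Trace length is the polyline segment sum. Width is the Euclidean length of
a manual perpendicular segment (the segment *is* the measurement). Line
profiles resample the trace at one-pixel arc steps, interpolate bilinearly
across a perpendicular width (e.g. 50 px ≈ 4 µm for marker-level
quantification on 5 µm maximum projections) and also return the whole-
profile mean intensity. Nuclei are local maxima strictly above a threshold,
plateaus counted once at their center, maxima closer than a minimum
separation merged keeping the higher.

**Nuclei detector calibration.** The intensity threshold is dataset-
specific by nature; on the synthetic profiles it is set midway between
background and the peak plateau (background + 0.6 × amplitude), and the
minimum separation to the ~10 µm nuclear diameter — below the generator's
enforced 15 µm packing gap, so true nuclei are never merged, while
noise-induced secondary maxima on a nucleus flank are. With that
calibration, exact count recovery is 100% for 1–30 planted nuclei at the
default SNR.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
the optics of microscopy (no PSF model beyond Gaussian smoothing, no shot
noise, no photobleaching); passing tests therefore demonstrate
correctness of the computations and recoverability under the assumed
structure, not robustness to every real-world artefact.

- **Orientation textures**: a complex Gaussian white-noise field of the
  doubled angle, low-pass filtered at the requested correlation length
  (infinite length gives a uniform field); fiber strokes are streamlines
  integrated tangent to the field (sign-continuous through the nematic
  identification), blurred to the fiber width, plus additive noise. The
  analytic field is returned as ground truth. Defaults (512² px, 800
  strokes, 2 µm width) give dense coverage like a confluent culture.
- **Trace sets**: bundles of near-parallel polylines bowing between two
  shared end foci, stacked so that within-bundle Hausdorff < 2 × spread
  and between-bundle Hausdorff > half the inter-bundle distance; both
  bounds are *verified at generation time* and recorded, so any threshold
  inside the measured gap must recover the planted partition exactly.
- **Periodic profiles**: Gaussian-peak trains (peak σ = period/8, the
  punctate Z-disc appearance) at a 2 µm default period with 10% amplitude
  noise; noise segments are i.i.d. samples matched to the mean and total
  variance of an equivalent periodic segment, so intensity statistics
  alone cannot separate the classes — only the ACF can.
- **Recoil tracks**: the asymptotic model (defaults L0 = 0, Lmax = 5 µm,
  τ = 1 s, 0.1 s sampling over 5 s — the scale of manual tracking records)
  plus Gaussian noise, clipped at zero separation.
- **Nuclei profiles**: Gaussian bumps (σ = 3 µm) with an exact
  minimum-gap placement (spacing transform, no rejection sampling) on a
  flat background; noise is smoothed at a 1 µm optical scale and rescaled,
  default SNR 10 — typical of the high-contrast DAPI channel.

All generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`; every output carries a `SyntheticTruth`
sidecar with generator name, parameters (including measured guarantees)
and seed.

## Problem sizes and numerical notes

The test suite exercises orientation statistics on 512² px images with a
16 px grid and σ = 8 px (the same σ/grid ratio as the 100 px production
grid, at a size where a correlation-length sweep of 5 values × 20
replicates completes quickly); the monotone-recovery test uses common
random numbers across the sweep — the same white-noise field filtered at
each length — which makes the per-replicate η_L curves strongly
positively correlated and the rank test sharp. η_L estimation is reliable
while C(d) decays below the 0.5 floor inside the sampled distance range;
for 512² images that holds for correlation lengths up to roughly 150 px,
and the acceptance script measures η_L at 75 px for that reason.

Floating-point outputs are written with a `%.10g` format, which
round-trips the quantities of interest to 10⁻⁹ and makes repeated runs
byte-identical. Degenerate inputs (constant profiles, all-masked windows,
zero-variance tracks, collinear hulls) are flagged or return NaN/None
explicitly rather than raising, except where the input violates a stated
precondition.

## Known limitations

- No automatic fiber tracing, foci detection or contraction detection:
  traces, foci and exclusion flags are manual inputs, as in the original
  workflow.
- The straightening assumes isotropic xy sampling and treats the stage-2
  arc length in index units; for strongly z-sloped paths with anisotropic
  voxels the physical sample spacing deviates slightly from the xy pixel
  size.
- Hausdorff clustering is O(n²) in trace pairs; tens of thousands of
  traces per condition are feasible but benefit from per-timepoint
  partitioning before clustering.
- The four morphological categories (myotube, immature, transitional,
  mature) are consumed as labels only; no classifier is provided.
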