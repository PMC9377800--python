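# myoscale

Quantification of multi-scale self-organisation in cultured human muscle
fibers. When myogenic precursors differentiate in 2D culture, myotubes
elongate, co-align, merge into large attached bundles, build up mechanical
tension and finally assemble periodic sarcomeres. `myoscale` implements the
image-quantification methods used to measure each of those scales from
fluorescence microscopy, together with a synthetic-data generator that
produces every input with known ground truth.

## What it measures

**Tissue scale — nematic orientation statistics** (`myoscale.orientation`).
A fiber-texture image is reduced to a grid of local orientations θ(**r**)
via the structure tensor (Gaussian-derivative gradients, tensor smoothing
σ = 10 px, one angle per 100 px grid block by default). The grid is
summarised by

- the spatial correlation `C(d) = 2⟨cos²(θ(r) − θ(r+d))⟩ − 1`, averaged
  over all grid-point pairs at distance `d`;
- the nematic length `η_L`: the x-intercept of the initial linear decay of
  `C(d)` — the size of co-aligned domains;
- the local nematic order
  `S = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²)` over 4×4-cell windows, and the fraction
  of disorder: windows with `S < 0.5`.

**Tissue scale — bundle clustering** (`myoscale.bundles`). Manually traced
fiber polylines are grouped into bundles: pairs with symmetric Hausdorff
distance below a threshold are linked, bundles are the connected components,
and each bundle is summarised by the convex-hull area of its member points.
Attachment foci are consumed as manual point lists and counted.

**Sarcomere scale — periodicity mapping** (`myoscale.periodicity`). A traced
myofibril is straightened (xy, then optionally xz) and collapsed to a 1D
titin intensity profile. The autocorrelation function's secondary peak gives
the sarcomere period (≈ 2 µm) and its topographic prominence the pattern
regularity. A sliding-window ACF (10 µm windows, 0.083 µm steps, prominence
> 0.6) maps periodicity along the fiber; runs of periodic windows become
regions (gaps < 10 µm connected, regions < 6 µm discarded), and per-fiber
metrics report the periodic proportion, regions per 100 µm, mean region
length and a homogeneity score.

**Mechanics — ablation recoil** (`myoscale.recoil`). After laser severing,
the separation of the cut ends follows the asymptotic viscoelastic model
`L(t) = Lmax − (Lmax − L0)·e^(−t/τ)`. The first-second linear slope gives
the initial recoil velocity v₀ (a pre-cut tension proxy) and bounded
nonlinear least squares gives the relaxation time τ (viscosity over elastic
modulus).

**Cell scale — morphometrics** (`myoscale.morphometrics`). Polyline fiber
lengths, manual perpendicular-segment widths, nuclei counts from local
maxima of DAPI intensity along traces, and wide-line mean-intensity
quantification of marker channels.

## Worked example

```bash
python examples/sarcomere_periodicity_demo.py
```

```
profile length:            99.9 um (1205 samples)
global ACF period:         1.992 um (sarcomere length; truth 2.0)
global peak prominence:    1.12 (pattern regularity)
periodic regions:          2 at [(4.9, 39.6), (66.4, 95.0)]
proportion periodic:       0.63 (truth 0.75 of the fiber)
homogeneity score:         30.5 um (std of periodic window positions)
```

The demo builds a 100 µm profile with two periodic stretches (Gaussian-peak
trains at the 2 µm sarcomere period) separated by matched-variance noise.
The global ACF recovers the period to within one sample; the local map
classifies the two stretches as distinct regions (their 25 µm separation
exceeds the 10 µm merge rule) covering 63% of the fiber — less than the
planted 75% because region extent is measured between window centers, so
each region loses about half a window at its ends.

The other scripts in `examples/` demonstrate orientation statistics, bundle
clustering, recoil fitting, nuclei counting and the end-to-end pipeline;
each prints the numbers it computes and what they mean.

A `myoscale` command-line tool wraps the same library for shell use
(`myoscale orient|bundles|periodicity|recoil|morpho|simulate|run`, see
`myoscale --help`); `myoscale run --config cfg.yaml` executes configured
stages end to end and writes a reproducibility manifest.

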