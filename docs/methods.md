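# Methods

This note records the model, the numerical choices, and the open design
decisions behind `fats`, in the order the pipeline applies them.

## Adaptive local Gaussian-mean binarisation

For each channel a `z × z` Gaussian kernel is built with

    G(x, y) = α · exp(−(x² + y²) / (2σ²)),   σ = 0.3·((z − 1)/2 − 1) + 0.8,

`α` normalising the kernel to unit sum.  The threshold field `T` is the
correlation of the unit-sum kernel with the image — the Gaussian-weighted
local mean — minus a constant `offset` (default 0).  A pixel is
foreground (255) iff its value strictly exceeds `T`; the alphabet of the
mask is exactly {0, 255}.  Because the comparison is against the local
mean, only pixels that stand proud of their own neighbourhood fire;
smooth background of any brightness cancels.

Numerical choices:

- Computation in float64; the threshold field is never re-quantised.
- Strict `>` is guarded by a 1e-6 tie tolerance: the kernel's floating
  sum is 1 within ~1e-16, so the weighted mean of a perfectly flat
  region lands within ~1e-13 of the pixel value and must not count as
  "exceeds".  Flat images therefore yield empty masks, which is the
  intended contract.
- Borders are handled by replicate-edge padding.  The convolution is run
  as two 1-D passes; with replicate padding this is exactly equal to the
  full 2-D correlation of the padded image, so the separable form is a
  speed choice, not an approximation.
- The strict local-mean comparison marks ~half the pixels of any noisy
  flat region as foreground (every pixel a hair above its local mean
  fires).  The `offset` knob exists for this: `T = mean − offset`, so a
  **negative** offset of a few noise standard deviations raises the
  threshold and suppresses flecking.  The default stays 0 to keep the
  pure local-mean behaviour; the synthetic benchmarks run at −10 on
  8-bit data with noise SD 3.
- Kernel sizes are physical.  `kernel_size_px` rounds `size_um / pitch`
  to the nearest odd integer ≥ 3 (even results bump up).  Defaults:
  33 µm for nuclei, 66 µm for lipid — two to three times a nucleus
  group, which is where detection empirically works best.  Pixel pitch
  at or above 2 µm/pixel triggers a warning (resolution is then marginal
  for droplet-scale structure) but processing continues.

## Colour unmixing (Oil Red O + haematoxylin)

RGB bright-field images are converted by bias differences: lipid =
`max(0, R − max(G, B))`, nuclei = `max(0, B − max(R, G))`.  Subtracting
the max of the other two channels makes neutral background cancel
exactly and attenuates both biases where red and blue co-occur, which is
why colorimetric scores run at or below their fluorescence counterparts
— the attenuation behaviour the synthetic ORO renderer exercises with
its `overlap` coefficient (at overlap 1 the biases vanish entirely).
Optical-density stain deconvolution is intentionally not used; the
pipeline's contract is the RGB-space difference image.  Users who want
Beer–Lambert stain separation can apply scikit-image's
`separate_stains` upstream and feed the result in as fluorescence
channels.

## Nucleus detection

1. **Clump guard.**  Connected components of the binarised nuclei mask
   larger than `max_component_area_um2` (default 5000 µm²) are removed
   before any splitting.  A saturated multilayer clump binarises to a
   thick ring (its flat interior cannot exceed the local mean) of many
   thousands of µm²; running the watershed first would shred that ring
   into nucleus-sized fragments that pass the per-nucleus filters.  The
   coarse bound sits far above any resolvable fused group of true
   nuclei, so ordinary touching nuclei are unaffected.
2. **Watershed splitting.**  Touching nuclei are split by a watershed on
   the negated Euclidean distance transform.  Seeds are distance-
   transform maxima at least `min_seed_distance_um` apart (default 6 µm,
   about one nucleus radius — larger values under-split, smaller values
   over-split) and at least half that distance away from background, so
   thin bridges and debris ridges cannot seed.  One-pixel cuts are laid
   along watershed lines; a component in which no seed survives is
   returned untouched rather than dropped.  Seed ordering is raster-
   deterministic, so masks are reproducible.
3. **Labelling** uses 8-connectivity, labels 1..N in raster order of
   each component's first pixel.
4. **Filters** annotate rather than delete: area below `min_area_um2`
   (default 20 µm²) → `too_small` (dead cells, debris); above
   `max_area_um2` (default 500 µm²) → `too_large`; aspect ratio
   (major/minor axis from second moments; infinite for 1-px-wide
   regions) above `max_aspect_ratio` (default 3) → `misshapen`.  The
   bounds are engineering defaults for mammalian nuclei (~7–12 µm
   across), config-overridable, and the shape filter runs after
   splitting.  Downstream scoring consumes only `kept` regions, and the
   per-field exclusion counts are reported, because what is *not*
   counted (dead cells, clumps) is the point of these stages.

## Per-cell scoring and aggregation

The search region of a kept nucleus is its bounding box dilated by
`search_radius_um` (default 3 µm — the distance that balances false
positives and negatives at high density) on every side, clipped to the
image.  Then

    P_T = (lipid-mask foreground pixels in region) / (region area)
    I_s = mean lipid intensity over those foreground pixels (0 if none)
    S   = P_T · I_s

`I_s` as a mean (not a sum) keeps `S` bounded by the bit-depth maximum
and independent of nucleus size, so a single gate value works across
cell sizes; a `sum` mode is available (`score.intensity_mode`).  The
denominator of `P_T` is the full dilated box, nucleus pixels included.
Search regions of neighbouring cells may overlap and double-count
droplets; droplets are tied to nuclei by proximity only, with no
exclusive assignment.

A cell is **differentiated** iff `S` strictly exceeds the gate
threshold.  Lipid scores are arbitrary fluorescence units, so no
universal gate constant exists: the gate is either set explicitly or
derived from designated undifferentiated control wells as mean + 2 SD
of their scores.  Wells pool nuclei across fields by concatenation (a
field carries no weight of its own), report
`adipogenic_score = 100 · differentiated/total`, the mean of `S`, and a
50-bin histogram over [0, max S] (presentation only).  A well with zero
nuclei is flagged invalid and its score reported as missing, never 0.
Screening mode subtracts the mean control adipogenic score and ranks
wells by the delta in percentage points.

## Droplet sizing

Slowly varying background is removed by subtracting a large-window
Gaussian smooth (same kernel machinery; window default 4× the largest
droplet diameter — below 2× the droplets themselves are attenuated and
a warning is raised).  Edges are gradient-magnitude pixels above a
percentile of the nonzero gradients (default 90th; sparse clean fields
warrant a higher cut, and the benchmarks use 99.5 on noisy 20-disc
fields).  A circular Hough transform votes over the configured radius
range (integer pixel radii; the minimum must be ≥ 1 px at the current
pitch); peaks above `sensitivity ×` the accumulator maximum survive,
then a greedy non-maximum suppression removes any weaker circle whose
centre lies within a kept circle — small circles fitted to arcs of a
larger one are duplicates, not droplets.  Heavily overlapping droplets
are not deconvolved and under-count; the method targets monolayer
cultures.

## Synthetic scenes

`fats.synthetic.generate_scene` renders, deterministically in its seed:
elliptical nuclei (radius 5 ± 0.8 µm, elongation up to 1.5×) placed by
rejection sampling with a 3 µm boundary clearance; for each
differentiated cell (exactly `round(fraction · n)` of them) a cluster
of anti-aliased droplet discs (radius 1.2 ± 0.3 µm, ≥ 4 per cell,
Poisson mean 12) confined to the nucleus's 3 µm-dilated bounding box so
the default search radius can see every droplet; background = base 30 +
horizontal gradient 10 + three smooth blotches of amplitude 8;
optional thin sub-minimum-area crescents as dead cells; an optional
disc saturated to 255 in both channels as an embryoid-body clump (cells
are placed outside it — a clump is a 3-D structure sitting on the
monolayer); and additive Gaussian noise (SD 3).  `render_oro` converts
a scene to subtractive RGB with a purple bleed on nuclei and an
`overlap` coefficient blending both stains toward grey.

Not modelled: optical PSF, shot noise, focus drift, intra-nucleus
texture, vignetting.  Passing benchmarks on these scenes demonstrates
algorithmic correctness and robustness to the modelled confounders
(background, clumps, dead cells, channel overlap), not instrument-level
performance on real cultures.

## Benchmark conditions and what they show

`fats.evaluation` fixes the study conditions: 1024 × 1024 px fields at
0.65 µm/pixel, 200 nuclei per well, binarisation offset −10, gate 5.0
(between the residual scores of undifferentiated cells, < 1, and
droplet-bearing cells, > 10, in this intensity regime).  Under them the
pipeline recovers planted differentiated fractions {0, ¼, ½, ¾, 1}
within ~1 percentage point (exactly at the endpoints); a clump
saturating 10 % of the field moves the adipogenic score by ≤ 1 point
while a bulk-intensity readout moves by > 50 %; no planted dead cell is
ever counted; the ORO path tracks fluorescence within a few points from
below; and 20-disc Hough benchmarks reach recall 1.0 with radius MAE
well under 1 px.  `scripts/acceptance.py` recomputes all of these; the
field and well sizes were chosen as representative single-field wells,
and nothing in the benchmarks reads data from disk.

## Known limitations

- The gate threshold is assay-specific; cross-plate comparability
  requires shared controls (no B-score/Z′ normalisation layer yet).
- `P_T`'s denominator includes the nucleus's own pixels; scores are not
  comparable with definitions that use cytoplasm-only area.
- No per-cell droplet assignment (needs a cell-surface stain) and no
  droplet deconvolution in dense clusters.
- 12-bit data in 16-bit containers is used as-is; only the relative
  thresholding is scale-free, absolute lipid scores are not comparable
  across bit depths.
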