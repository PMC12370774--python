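# Methods

`tensiomap` quantifies the mechanical state of fibronectin fibers in
multichannel fluorescence images of microthrombi and relates platelet
positions to it. This note documents the models, the conventions the
implementation fixes where the underlying experimental workflow leaves
them open, the synthetic-data model used for validation, and the known
limitations.

## Biological setting and measurement model

Fibronectin fibers in tissue can be mechanically stretched (tensed) or
relaxed (untensed). A polyclonal fibronectin antibody (channel `FN`)
stains all fibers regardless of strain; the peptide tension probe
Cy5-FnBPA5 (channel `FNBPA5`) binds untensed fibers with nM affinity and
loses binding as fibers stretch, because stretching disrupts its
multivalent binding motif. A pixel that is positive in both channels is
therefore an untensed fiber pixel; a fiber pixel negative for the probe
is treated as stretched. CD31 marks platelets (and also endothelium and
some leukocytes); DAPI-negativity distinguishes anucleate platelets from
nucleated CD31+ cells.

Two readouts summarise a field of view:

- **Untensed-pixel density** (`ratiometrics`):
  `100 · |FNBPA5+ ∧ FN+| / |FN+|`, the percentage of fibronectin-positive
  pixels that are also probe-positive. The numerator is restricted to the
  FN-positive universe so the statistic is bounded in [0, 100] and reads
  as "share of all fibronectin fiber pixels"; an unrestricted numerator
  could exceed 100% through probe-positive pixels off the fiber mask.
- **Platelet proximity** (`proximity`): for each platelet centroid, the
  Euclidean distance (µm) to the nearest untensed and nearest stretched
  pixel, plus contact percentages and mean distances per image. A
  platelet may be in contact with both classes at once, so the two
  contact percentages need not sum to 100.

## Pixel-level conventions

These are fixed package-wide and deliberately explicit, because the
readouts are counts of thresholded pixels:

- Coordinates are 0-based `(row, col)`; pixel centers sit at integer
  coordinates; physical distance = pixel distance × `pixel_size_um`.
- "Positive" always means intensity **strictly greater** than the
  threshold.
- Otsu's method maximizes between-class variance over a 256-bin histogram
  spanning the observed min–max; the returned threshold is an interior
  bin edge; ties break toward the lowest bin. The argmax is resolved in
  exact integer arithmetic for near-tied splits (uniform-ish histograms
  produce splits whose variances agree to 1 ulp, where float rounding
  would otherwise make the winner platform-dependent). Thresholds are
  per-image; nothing in the pipeline shares thresholds across images.
- The ratio map divides background-subtracted probe by antibody
  intensity on the joint mask only; the denominator is floored at
  10⁻⁶ of the FN dynamic range to keep the map finite. Background is a
  single scalar (default 0) — no local background estimation.
- Distance transforms are exact Euclidean (pixel-center to
  pixel-center); sub-pixel centroids sample the distance grid by
  bilinear interpolation (error bounded by half a pixel diagonal;
  nearest-pixel sampling is available by flag).

## Pixel classification (untensed vs. stretched)

The supervised classifier mirrors an annotate-train-apply workflow: a
random forest (100 trees, fixed seed) over multiscale per-pixel features
— raw intensity, Gaussian-smoothed intensity, gradient magnitude and
Laplacian at σ ∈ {1, 2, 4} px, for the `FNBPA5` and `FN` channels — is
trained on sparse positive (untensed) / negative annotations, with a
stratified 20% pixel holdout reported. Applying the model is restricted
to the FN-positive universe: `untensed = forest-positive ∧ fn_mask`,
`stretched = fn_mask ∧ ¬untensed`. Complementing within the fiber mask
(rather than taking all probe-negative pixels) prevents background from
counting as stretched fiber; the two masks partition the fiber universe
by construction.

A non-learned baseline — Otsu on the probe channel restricted to the
fiber mask — serves as a floor: on synthetic scenes the forest must never
perform worse. The probability threshold defaults to 0.5 (configurable);
there is no canonical operating point for this task.

## Platelet detection and gating

CD31 segmentation is Gaussian smoothing (σ = 1 px) → Otsu → 8-connected
components → watershed splitting of touching blobs (markers at distance-
transform peaks ≥ 3 px apart) → area filter. Area bounds default to
1–20 µm², the platelet scale; they are prominent configuration items.
Centroids are CD31-intensity-weighted (sub-pixel). A guard refuses to
"detect" objects when the Otsu foreground exceeds 25% of the field:
stains of micron-scale objects cover a small minority of pixels, whereas
Otsu applied to a signal-free (noise-only) channel splits near the
distribution center and marks 30–50% of pixels positive. (An Otsu
separability criterion was considered and rejected: sparse bright
objects yield *lower* between-class/total-variance ratios than pure
Gaussian noise, so separability cannot distinguish the two cases.)

Gating uses the fraction of each object's pixels inside the Otsu DAPI
mask; `is_platelet ⇔ overlap < 0.1`. Area overlap is robust to
nucleus/membrane offsets, unlike a centroid-in-nucleus rule. Without a
usable DAPI channel, gating is skipped with a warning and objects are
flagged ungated.

## Contact rule

"In contact" is not self-defining for centroid-to-pixel distances, since
a platelet touching a fiber still has a centroid one radius away. The
default rule is `distance ≤ equivalent_radius + ½·pixel`: a centroid
within its own equivalent-disk radius of a target pixel implies the
object overlaps the target. A fixed tolerance (`--contact-um`) is
available for sensitivity analyses.

## Statistics pathway

Group comparisons follow a normality-battery-then-test design. Four
normality tests are run per sample: D'Agostino–Pearson, Anderson–Darling,
Shapiro–Wilk, and Kolmogorov–Smirnov in its Lilliefors-corrected form
(population parameters are estimated from the sample, so the classical
KS null is wrong). The verdict is parametric when ≥ 3 of 4 tests fail to
reject at α = 0.05; majority voting keeps one oversensitive test (KS at
large n) from forcing the non-parametric branch, and an all-4 rule is
available. Samples with n < 8 or zero variance are non-parametric by
fiat, with a warning.

Two parametric groups are compared with the pooled-variance unpaired t
test (Welch by flag); otherwise the two-sided Mann–Whitney test is used:
exact, via the classical counting recursion over the U null
distribution, when the pooled sample is tie-free with n ≤ 20, and the
normal approximation with tie correction otherwise. Stars: * < 0.05,
** < 0.01, *** < 0.001. Simulation places the full pathway's type-I
error at the nominal 5% level (see the acceptance tests).

When the pipeline runs over several images, the comparison unit is the
per-image mean distance (one dot per image/microthrombus), not the
pooled per-platelet records, avoiding pseudo-replication.

## Synthetic scene model

The generator produces the ground truth every stage is validated
against. It emulates:

- **Fibers**: dilated random-walk polylines (step 2 px, heading jitter
  0.25 rad, exponential length, mean 100 px, width ~3 px ≈ 1.5 µm at the
  default 0.5 µm pixels) — curvilinear, crossing, partially bundled.
- **Tension labels**: a Gaussian random field smoothed to a correlation
  scale of `patchiness_um` (default 8 µm) is thresholded *by quantile*
  over the fiber pixels, so the realized untensed fraction equals
  `untensed_fraction` to the nearest pixel. Labels therefore form
  spatial patches, as in real microthrombi, rather than i.i.d. pixels;
  the fraction is exactly recoverable ground truth. Defaults encode the
  measured study conditions: `untensed_fraction = 0.4`,
  `contact_fraction = 0.8`.
- **Objects**: platelets are CD31+ disks (radius 1 µm, area ≈ 3 µm²);
  nucleated cells are CD31+ disks of radius 2 µm with a 1.5 µm DAPI+
  nucleus. `round(contact_fraction · n_platelets)` platelets are seeded
  within one pixel of a stretched fiber pixel. The remainder are placed
  at nearest-stretched-pixel distances drawn as `d₀ + Exp(mean − d₀)`
  with `d₀ = platelet_radius + 3 px`: the shift keeps the sample mean at
  `offset_distance_um` (default 4 µm) while guaranteeing that every
  "non-contact" platelet really is beyond the contact rule plus the
  mask-resolution slack — an unshifted exponential with a µm-scale mean
  would put a large share of nominally non-contact platelets inside the
  contact threshold, making the contact fraction unrecoverable by
  construction. Centroids keep ≥ 3 px of clearance between disk edges
  (rejection sampling with a bounded retry budget), which also keeps
  blobs separable by the detector.
- **Rendering**: `FN` = all fiber pixels, `FNBPA5` = untensed pixels
  only, `CD31` = all object disks, `DAPI` = nuclei only; Gaussian PSF
  (default σ = 0.5 px, the sub-pixel blur of confocal imaging at
  ~0.5 µm sampling); constant background (10 photons); Poisson shot
  noise plus Gaussian read noise (σ = 2 counts). The peak amplitude N
  solves N² / snr² = N + σ_r², so peak over total noise s.d. equals
  `snr` (default 10); `snr = inf` renders noiselessly. Output is
  quantized to the 16-bit range.

Reproducibility: one scene seed derives independent per-stage RNG
streams (fibers, placement, rendering), so identical parameters give
identical scenes bit-for-bit.

What the simulator does **not** emulate: out-of-focus light and 3-D
sectioning, spatially varying background and autofluorescence, spectral
bleed-through, fiber-intensity variation with strain, platelet shape
change/aggregation, and imaging artifacts (stitching seams, saturation).
Passing the recovery tests therefore shows the analysis is correct and
well-calibrated *under the stated image-formation model*, not that it is
robust to every property of real cryosection images.

## Numerical and I/O choices

- Otsu near-tie resolution in exact integer arithmetic (above).
- The exact Mann–Whitney p uses the counting recursion
  `c(n₁,n₂,u) = c(n₁−1,n₂,u−n₂) + c(n₁,n₂−1,u)`;
  p = min(1, 2·min(P(U≤u), P(U≥u))).
- OME-TIFF is written with named channels and physical pixel size. The
  OME writer embeds a fresh UUID per file, so determinism of artifacts
  is defined (and tested) over canonical content — pixel bytes plus
  essential metadata — not raw file bytes; CSV/PNG/JSON artifacts are
  byte-reproducible and hashed raw.
- Pipeline reports contain no timestamps (they live in the run
  manifest), so identical config + inputs reproduce the report exactly.
- Undefined distances (an absent tension class) are reported as NaN,
  excluded from means, and counted in QC columns — never imputed.

## Validation problem sizes

The test suite validates on 256×256-pixel scenes (128×128 µm at 0.5 µm
pixels) with ~10⁴–1.3·10⁴ fiber pixels and 50 platelets per scene: 10
seeds per grid point over untensed fractions {0.1, 0.25, 0.4, 0.6, 0.8}
and contact fractions {0.2, 0.5, 0.8}, chosen as the smallest fields
that hold enough fiber pixels and platelets for the stated recovery
tolerances to be meaningful. The statistics pathway is calibrated with
2,000 same-distribution replicates (n = 20 per group).

## Known limitations

- Stretched fibers are defined by probe-negativity within the fiber
  mask; true intermediate strains are dichotomized. No absolute strain
  is estimated (that would need a calibrated FRET-type probe).
- Whether distances should be measured from the platelet centroid or
  boundary is a modeling choice; the centroid convention is implemented
  because that is what the upstream cell-detection workflow reports.
  Boundary distances would be shorter by roughly one platelet radius.
- Per-image Otsu thresholds adapt to staining intensity but make
  densities comparable across images only under similar acquisition
  settings.
- The detector is tuned for sparse, roughly convex blobs at the platelet
  scale; dense platelet aggregates beyond the watershed's resolving
  power are counted as single objects.
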