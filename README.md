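# tensiomap

Quantifying the tensional state of fibronectin fibers in microthrombi —
and where platelets sit relative to it — from multichannel fluorescence
images.

## The problem

Fibronectin fibers in the extracellular matrix can be mechanically
stretched (tensed) or relaxed (untensed). The peptide probe FnBPA5 binds
untensed fibers with nM affinity and loses binding when fibers are
stretched, so co-staining with a Cy5-FnBPA5 conjugate and a polyclonal
fibronectin antibody turns fiber tension into a two-channel pixel
readout. In micron-scale thrombi (microthrombi), the share of relaxed
fibronectin and the spatial relationship between platelets and fiber
tension are informative readouts for thrombus biology and for
tension-targeted detection strategies.

`tensiomap` implements that image analysis as a tested, reusable Python
pipeline for researchers working with immunofluorescence sections:

- **Ratiometrics** — per-channel Otsu thresholds, the joint
  FN+ ∧ FNBPA5+ mask, the per-pixel FNBPA5/FN ratio map, and the
  *untensed-pixel density*
  `100 · |FNBPA5+ ∧ FN+| / |FN+|` (percent of fibronectin-positive
  pixels that are probe-positive).
- **Pixel classification** — a random-forest classifier over multiscale
  intensity features (plus a non-learned Otsu baseline) that partitions
  the fiber mask into untensed and stretched pixels.
- **Platelet detection** — CD31 blob segmentation with watershed
  splitting and area gating, then DAPI-overlap gating to separate
  anucleate platelets from nucleated CD31+ cells.
- **Proximity statistics** — exact Euclidean distance transforms give
  each platelet's centroid distance (µm) to the nearest untensed and
  nearest stretched pixel, contact percentages and per-image means.
- **Group statistics** — a four-test normality battery
  (D'Agostino–Pearson, Anderson–Darling, Shapiro–Wilk,
  Lilliefors-corrected KS) choosing between the unpaired Student's t
  test and the Mann–Whitney test (exact for small tie-free samples).
- **Synthetic scenes** — a ground-truthed generator (fiber networks
  with patchy tension labels, tension-coupled platelets, PSF blur,
  Poisson–Gaussian noise) so every stage is validated by parameter
  recovery rather than by eye.

Inputs are OME-TIFF (channel names and pixel size read from metadata) or
per-channel grayscale TIFFs with an explicit channel map. Outputs are
PNG masks, 32-bit float TIFF ratio maps, CSV tables and a JSON report.
See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate a scene at the default study conditions (40% untensed fiber
pixels, 80% of platelets in contact with stretched fibers) and analyse
it stage by stage:

```sh
$ tensiomap simulate --seed 7 --out scene
$ tensiomap ratiometric scene/scene.ome.tif --out ratio_out
untensed_density_pct=40.00
$ tensiomap apply-classifier scene/scene.ome.tif --out cls_out
untensed_px=4325 stretched_px=6487
$ tensiomap detect-platelets scene/scene.ome.tif --out det_out
objects=56 platelets=50
$ tensiomap proximity det_out/platelets.csv cls_out/untensed_mask.png \
      cls_out/stretched_mask.png --pixel-size 0.5 --out prox_out
group  n_platelets  n_defined_stretched  pct_contact_stretched  mean_d_stretched_um  n_defined_untensed  pct_contact_untensed  mean_d_untensed_um
  all           50                   50                   80.0              0.95584                  50                  10.0           11.371155
```

Reading the numbers: 40.00% of fibronectin-positive pixels are
probe-positive (the generator planted 40%); all 56 planted CD31+ objects
are found, and DAPI gating keeps the 50 anucleate platelets; 80% of
platelets are in contact with stretched fibers (the generator seeded
80%), with a mean centroid distance of ~0.96 µm — about one platelet
radius, i.e. touching — while untensed fibers are an order of magnitude
farther away on average.

The same analysis runs end to end with `tensiomap run --input
scene/scene.ome.tif --out results`, which writes `report.json` plus all
masks and tables, and compares per-image mean distances to stretched
vs. untensed fibers when given several images. Everything is also
available as a library:

```python
from tensiomap import SceneParams, simulate_scene, joint_mask, untensed_density

truth, image = simulate_scene(SceneParams(seed=7))
fn_mask, probe_mask, joint = joint_mask(image)
print(untensed_density(fn_mask, probe_mask).untensed_density_pct)  # 40.00...
```

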