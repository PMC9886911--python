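# Methods

`cryoassay` re-implements, as a tested pipeline, the image-analysis half of a
whole-animal cryo-imaging platform for tracking fluorescently labelled cells
after bone-marrow transplantation: single-cell detection of CFSE-labelled
T-cells (green channel) and Qdot-labelled MSCs (red channel) in 3D
multispectral volumes, secondary-lymphoid-organ (SLO) volumetry, and an
imaging-based CFSE-dilution proliferation statistic (%High). Because no
imaging data are deposited for this kind of experiment, the package ships a
first-class synthetic phantom generator with exact ground truth; every
pipeline stage is validated against phantoms rather than against mouse data.

## Coordinate and intensity conventions

Volumes are `(channel, z, y, x)` arrays of 8-bit intensities; `z` is the
sectioning axis. All physical conversions go through
`voxel_size_um = (dz, dy, dx)`, default `(40, 10.5, 10.5)` µm: 40 µm
cryo-sections with 10.5 µm in-plane pixels, so a voxel is about the size of a
single cell in-plane but almost 4× coarser axially. Intensities are kept on
the 0–255 scale end to end because every operating threshold of the assays
(render bounds 40/130 and 60/200, detection thresholds, `T_ref`) is defined
on that scale.

## Phantom generator

The phantom emulates the statistical structure the assays rely on, not
optics:

* **Anatomy.** Nested ellipsoids. A spleen is an envelope of red pulp
  containing spherical white-pulp nodules; the marginal zone is a thin
  (1–3 voxel) dilation shell of red pulp hugging the white pulp — the
  white-pulp/red-pulp interface. A lymph node is a cortex shell with a
  concentric paracortex core. Region labels are integers with a name map.
* **Autofluorescence.** Constant per-region background per channel (red pulp
  brightest in green, ~12 of 255) plus additive Gaussian sensor noise
  (default SD 2), clipped to [0, 255] and quantised.
* **Cells.** Point sources at region voxels, blurred with an anisotropic
  Gaussian PSF (default σ = (12, 6, 6) µm) that is peak-normalised so the
  centroid voxel carries the emitted intensity. Placement is uniform in the
  target region without replacement.
* **CFSE dilution.** Emitted intensity after `g` divisions is
  `I0 · 2^(−g) · (1 + ε)`, `ε ~ N(0, cv)`: the dye is covalent and is split
  between daughters, so intensity halves per division and is stable in
  non-dividing cells. Division counts per cell are fixed, zero, or Poisson
  with a given mean.
* **Subsurface fluorescence.** With a configurable probability a cell leaves
  an attenuated echo (default ×0.5) at the same in-plane position one
  section deeper. A single-section echo suffices: at 40 µm sections, deeper
  bleed-through is negligible. Echoes are rendering artefacts; the ground
  truth lists each cell exactly once.

Every random step consumes an explicit `numpy` generator seeded from the
spec, so identical inputs reproduce volumes, masks and ground truth bit for
bit.

What the phantom does **not** model: scattering and depth-dependent
attenuation, tiling/stitching artefacts, brightfield texture, non-ellipsoidal
anatomy, and spatially correlated autofluorescence. Detection thresholds are
calibrated on the phantom's own autofluorescence structure, so performance
numbers quoted here certify the algorithms under these study conditions —
they do not certify recall on real tissue, where autofluorescence is more
structured.

## T-cell detection

The green channel is filtered with a Mexican-hat kernel (negated
Laplacian-of-Gaussian). Scales are physical (µm per axis) and converted to
voxels through the voxel geometry, so the kernel is strongly anisotropic in
voxel space; the Laplacian is likewise taken with respect to physical
coordinates. The response is multiplied by `σ̄^(2γ)` (geometric-mean scale,
γ = 1.25): with this exponent the response of a 3D Gaussian blob is
maximised at the matched scale, which keeps "the kernel matched to the cell
size" meaningful across the scale list. The discrete second-derivative
kernels are zero-sum-corrected so constant images give exactly zero
response. Scales smaller than half a voxel on any axis are rejected.

A threshold `T_isolated` marks candidate voxels. It is calibrated per scale
on an autofluorescence-only control phantom: the `1 − 10⁻⁶` quantile of the
filtered control response, times a 1.15 safety margin. On the control this
marks at most a 10⁻⁶ fraction of voxels; the margin absorbs noise
fluctuations of the strongest autofluorescent structure (organ rims,
compartment interfaces) on comparable volumes, operationalising "minimally
mark the autofluorescent pixels".

Marked voxels are grouped by 3D connected components, default
26-connectivity — the most aggressive merging, which is the point: a cell
and its subsurface echo in the adjacent section share a component and are
counted once. Component size gates (default 1–125 voxels) drop large
autofluorescent sheets. The filter–threshold–group cycle repeats over an
ascending scale list to pick up larger cell clusters; a component that
overlaps any detection accepted at a finer scale is discarded, so a single
cell is never re-counted at a coarse scale.

Per-cell intensity is the morphological white top-hat of the raw channel
(flat ellipsoidal footprint, default radius 32 µm — larger than a cell,
smaller than background variation) evaluated at the detection's peak voxel.
When a mask is supplied, detections are labelled with the region at their
centroid and detections outside every labelled region are dropped; this
mask-based plausibility filter replaces the platform's interactive manual
curation.

At the study conditions (bright CFSE cells, I0 ≈ 200 over background ≈ 10,
noise SD 2) detection on a 64×256×256 spleen phantom with 200 cells reaches
recall and precision ≥ 0.95 in a few seconds on one CPU. The regime is
autofluorescence-limited, not noise-limited: with the calibrated thresholds,
cells dimmer than the strongest autofluorescent edge responses (intensity
≲ 15–20) are not recoverable, which for the dilution assay means cells
beyond ~4 divisions fade from the detected sample.

## MSC detection

Each voxel carries four features — white top-hat of red and green, and
Mexican-hat response of red and green at the finest scale — and a bagged
ensemble of decision trees (default 50, scikit-learn `BaggingClassifier`)
votes MSC/non-MSC per voxel; out-of-bag accuracy is reported from training.
Voxels with probability > 0.5 (ties in an even ensemble therefore vote
non-MSC) are grouped by the same 3D connected-component analysis, one
detection per component with top-hat intensity from the red channel. Only
voxels whose red top-hat exceeds a small floor (default 2 of 255) are sent
to the ensemble; anything dimmer cannot be a labelled cell, and the floor
cuts prediction cost by ~100×.

Training data come from a phantom with known red cells: positives are the
ground-truth centroid voxels only. The PSF halo and the possible echo voxel
one section deeper are *excluded from both classes* — they carry attenuated
signal and labelling them either way teaches the trees the wrong boundary
(labelling them positive pushed the decision threshold down into the noise
tail and produced spurious red-spike detections). Negatives are random
voxels outside the exclusion zones, with the phantom's green T-cells left in
place so the ensemble learns cross-channel rejection.

## Volumetry

Volume is segmented-voxel count × voxel volume, reported in mm³ at full
float precision (rounding is a display concern). Spleen metrics: total
volume (red pulp + white pulp + marginal zone), white-pulp volume, and %WP =
100·WP/total. The marginal zone counts toward total spleen but not white
pulp, since it is the WP/RP interface rather than white pulp proper. Lymph
node size is the whole-node labelled volume; nodes come from provided masks
(no automatic node segmenter is attempted).

A stand-in white-pulp segmenter is provided for volumes without masks: the
green channel is smoothed far above the single-cell scale (default
(20, 40, 40) µm), Otsu-thresholded within the envelope, and bright
components above a size floor become white pulp. It assumes white pulp is
the brighter compartment (dense CFSE-labelled infiltrate) and refuses to
segment when the two Otsu classes differ by less than 10 intensity units —
several times the compartmental autofluorescence contrast — so a spleen
without labelled cells falls back to provided masks. On densely seeded
phantoms it reaches Dice ≥ 0.8 against the true white pulp; on
inverted-contrast controls it fails or scores Dice < 0.5, which is the
documented limit of the assumption.

## CFSE dilution assay

Detected T-cell intensities per organ form a sample; a Gaussian KDE on a
256-point grid over [0, 255], renormalised on that support, estimates the
intensity PDF. The default bandwidth is Silverman's rule **capped at 15
intensity units**: CFSE samples are multimodal (one mode per division
generation), which inflates the sample SD and makes the plain rule of thumb
over-smooth; the cap keeps the area above a threshold within 2 percentage
points of the empirical exceedance fraction for n ≥ 100, which is the
contract %High relies on.

%High is the area of the PDF above a single reference threshold `T_ref`
shared by all groups and timepoints. `T_ref` is calibrated once as the
midpoint between the modal top-hat intensity of undivided calibration cells
and the background noise floor (95th percentile of the control green
channel); with the defaults this lands near 105 of 255, i.e. between the
generation-0 and generation-1 intensity modes. Under the halving model
%High is (in expectation) non-increasing in the mean division count, stable
for non-dividing cells, and falls monotonically across 24–96 h for dividing
cohorts.

Two assay modes are exposed: `cell_based` (default; intensities of detected
cells, matching how the detection list is built) and `voxel_based` (all
organ voxels of the green channel, matching how whole-organ renderings are
summarised). Results tables record the mode.

Colour-coded renderings are maximum-intensity projections along the section
axis of the green channel inside the organ mask, mapped linearly onto the
standard rainbow map (blue = dim/divided, red = bright/undivided), with
default bounds 40–130 for spleen and 60–200 for lymph nodes, clipped
outside.

## Cohort simulation

`CohortDesign` encodes the study: groups syn / allo / allo+MSC, timepoints
24–96 h, 4 animals per group. Latent biology per group: mean T-cell
divisions per 24 h (syn 0, allo 1, allo+MSC 0.5) and a spleen MSC
recruitment multiplier (2 for allogeneic recipients). Per-cell division
counts are Poisson around `rate · t/24`. White-pulp volume scales by
`1 + g·ḡ` with growth coefficient g = 1 per mean division, and the envelope
grows by the corresponding absolute white-pulp increment, so total spleen
volume roughly doubles by 96 h in the allo group — the magnitude of
enlargement the assay is designed to detect. Animal-to-animal variability
is a 3% SD jitter on envelope radii (~9% volume CV). Realised MSC counts
are Poisson. The expansion kinetics are free parameters of the design, not
claims about the mouse model; the defaults are chosen to be biologically
plausible and to give group separations of the same order as the phenomena
the original assays report.

The cohort phantoms are deliberately small (18×72×72 voxels,
≈ 0.72×0.76×0.76 mm) so that a hundred replicate cohorts — 48 phantoms each
— simulate, detect and assay in a couple of minutes; all geometry-dependent
code paths are identical at larger sizes.

## Statistics and reporting

Between-group comparisons use the classic two-tailed Student's t-test with
pooled variance (Welch behind a flag), annotated `*` for p < 0.05 and `**`
for p < 0.005; error bars are standard errors of the group mean. No
multiple-testing correction is applied, and reports say so. Two identical
zero-variance samples give p = 1 by convention; zero variance with unequal
means raises rather than fabricating a p-value.

## Numerical and design notes

* Degenerate KDE samples (zero spread) fall back to a unit-width Gaussian
  bump at the common value.
* `percent_high` integrates the truncated, renormalised density with a
  linear-interpolated cut at `T_ref`; on raw samples it is the empirical
  fraction.
* Component centroids are response-weighted centres of mass; the intensity
  lookup uses the response peak voxel.
* Detection-count monotonicity in `T_isolated` holds for isolated unimodal
  peaks; merged multi-cell components can split as the threshold rises, so
  the property is only asserted where it is well-defined.
* The scale-equivariance of detection (dilating image and σ together) holds
  in-plane; the z axis is pinned by the section thickness.
* In dense regions (≳ 5% of region voxels occupied) nearby cells merge into
  single components and counts undershoot; the cohort's %High statistic is
  robust to this because each merged component still contributes one real
  cell's intensity.

## Known limitations

* Thresholds calibrated on phantom autofluorescence transfer to real data
  only insofar as the control volume is representative; on real tissue the
  control-image calibration step must be repeated per imaging configuration.
* The MSC classifier is trained on matched synthetic phantoms; applying it
  to other PSFs, label brightnesses or background structures requires
  retraining.
* The stand-in white-pulp segmenter presumes CFSE-bright white pulp and is
  not a substitute for a purpose-built spleen compartment segmenter.
* `%High` in cell-based mode inherits the detector's dim-cell censoring:
  heavily divided cells (≳ 4 generations at default brightness) drop out of
  the sample, biasing %High slightly upward in strongly proliferating
  groups. Group orderings are preserved.
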