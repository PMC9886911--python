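# cryoassay

Cell-tracking and proliferation assays for 3D multispectral cryo-imaging
volumes: single-cell detection of CFSE-labelled T-cells and Qdot-labelled
MSCs, secondary-lymphoid-organ (SLO) volumetry, and an imaging-based
CFSE-dilution statistic (%High) — together with a synthetic whole-organ
phantom generator that provides exact ground truth for every stage.

The package is aimed at people analysing (or simulating) block-face
cryo-imaging data from cell-therapy experiments — e.g. tracking donor
T-cells and mesenchymal stromal cells after bone-marrow transplantation —
where the readouts of interest are *where labelled cells are*, *how large
the lymphoid organs have grown*, and *how much the T-cells have divided*.

## The core methods

**T-cell detection.** The green channel is filtered with a Mexican-hat
kernel (negated, scale-normalised Laplacian of Gaussian, σ in µm per axis,
anisotropy-aware); a threshold `T_isolated`, calibrated on an
autofluorescence-only control so that autofluorescent voxels are minimally
marked, selects candidate voxels; 3D connected components group the marks
so that a cell and its subsurface echo (the same cell re-appearing in the
next 40 µm section) are counted once; the process repeats over an ascending
scale list for larger clusters. Per-cell intensity is the white top-hat of
the raw channel at the detection peak, i.e. the background-subtracted
single-cell brightness.

**MSC detection.** Four features per voxel — top-hat and Mexican-hat of the
red and green channels — feed a bagged decision-tree ensemble that votes
MSC/non-MSC per voxel; positives are grouped by the same 3D connected
component analysis.

**Volumetry.** Volume = labelled-voxel count × voxel volume (default
40 × 10.5 × 10.5 µm³), in mm³. Spleen metrics are total volume, white-pulp
(WP) volume and %WP = 100·WP/total; lymph-node size is whole-node volume.

**CFSE dilution (%High).** CFSE intensity halves with each division, so the
intensity distribution of detected T-cells encodes proliferation. A
Gaussian-kernel density estimate on [0, 255] summarises the sample, and
%High is the area of that density above a single fixed threshold `T_ref`
shared by all groups and timepoints: non-dividing cells keep %High near 1,
proliferating cells drive it toward 0.

**Statistics.** Two-tailed Student's t-test (pooled variance) between study
and control groups, annotated `*` (p < 0.05) and `**` (p < 0.005); error
bars are standard errors.

Because no real cryo-imaging volumes ship with the package, a phantom
module generates spleen and lymph-node volumes with realistic structure
(anisotropic voxels, per-region autofluorescence, point-like cells under an
anisotropic PSF, halving CFSE dilution, subsurface echoes) plus exact
ground truth, and a cohort simulator builds whole studies (syngeneic /
allogeneic / allogeneic+MSC groups over 24–96 h). See `docs/methods.md`
for the model details and their limits.

## Worked example

Simulate the default cohort, calibrate the detector and `T_ref` on
dedicated phantoms, then run the dilution assay and volumetry:

```python
import dataclasses
import numpy as np

from cryoassay import (
    CellPopulationSpec, CohortDesign, DetectionConfig, PhantomSpec,
    calibrate_t_isolated, detect_tcells, generate_phantom, simulate_cohort,
    spleen_metrics, two_tailed_ttest, annotate,
)
from cryoassay.cfse import calibrate_t_ref, cfse_assay, collect_intensities
from cryoassay.phantom import RegionGeometry

control, _, _ = generate_phantom(PhantomSpec(rng_seed=1), [])
config = DetectionConfig()
config = dataclasses.replace(config, t_isolated=calibrate_t_isolated(control, config))

calib, calib_mask, _ = generate_phantom(
    PhantomSpec(rng_seed=2,
                region_geometry=RegionGeometry(n_wp_nodules=1, wp_radius_um=140.0)),
    [CellPopulationSpec(n_cells=100, region_label="white_pulp")],
)
t_ref = calibrate_t_ref(
    collect_intensities(detect_tcells(calib, config, mask=calib_mask)),
    noise_floor=float(np.quantile(control.channel("green"), 0.95)),
)

records = simulate_cohort(CohortDesign(), seed=7)
table = cfse_assay(records, config, t_ref)
```

With seed 7 this prints (`T_ref = 114` of 255):

```
spleen volume at 72 h: syn 0.063 mm^3, allo 0.104 mm^3, allo+MSC 0.081 mm^3
allo vs syn: t = 6.27, p = 0.00076 **
%High at 72 h: syn 99.2%, allo 15.4%, p = 2.1e-09 **
```

Reading the numbers: allogeneic T-cells divide about once a day, so by 72 h
their white pulp has expanded (total spleen volume 0.104 vs 0.063 mm³ for
the non-dividing syngeneic control — these are miniature simulated spleens,
not real organ sizes) and their CFSE has diluted below `T_ref` (%High 15%
vs 99%). The MSC-treated group sits between the two on both axes. The group
means of %High per timepoint fall monotonically for the allo group
(0.58 → 0.31 → 0.15 → 0.07 over 24–96 h) while the syn group stays at ~1.0.

A command-line surface wraps the same functionality
(`cryoassay simulate|detect|volumetry|cfse|report --config c.yaml --out dir
--seed 7`), writing TIFF volumes with JSON geometry sidecars, detection
CSVs and a run manifest.

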