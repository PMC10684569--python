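# osseosurf

Precision and trueness assessment of craniofacial bone surface models
segmented from CT/CBCT volumes by a single grey-value threshold.

## The problem

Three-dimensional surface models of the facial skeleton are routinely
extracted from CT or cone-beam CT (CBCT) volumes by choosing one
visually defined segmentation threshold and meshing its level set with
marching cubes. Two questions decide whether such models are fit for
morphometric use:

* **Precision (reproducibility)** — how much do repeatedly segmented
  models of the *same* volume differ, given that the operator's
  threshold choice varies a little from session to session?
* **Trueness** — how close is a segmented model to the *actual* bone
  surface, as captured by a gold-standard reference model?

Physical validation studies answer these with dry skulls in
water-filled head shells (water emulates soft tissue) and
optical-scanner reference models. Such raw data are confidential and
scanner-bound, so this package provides the entire measurement pipeline
together with a **digital phantom generator**: a bone-density closed
surface embedded in a water-density background, rasterised on
machine-specific voxel grids with partial-volume mixing, scanner-like
blur and noise, and a simulator of operator threshold variability. The
phantom's surface is known analytically, so every stage of the pipeline
is testable against exact ground truth.

It is aimed at researchers in craniofacial imaging, morphometrics and
medical image analysis who need a reproducible, fully scripted
implementation of the accuracy-assessment protocol.

## The method

Given two triangle meshes *A* (query) and *B* (target), the deviation
metrics are computed from the distance of each vertex *vᵢ* of *A* to
the closest point on *B*'s triangle surface (exact nearest neighbour,
no approximation):

```
dᵢ   = min over triangles T of B of ‖vᵢ − proj_T(vᵢ)‖
MAD  = (1/n) Σ dᵢ                      (mean absolute distance, mm)
SDAD = sqrt( (1/(n−1)) Σ (dᵢ − MAD)² ) (SD of the absolute distances, mm)
```

summarised over *measurement areas* — triangle patches grown
breadth-first to an exact count (1000 triangles per circular patch;
bilateral patches are unified into 2000-triangle areas for
reproducibility testing and 4000-triangle areas for trueness testing).

Reproducibility is assessed at three levels: (1) MAD/SDAD between
repeated segmentations at their original position in the volume,
(2) the six rigid movement components (X/Y/Z translations in mm and
rotations in degrees; X lateral, Y vertical, Z anteroposterior)
required to best-fit one model onto the other, and (3) MAD/SDAD after
that superimposition. The best fit is a point-to-plane ICP variant with
100% estimated overlap, 100% point sampling, exact nearest-neighbour
search and at most 50 iterations, solved per iteration by the
linearised screw least squares

```
min over (ω, t) of Σᵢ ( nᵢ · (vᵢ + ω×vᵢ + t − qᵢ) )²
```

where *qᵢ* is the closest surface point on the fixed mesh and *nᵢ* its
normal. Trueness best-fits each segmented model to the gold-standard
mesh and summarises MAD/SDAD over areas selected once on the gold
standard. Group comparisons use Shapiro–Wilk screening, Wilcoxon
signed-rank, Kruskal–Wallis and pairwise Mann–Whitney U tests with
Bonferroni adjustment (exact small-sample p-values by full
enumeration), with median/IQR descriptives and colour-coded signed
distance maps (±0.1 mm reproducibility scale, ±0.5 mm trueness scale).

## Worked example

Segment one noisy face-like phantom twice with two independently
sampled operator thresholds and compare the two models:

```python
from osseosurf import phantom
from osseosurf.segmentation import extract_isosurface, keep_main_components
from osseosurf.deviation import closest_distances, summarise
from osseosurf.registration import icp_register, decompose_transform

spec = phantom.face_like_spec(semi_axes=(16, 19, 15), spacing=(0.7, 0.7, 0.7),
                              psf_fwhm=1.2, noise_sigma=40, seed=3)
volume = phantom.simulate_acquisition(spec)
thresholds = phantom.sample_operator_thresholds(spec.midpoint_threshold, 0.01,
                                                spec.intensity_full_range, n=2, seed=4)
meshes = [keep_main_components(extract_isosurface(volume, t), 0.01) for t in thresholds]
pre = summarise(closest_distances(meshes[0], meshes[1]))
print(f"MAD = {pre.mad:.4f} mm, SDAD = {pre.sdad:.4f} mm, max = {pre.max_abs:.4f} mm")
transform, result = icp_register(meshes[0], meshes[1])
print(decompose_transform(transform).as_dict())
```

Output:

```
MAD = 0.0333 mm, SDAD = 0.0036 mm, max = 0.0536 mm
{'tx_mm': -0.0, 'ty_mm': 0.00022, 'tz_mm': 9e-05,
 'rx_deg': -0.00899, 'ry_deg': -0.00239, 'rz_deg': 0.00275}
```

The two thresholds drawn here differ by 34.5 grey values (0.86% of the
4000 grey-value range), yet the repeated surface models agree to a mean
of 0.033 mm — far below the 0.7 mm voxel size — and the rigid movement
needed to superimpose them is below 0.01 mm/°, i.e. the models are
nearly coincident already at their original position.

Full studies run from the CLI:

```
osseosurf study repro --out runs/repro     # three-level reproducibility
osseosurf study trueness --out runs/true   # trueness vs ground truth
```

Each run folder contains long-format CSV tables (`deviations.csv`,
`movements.csv`, `thresholds.csv` with box-plot outlier flags), a
`stats.json` with the test battery, colour-map PLY/PNG renderings and a
`manifest.json` whose seed and config hash reproduce the run
bit-identically.

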