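# Methods

This note documents the models, numerical choices and limitations of
`osseosurf`: what the digital phantoms emulate, how each pipeline stage
is defined, which parameters matter and why their defaults were chosen.

## Digital phantom model

The phantom stands in for a dry skull scanned inside a water-filled
head shell. The background is pure water everywhere — no air gap or
shell wall — because the assessed interface is bone–water and the water
layer is the soft-tissue simulant; modelling the shell would add
geometry without changing that interface.

### Analytic surfaces

All shapes are star-shaped about the origin: the surface is
`{ R(u)·u : ‖u‖ = 1 }` for a smooth radius function `R`.

* **sphere** — `R(u) = r`.
* **ellipsoid** — `R(u) = (Σ (u_k/a_k)²)^(−1/2)` with semi-axes
  `(a, b, c)` in mm.
* **face-like** — the ellipsoid radius plus a fixed set of low-order
  sinusoidal perturbations in spherical coordinates
  (`θ = arccos u_z`, `φ = atan2(u_y, u_x)`):

  ```
  R(u) = R_ell(u) + a₁ cos 2θ + a₂ sin 3θ cos 2φ + a₃ sin 4θ sin 3φ
  ```

  The degree-3/4 terms are strong enough (`A·l² > R`) to create locally
  concave recesses, giving the mix of convex (zygoma-like) and concave
  (maxilla-like) curvature the measurement areas need, without any
  anatomical data. Validation rejects amplitude sets whose sum exceeds
  half the smallest semi-axis, which keeps the radius positive and the
  surface single-valued (no self-intersection).

Default face-like parameters: semi-axes 24 × 28 × 22 mm, amplitudes
(1.5, 2.0, 1.2) mm — a desk-scale face analogue whose surface area
(≈ 7,500 mm²) keeps full-resolution runs tractable while preserving
realistic curvature variety.

### Rasterisation

Voxel values mix bone and water intensity by the fraction of the voxel
inside the surface, estimated from the *radial signed distance*
`d(p) = ‖p‖ − R(p/‖p‖)` at the voxel centre through a clamped linear
ramp of one-voxel width (`w` = mean spacing):

```
value = water + (bone − water) · clip(0.5 − d/w, 0, 1)
```

This is exact for spheres and first-order accurate for the other
shapes near the surface. The ramp is monotone along any ray crossing
the surface, cheap, and places the half-intensity level exactly on the
analytic surface — which is what sub-voxel localisation tests need. It
deliberately ignores true sub-voxel integration; the approximation
error is far below the half-voxel acceptance bound. Grids are sized
automatically to the shape plus a 4-voxel margin; explicit grids
smaller than the shape plus a 2-voxel margin are rejected.

The grey scale defaults to a 0–4000 full range with bone at 1500 and
water at 0, so a threshold difference of 10 grey values is 0.25% of
the full range — the granularity at which operator threshold
variability is typically reported for CT.

### Degradation

`degrade` applies a Gaussian point-spread function (isotropic FWHM in
mm, converted to per-axis sigma in voxels) followed by additive white
Gaussian noise (SD in grey values), seeded through
`numpy.random.default_rng` so identical inputs give bit-identical
output. Defaults (FWHM 0.6 mm, noise SD 40 ≈ 1% of range at full
contrast) are engineering choices: no quantitative blur/noise data per
scanner exist, so the values were fixed once at levels that produce
visually CBCT-like edges, and are not calibrated to any machine.
Blur-then-noise ordering means the noise is *not* band-limited; this is
the conservative choice for segmentation (raw marching cubes sees the
full noise power).

### What the phantom does not emulate

Cone-beam projection/reconstruction physics — scatter, beam hardening,
metal and motion artefacts, spatially varying noise, CBCT grey-value
drift across the field of view. Passing tests therefore demonstrate
correctness of the *measurement pipeline* and achievable bounds under
idealised acquisition, not the absolute accuracy of any clinical
scanner. Real-data MAD/SDAD values depend on the specimens and
machines and are outside what synthetic runs can reproduce.

### Operator model

The visual threshold choice is never computed — it is always an input.
Operator variability is simulated as uniform draws from
`base ± spread · full_range` (default spread 1%, below the ~2%
spread observed between repeated visual selections). For phantoms the
optimal base is the bone/water midpoint, where the partial-volume ramp
crosses the true surface. Intra- vs inter-operator comparisons use two
independent seeded streams with equal spread.

## Segmentation

`extract_isosurface` is scikit-image's marching cubes (Lewiner variant)
with per-edge linear interpolation, spacing/origin applied so vertices
are in world mm, and `gradient_direction='ascent'`, which makes the
winding produce outward normals (from high-value bone toward
background); this is asserted by test. Voxels exactly equal to the
threshold lie on the extracted surface (strict comparison inside the
algorithm); the difference from treating them as interior is
measure-zero on floating-point data and deterministic. No smoothing or
decimation is applied — deviation metrics must see the raw mesh.
`keep_main_components` removes speckle components below a fraction
(default 1%) of the largest component's triangle count.

## Measurement areas

Patches grow breadth-first over edge adjacency from a seed triangle,
ring by ring, admitting the final partial ring in order of centroid
distance to the seed; growth stops at exactly the requested count.
This "BFS-ring-then-distance" rule is deterministic and yields
disc-like patches whose shape is independent of mesh resolution.
Bilateral patches are unified by set union into one area (2000
triangles for reproducibility, 4000 for trueness, 1000 per circular
patch). Anatomy has no phantom equivalent, so seed placement uses
configured unit *anchor directions* (forehead upper-anterior, zygoma
lateral-anterior, maxilla lower-anterior, bilateral pairs) projected
onto the analytic surface; the nearest triangle centroid becomes the
seed.

Transfer of an area to a differently triangulated mesh (`map_area`) is
a deduplicated bidirectional centroid match: each source centroid
admits its nearest target triangle, and every target triangle whose
nearest source triangle lies in the area is admitted too. One-way
matching would undercover whenever the target is finer than the
source; the bidirectional rule preserves the region's extent in both
directions (verified to 10% surface area on re-meshed spheres). A
median forward distance above a 2 mm gate flags misalignment.

## Registration

Point-to-plane ICP with the study's settings as defaults: 100%
estimated overlap, 100% sampling, exact nearest neighbour, hard cap of
50 iterations. Correspondences run from (sampled) source-area vertices
to the exact closest point on the fixed mesh's *triangle surface* —
not the nearest vertex — because movements are reported at 0.01 mm
resolution, below the edge length. Each iteration solves the
linearised screw least squares and applies the exactly
re-orthonormalised rotation (Rodrigues); iteration stops early when
the RMS residual changes by less than 1e-6 mm (the iteration cap and
the tolerance are both honoured). With overlap < 1 the worst
(1 − overlap) fraction of correspondences by distance is discarded
each round.

Degenerate geometry (e.g. concentric spheres, where rotation produces
no point-to-plane residual) is detected by a scale-normalised
conditioning test: the rotation block of the design matrix is divided
by the cloud's RMS radius so all six columns share units, and a
singular-value ratio below 0.1 flags the unobservable directions. The
solve itself uses minimum-norm least squares, which returns zero for
unobservable components — equivalent in effect to falling back to a
translation-only fit for those directions, and simpler. Raw numerical
rank alone cannot detect this: facet normals of a tessellated sphere
deviate slightly from radial, so the system is full-rank numerically
while rotation remains meaningless.

Movements are reported as translations on the X (lateral), Y
(vertical), Z (anteroposterior) axes and Euler angles in degrees under
the fixed-axis X→Y→Z convention (no axis order is standard in the
application domain; the convention is recorded in all serialised
output, and decompose/recompose round-trips to 1e-9 away from gimbal
lock, which is flagged at |ry| ≈ 90°).

## Deviation metrics

`closest_distances` returns, for every query vertex, the unsigned
distance to the exact nearest point on the target surface. The engine
builds a k-d tree over triangle centroids and prunes with a provable
bound: the distance to a triangle is at most the distance to its
centroid and at least the centroid distance minus the triangle's
circumscribing radius. Candidates are expanded (k-NN escalation) until
the bound certifies exactness, then decided by a vectorised
closest-point-on-triangle classification (seven barycentric regions).
A brute-force all-pairs scan is the correctness oracle in tests
(agreement to 1e-9).

MAD is the mean and SDAD the (n−1)-denominator standard deviation of
the absolute distances. The default mode is point-to-*surface*; a
point-to-*vertex* mode exists for sensitivity analysis of software
that compares vertex clouds only (surface projection can only shorten
distances, so `surface ≤ vertex` everywhere). Within each unified
area, raw distances are pooled before summarising (so the pooled MAD
is the sample-size-weighted mean of per-area MADs); this choice is
recorded in the run manifest.

Colour maps use the signed distance (positive outside the target,
sign taken along the nearest triangle's normal) on a symmetric
diverging scale with saturation beyond ±scale — 0.1 mm for
reproducibility maps, 0.5 mm for trueness maps — exported as
per-vertex-coloured PLY plus an orthographic frontal PNG.

## Statistics

All tests are two-sided. Exact p-values are computed by full
enumeration up to a total sample size of 12 (all 2ⁿ sign patterns for
Wilcoxon; all C(n, n_a) labelings for Mann–Whitney — both tie-safe via
average ranks), and by normal approximation with tie correction above;
the switchover is recorded in each result. Zero differences in the
Wilcoxon test are dropped (Wilcoxon's original rule) and the count
reported. Kruskal–Wallis uses the tie-corrected H with a chi-squared
reference (k−1 df). Pairwise Mann–Whitney follow-ups are the classical
two-sample test (not the pooled-rank variant some packages report) and
are Bonferroni-adjusted. Shapiro–Wilk screening is always reported and
never gates the pipeline: the nonparametric path runs regardless.
Descriptives are median and IQR (Q3 − Q1, linear-interpolation
quantile rule).

## Study orchestration

`run_reproducibility` executes the three-level protocol per acquisition
setting × subject: repeated segmentation with independent thresholds,
level-1 MAD/SDAD at original position, point-to-plane best fit on the
reference area with SixDoF recording, level-3 MAD/SDAD after
superimposition. `run_trueness` segments once, best-fits to the
analytic ground-truth mesh (areas selected once on the ground truth
and transferred by `map_area`), and summarises post-fit deviations.
"All measurement areas as one variable" is implemented by pooling the
per-area summary values as statistical units (each box-plot point is
one area summary), not by pooling raw distances across areas.

Every random draw derives from a single study seed via SHA-256 of the
(seed, setting, subject, purpose) tuple, truncated below 2³¹ — runs
are bit-identically reproducible from the manifest, including exported
CSV/JSON/PLY/PNG bytes.

The default configuration mirrors four acquisition settings: a CT-like
anisotropic grid (0.49 × 0.49 × 0.31 mm), 0.3 mm and 0.2 mm isotropic
CBCT analogues, and an ultra-low-dose variant of the finest grid with
doubled noise — the only differences the emulated protocols state are
voxel size and exposure. A `demo_study_config` runs the identical
workflow on smaller phantoms (16 × 19 × 15 mm semi-axes, 0.7–0.85 mm
grids, 400/800-triangle areas) for examples and fast CI-scale runs;
the test suite and the acceptance script use these desk-scale problem
sizes, chosen as the package's own trade-off between runtime and
statistical resolution.

## Ground-truth meshes

The gold-standard stand-in projects a subdivided icosahedron radially
onto the analytic surface: every vertex lies on the surface to
floating-point precision, the mesh is watertight, and the subdivision
level is chosen so the median edge length approximates the requested
target (each subdivision halves the edge, quadrupling the triangle
count). Optical-scanner artefacts (holes, registration seams,
semi-automatic post-processing) are not emulated.

## Known limitations

* The radial signed distance used by the rasteriser is first-order
  near the surface for non-spherical shapes; strongly eccentric
  ellipsoids would bias the ramp width slightly (not the surface
  position).
* Patch "circularity" is graph-geodesic, not exact-geodesic; on very
  anisotropic triangulations patches can be mildly elliptical.
* The ICP observability flag uses a fixed 0.1 conditioning threshold;
  geometries between "clearly constrained" and "symmetric" may not be
  flagged.
* Euler-angle reporting degenerates near |ry| = 90° (flagged, still
  returned); study-scale movements are orders of magnitude below that.
* Statistics at demo scale have few samples per group; exact
  enumeration keeps p-values valid, but power is limited by design.
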