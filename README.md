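# tomovault

Quantitative in-situ analysis of membrane geometry and particle context in
cryo-electron tomograms.

Cryo-ET studies of large cytosolic particles — vaults, ribosomes —
increasingly ask *where* a particle sits and *how* it is oriented relative to
its surroundings: does a membrane-bound particle sit on a bilayer patch of
altered thickness or curvature?  Are particles enclosed by another complex,
and if so, in random or preferred orientations?  `tomovault` packages the
measurement machinery those questions need, so that each step is testable
against synthetic scenes with known ground truth rather than only runnable on
raw tomograms:

* **Bilayer thickness from intensity profiles.**  A profile along the
  membrane normal shows the two leaflets as minima.  Thickness is reported
  both as the distance between the two minima and as the distance between the
  inflection points (maximal intensity gradient between each minimum and its
  adjacent maximum), with sub-voxel localisation on a cubic-spline
  interpolant.
* **Leaflet-resolved thickness maps.**  A membrane segmentation becomes a
  marching-cubes mesh; local PCA separates the two leaflet surfaces; local
  thickness is the Euclidean distance between one-to-one matched
  nearest-neighbour points on the opposing surfaces.
* **Mesh curvature.**  Per-face curvature tensors are fit by least squares to
  the vertex-normal differences along each triangle edge, accumulated at
  vertices with mixed-Voronoi-area weights, and eigen-decomposed into
  principal curvatures k1 >= k2, mean curvature H = (k1 + k2)/2 and Gaussian
  curvature K = k1*k2 (units nm^-1 / nm^-2; indentations have H < 0 with
  cytosol-facing normals).
* **Pose context.**  Particles are paired by a nearest-neighbour rule with a
  distance cutoff (10 nm for "enclosed" calls); relative orientations
  R_rel = R_host^-1 R_guest are summarised as a reference axis on a
  near-equal-area spherical histogram (subdivided icosahedron faces) and
  classified against a target configuration.
* **Template scoring.**  Masked, normalised constrained cross-correlation of
  particle-centred volumes against rotated templates over a near-uniform
  rotation grid (with Cn-symmetry reduction and optional missing-wedge
  weighting); class assignment by the higher best score, peak thresholding by
  z-score.
* **Exact small-sample statistics.**  Two-sided Fisher's exact test
  (probability-mass summation) and the exact Mann-Whitney U test (dynamic
  programming, groups up to 25 without ties).
* **Synthetic scenes.**  Seeded generators for bilayer volumes (two negative
  Gaussian leaflet troughs, optional thinned patch and indentation ring, with
  analytic ground truth), parametric oracle meshes (plane / sphere / cylinder
  / saddle), vault–ribosome pose populations with controllable encapsulation
  and von Mises–Fisher orientation concentration, and toy subtomograms.

## Worked example

Measure bilayer thinning under a bound particle on a synthetic scene:

```python
import numpy as np
import tomovault as tv

# a membrane patch thinned by 0.6 nm under a bound particle, 0.87 nm voxels
spec = tv.BilayerSpec(grid_shape=(48, 96, 96), voxel_size=0.87,
                      leaflet_separation=6.5, patch_radius=15.0,
                      patch_thinning=0.6, noise_sd=0.05, seed=7)
volume, mask, truth = tv.make_bilayer_scene(spec)

# sample intensity profiles inside and outside the patch
rng = np.random.default_rng(0)
xx, yy = np.meshgrid(truth.x, truth.y)
r = np.hypot(xx - truth.x.mean(), yy - truth.y.mean())
sites = []
for group, sel in (("internal", r < 12.0), ("external", r > 20.0)):
    for idx in rng.choice(np.flatnonzero(sel.ravel()), 20, replace=False):
        point = [xx.ravel()[idx], yy.ravel()[idx], truth.mid_z.mean()]
        sites.append((point, [0.0, 0.0, 1.0], group))

groups = tv.measure_group_thickness(volume, sites, half_length=10.0,
                                    basis="inflection", min_prominence=0.05)
medians, result = tv.group_compare(groups)
print(f"median thickness (inflection-based): "
      f"internal {medians['internal']:.2f} nm, "
      f"external {medians['external']:.2f} nm")
print(f"Mann-Whitney U = {result.statistic:.0f}, "
      f"two-tailed p = {result.p_value:.2e} (exact={result.exact})")

# leaflet-resolved thickness map from the segmentation
mesh = tv.refine_normals(tv.mask_to_mesh(mask), iterations=2)
leaflets = tv.separate_leaflets(mesh, neighborhood_radius=18.0)
tmap = tv.compute_thickness_map(leaflets, max_pair_distance=15.0)
print(f"{len(tmap)} matched leaflet point pairs, "
      f"median envelope thickness {np.median(tmap.thickness):.2f} nm")
```

prints

```
median thickness (inflection-based): internal 8.12 nm, external 8.66 nm
Mann-Whitney U = 1, two-tailed p = 7.82e-08 (exact=False)
8928 matched leaflet point pairs, median envelope thickness 10.50 nm
```

The inflection-based readout includes the leaflet half-widths (the analytic
value for a 6.5 nm leaflet separation with 1 nm-wide troughs is
6.5 + 2 = 8.5 nm); the internal-vs-external median difference of ~0.54 nm
recovers the generated 0.6 nm thinning, and the highly significant U
statistic mirrors how such patch comparisons are reported.  The
segmentation-based map measures the envelope of the whole bilayer (leaflet
separation + 4 trough widths = 10.5 nm here), which is the quantity a
membrane segmentation can see.

A command-line interface mirrors the library:
`tomovault simulate`, `tomovault profile-thickness`, `tomovault
mesh-thickness`, `tomovault pose-context`, `tomovault template-score`
(see `tomovault --help`).

## Further reading

`docs/methods.md` documents the models, estimator details, parameter
defaults, and what the synthetic scenes do and do not emulate.
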