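# Methods

This note documents the models and estimators implemented in `tomovault`,
the defaults and the reasoning behind them, and the limits of what the
synthetic scenes can demonstrate.

## Conventions

Volumes are arrays indexed `[z, y, x]`; all internal lengths are nm
(angstroms converted at the MRC boundary).  Voxel indices are 0-based and the
world position of the centre of voxel `i` is `origin + (i + 0.5) *
voxel_size` — the half-voxel convention keeps masks, meshes and poses aligned
exactly.  Rotations are proper 3x3 matrices mapping the particle frame into
the world frame; on-disk Euler angles default to intrinsic ZXZ in degrees
(the dominant subtomogram-averaging convention), with other conventions
accepted by tag.  MRC I/O goes through gemmi; anisotropic voxel sizes are
rejected rather than silently averaged.

## Preprocessing filters

The low-pass filter is an isotropic radial mask with a raised-cosine edge;
the edge shape is not standardised across packages, so its relative width is
a parameter (default 10% of the cutoff frequency).  DC is always passed, so
volume means are preserved.  The Wiener-like deconvolution applies
`W(f) = C(f) / (C(f)^2 + 1/SSNR(f))` with a pure amplitude-decay contrast
model `C(f) = exp(-f / contrast_falloff)` and `SSNR(f) = strength *
exp(-f / falloff)`.  A pure decay (no CTF oscillation) is used because the
filter targets already CTF-corrected tomograms where only an overall
amplitude falloff remains; no defocus parameters are invented.  All filters
are linear, which the tests exercise on random volume pairs.

## Bilayer density model and profile thickness

Cryo-ET membranes appear as two dark bands: the generator models intensity as
`I(x) = -A g(d1; sigma) - A g(d2; sigma) + noise`, where `d1, d2` are the
distances to the two leaflet mid-planes, `g` a Gaussian of width `sigma`
(default 1 nm) and `A` the trough depth.  Defaults follow the analysed
tomograms: 0.87 nm voxels (4x binning of a ~2.2 A pixel), 6 nm leaflet
separation.  An `inverted` flag is exposed because the sign convention of
normalised maps varies between processing chains; the minima-are-leaflets
convention is the default.  The optional thinned patch is a hard-edged disc
(ground truth stays exact); the indentation ring displaces the mid-surface by
a Gaussian ring profile, and the returned ground-truth mean curvature of the
mid-surface is computed from its height map with the bulge-toward-normal =
positive sign convention, so indentations have H < 0.

Feature detection mirrors how leaflet positions are read off profiles:
minima via peak finding on the inverted signal (two most prominent kept, ties
broken toward the profile centre), the centring maximum between them, and per
minimum an inflection point — the position of maximal absolute gradient
between the minimum and its adjacent maximum.  "Adjacent maximum" is
ambiguous (each minimum has an inner and an outer one); both are implemented
behind `inflection_side`, default `outer`, which spans the full bilayer and
yields the leaflet-width-inclusive readout (`t + 2 sigma` on the Gaussian
model, vs `t - 2 sigma` for `inner`, with `t` the minima distance).  Which
side a given study used is generally not reported; results should state the
basis, as `GroupMeasurements` does.

**Sub-sample localisation.**  All extrema and gradient maxima are refined on
a cubic-spline interpolant of the profile, evaluated at 1/64 of the sample
spacing.  The more common 3-point parabolic refinement was measured against
the closed-form two-Gaussian oracle and found biased ~0.27 nm outward per
inflection at 0.87 nm sampling (the |gradient| peak of a Gaussian flank is
asymmetric); the spline interpolant reduces that bias to ~0.03 nm.  The
spline grid quantises readouts to ~0.014 nm, which can produce exact ties
between measurements — the Mann-Whitney implementation then switches to its
tie-corrected branch, which is the statistically appropriate behaviour.

## Segmentation meshes, leaflets, and thickness maps

Meshes come from marching cubes at iso 0.5 on the (binary or probability)
segmentation, converted to world nm with the half-voxel convention;
degenerate faces and unreferenced vertices are removed.  Note that marching
cubes on a *strictly binary* mask quantises the surface position to
half-voxel planes and overestimates curved-surface area by up to ~9%
(staircase effect); probability-valued masks with a soft edge, as produced by
learned segmentation tools and by the generator, do not suffer from this.

Vertex normals start as angle-weighted averages of incident face normals and
are optionally refined by vertex-area-weighted one-ring averaging.
Refinement helps when the surface itself is noisy; on smooth curved surfaces
extra iterations slowly bias normals, so the default is a small number (2–3).

Leaflet separation uses *local* PCA: for each vertex, the vertices within a
neighbourhood radius (sensible default: ~3x the expected bilayer envelope,
large enough to span both sheets) define a local frame whose minor axis
approximates the sheet normal; the sign of the vertex offset from the
neighbourhood centroid along that axis says on which side of the local
mid-surface it lies.  A global PCA would fail on curved membranes.  Because
the per-vertex minor-axis sign is arbitrary, labels are made consistent by
flood-fill over mesh connectivity; opposing sheets are usually *disconnected*
components, so components are then reconciled spatially — each component is
voted against already-labelled vertices using their oriented local frames.
Vertices whose neighbourhood is not two-sheet-like stay unassigned; more than
20% unassigned aborts with an error.

Thickness is the Euclidean distance between paired points on opposing
leaflets.  Candidate pairs (each point with its nearest neighbour on the
other leaflet) are sorted by ascending distance and accepted greedily,
skipping pairs that would reuse a matched point; this enforces the one-to-one
rule deterministically and is effectively optimal for well-separated sheets.
Pairs beyond `max_pair_distance` are rejected.  On segmentation data the map
measures the *envelope* thickness (leaflet separation plus the segmented
leaflet widths), so comparisons between regions — not absolute values — are
the meaningful readout; the generator's patch scenes confirm the contrast is
recovered to within a small fraction of a voxel.

## Curvature tensors

The per-face curvature tensor solves, in least squares over the three edges,
`II * proj(e) = proj(dn)` (edge and vertex-normal difference projected into
the face tangent frame) — six equations for the three unknowns of the
symmetric 2x2 tensor, solved via normal equations.  Face tensors are
transported into each incident vertex's tangent frame by rotating about the
cross product of face and vertex normals, and averaged with mixed-Voronoi
weights (cotangent Voronoi areas for acute triangles, area/2 for the obtuse
corner and area/4 otherwise, keeping all weights positive).  Principal
curvatures and directions come from the eigen-decomposition, ordered
`k1 >= k2` by signed value with direction signs fixed deterministically.
With outward/cytosol-facing normals a convex bulge has positive curvature
(sphere: H = +1/R); flipping normals negates H and leaves K unchanged.

Accuracy on analytic oracles at ~2500 vertices: median H on a sphere within
2%, median K within 4%, the Voronoi-weighted integral of K over a closed
sphere within 5% of the Gauss–Bonnet value 4*pi, and the cylinder's zero
principal curvature resolved to |k2| < 0.01/R.  The estimator degrades
gracefully with vertex jitter (median H error < 10% at 5% edge-length
jitter).

## Pose context

Pairing follows the encapsulation rule used for enclosed-particle calls: a
guest particle is assigned to its nearest host *in the same tomogram* iff the
centre distance is at most the cutoff (default 10 nm); equidistant hosts are
broken toward the lower index, making the assignment deterministic.  The
relative rotation is fixed as `R_rel = R_host^-1 R_guest`, and the plotted
quantity is a designated guest reference axis expressed in the host frame —
equivariant under global rotations of the tomogram, which the tests assert.
Both the reference axis and the comparison target axis are explicit
parameters, since axis conventions differ between processing chains.

Spherical histograms bin directions into the faces of a subdivided
icosahedron (80 near-equal-area bins at subdivision 1); a direction belongs
to the face whose three edge-plane signed distances are all non-negative.
"RTC-like" classification is a cone test: a pair is RTC-like iff its
host-frame axis lies within `theta_rtc` (default 30 degrees, inclusive
boundary) of the target axis.  Published analyses of this kind report the
resulting 2x2 contingency counts rather than the bin edges, so the summary
operations also accept printed counts directly.

## Template scoring

Scoring reimplements single-iteration alignment of particle-centred volumes:
the template is rotated over a grid (trilinear interpolation), optionally
filtered with the same binary missing wedge as the volume, both are
standardised under a mask (spherical by default), and the score is the masked
normalised cross-correlation at zero translational lag — bounded in [-1, 1]
and invariant to affine intensity changes.  Volumes are assumed centred, as
is the case for subtomograms extracted at refined positions.  The rotation
grid combines a Fibonacci covering of axis directions (one per step^2 of
solid angle) with in-plane angles over the Cn fundamental domain
`[0, 360/n)`; grid constructions differ between packages, so the size is
logged.  The missing wedge is the simplest binary model: Fourier coefficients
are kept where the (fx, fz) direction lies within the tilt half-angle of the
fx axis (tilt axis y).  Class assignment takes the template with the higher
best score (exact ties go to the first template with a logged warning), and
peak thresholding uses the z-score of a score against its population.

## Exact statistics

Fisher's exact test sums hypergeometric probability masses over all tables
with the observed margins whose probability is at most the observed table's,
with a `1 + 1e-7` relative slack absorbing floating error — the conventional
two-sided definition that reproduces standard published values.  The p-value
is computed on a canonical representative of the table's symmetry orbit, so
invariance under row/column swaps and transposition holds bitwise.  A zero
margin makes the table degenerate (p = 1, with a warning).

The Mann-Whitney U statistic is `min(U_x, U_y)` with midrank ties.  Without
ties and with both groups at most 25, the p-value is exact: twice the lower
tail of the null distribution built by the recurrence
`f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u)`, capped at 1.  Otherwise a
normal approximation with tie and continuity corrections is used; fully tied
data return p = 1.  The exact branch covers the n = 20 per-group comparisons
that motivated it, and matches brute-force enumeration over all label
assignments for every group size up to 6.

## Synthetic scenes: what they do and do not show

The generators are deterministic given their spec (random streams are derived
from the seed plus a fixed per-operation label, so one generator never shifts
another's stream).  Encapsulated guests are placed uniformly in an 8 nm ball
around their host (inside the 10 nm rule); free guests at least twice the
cutoff away, so pairing truth is unambiguous by construction.  Concentrated
relative orientations follow a von Mises–Fisher distribution with default
kappa = 200 (~4 degrees angular spread), a realistic reading of "highly
ordered" orientations, and chosen so that a concentrated population is
cleanly separable from uniform at the default 80-bin histogram: the bins have
~9 degree inradius.  Orientation-concentration tests place the vMF mode at a
bin centroid because the +z axis happens to be a vertex of the subdivided
icosahedron — any distribution centred there splits over ~6 bins regardless
of concentration.

Subtomogram fixtures are rotated copies of chirally asymmetric Gaussian-blob
templates (a two-lobe "intact particle" and a one-lobe "large subunit") with
white noise and the binary wedge.  They exercise the scoring logic, not the
imaging physics: no CTF, no reconstruction artefacts, no structural noise.
Correspondingly, passing the synthetic benchmarks demonstrates the
correctness of the estimators and decision rules — recovery of constructed
thickness contrasts, curvatures, pairings, orientations and classes — but
not performance on real tomograms, where segmentation quality, missing-wedge
anisotropy beyond the binary model, and template bias dominate.

## Problem sizes

The shipped tests and the acceptance script use 48x64x64 to 48x96x96 voxel
scenes, 2562-vertex oracle meshes, 50–150-vault populations and 40
subtomograms of 24^3 voxels on a 15-degree rotation grid (4392 rotations) —
sizes chosen so every pipeline stage is exercised end-to-end with comfortable
statistical margins while the whole suite runs in about a minute on one CPU.
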