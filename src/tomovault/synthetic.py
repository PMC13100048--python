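"""Seeded generators for every fixture the pipeline consumes.

Four families of synthetic data emulate the in-situ inputs:

* **Bilayer scenes** — two negative Gaussian troughs (cryo-ET leaflets are
  darker than background) around a mid-surface that may carry a thinned
  circular patch and an indentation ring, with the exact ground-truth
  thickness and mid-surface mean curvature returned alongside.
* **Parametric meshes** — plane / sphere / cylinder / saddle triangulations
  with optional vertex jitter and the analytic curvature evaluated at the
  final vertex positions, as oracles for the mesh curvature estimator.
* **Pose populations** — vault and ribosome pose sets with a controllable
  encapsulated fraction; encapsulated ribosomes sit inside the 10 nm pairing
  rule and draw their vault-frame orientation either uniformly or from a
  von Mises-Fisher distribution of concentration kappa.
* **Subtomograms** — rotated copies of one of two blob templates with
  Gaussian noise and an optional binary missing wedge.

All generators are deterministic given their spec: random streams are derived
from the seed together with a fixed per-operation label, so adding a call to
one generator never shifts the stream of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh as trimesh_pkg
from scipy.spatial.transform import Rotation
from scipy.stats import vonmises_fisher

from .errors import PackingError, SizingError
from .membrane_mesh import TriMesh
from .rotations import random_rotations, rotate_volume, rotation_between
from .volume_prep import DensityVolume, PoseSet, SegmentationMask
from .wedge import apply_wedge

_LABEL_BILAYER = 101
_LABEL_MESH = 102
_LABEL_POSES = 103
_LABEL_SUBTOMO = 104


# ---------------------------------------------------------------------------
# bilayer scenes
# ---------------------------------------------------------------------------

@dataclass
class BilayerSpec:
    """Geometry of a synthetic bilayer volume (lengths in nm).

    The membrane normal is the volume z axis.  ``leaflet_separation`` is the
    distance between the two leaflet mid-planes (the minima-based thickness),
    ``trough_width`` the Gaussian sigma of each leaflet trough and
    ``trough_depth`` its (positive) depth below background.  A circular patch
    of radius ``patch_radius`` centred in the field of view is thinned by
    ``patch_thinning``; an optional Gaussian ring of radius
    ``indent_ring_radius`` indents the mid-surface by ``indent_depth``.
    """

    grid_shape: tuple[int, int, int] = (48, 64, 64)   # (nz, ny, nx)
    voxel_size: float = 0.87
    leaflet_separation: float = 6.0
    trough_width: float = 1.0
    trough_depth: float = 1.0
    patch_radius: float = 0.0
    patch_thinning: float = 0.0
    indent_ring_radius: float = 0.0
    indent_depth: float = 0.0
    indent_width: float = 2.0
    noise_sd: float = 0.0
    inverted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.leaflet_separation > 0:
            raise ValueError("leaflet_separation must be positive")
        if not self.trough_width > 0:
            raise ValueError("trough_width must be positive")
        if self.patch_thinning >= self.leaflet_separation:
            raise ValueError("patch_thinning must be below leaflet_separation")
        if min(self.patch_radius, self.indent_ring_radius,
               self.indent_depth, self.noise_sd) < 0:
            raise ValueError("radii, depths and noise_sd must be >= 0")


@dataclass
class BilayerGroundTruth:
    """Per-(x, y) ground truth of a bilayer scene."""

    x: np.ndarray                 # voxel-centre x coordinates (nm)
    y: np.ndarray
    mid_z: np.ndarray             # mid-surface height map (ny, nx)
    thickness: np.ndarray         # true leaflet separation map (ny, nx)
    mean_curvature: np.ndarray    # mid-surface H map (nm^-1), indent < 0
    in_patch: np.ndarray          # boolean (ny, nx)


def make_bilayer_scene(
    spec: BilayerSpec,
) -> tuple[DensityVolume, SegmentationMask, BilayerGroundTruth]:
    """Render a bilayer volume, its segmentation mask and the ground truth."""
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size
    x = (np.arange(nx) + 0.5) * v
    y = (np.arange(ny) + 0.5) * v
    z = (np.arange(nz) + 0.5) * v
    cx, cy = nx * v / 2.0, ny * v / 2.0
    z0 = nz * v / 2.0

    extent = min(nx, ny) * v
    if spec.patch_radius > 0 and 2 * spec.patch_radius > extent:
        raise SizingError(f"patch (r={spec.patch_radius} nm) exceeds the "
                          f"{extent} nm lateral field of view")
    if spec.indent_ring_radius > 0 and \
            2 * (spec.indent_ring_radius + 2 * spec.indent_width) > extent:
        raise SizingError("indentation ring does not fit the field of view")
    z_needed = (spec.leaflet_separation / 2 + 2 * spec.trough_width
                + spec.indent_depth)
    if z_needed > nz * v / 2.0:
        raise SizingError(f"bilayer envelope ({z_needed} nm half-height) "
                          f"exceeds the grid half-height {nz * v / 2.0} nm")

    xx, yy = np.meshgrid(x, y)                        # (ny, nx)
    r = np.hypot(xx - cx, yy - cy)

    in_patch = (spec.patch_radius > 0) & (r < spec.patch_radius)
    thickness = np.full((ny, nx), spec.leaflet_separation)
    thickness[in_patch] -= spec.patch_thinning

    mid_z = np.full((ny, nx), z0)
    if spec.indent_ring_radius > 0 and spec.indent_depth > 0:
        mid_z -= spec.indent_depth * np.exp(
            -((r - spec.indent_ring_radius) ** 2) / (2 * spec.indent_width**2))

    zz = z[:, None, None]
    upper = mid_z[None] + thickness[None] / 2.0
    lower = mid_z[None] - thickness[None] / 2.0
    sig2 = 2.0 * spec.trough_width**2
    density = -spec.trough_depth * (np.exp(-((zz - upper) ** 2) / sig2)
                                    + np.exp(-((zz - lower) ** 2) / sig2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng([_LABEL_BILAYER, spec.seed])
        density = density + spec.noise_sd * rng.standard_normal(density.shape)
    if spec.inverted:
        density = -density

    # probability-style mask: 1 inside the bilayer envelope, 0 outside, with a
    # two-voxel linear edge; the ramp spans at least one full voxel interval on
    # each side of the boundary, so the marching-cubes 0.5 crossing sits on
    # the envelope surface without sub-voxel quantisation bias
    half_env = thickness[None] / 2.0 + 2.0 * spec.trough_width
    dist = np.abs(zz - mid_z[None]) - half_env
    mask = SegmentationMask(np.clip(0.5 - dist / (2.0 * v), 0.0, 1.0), v)

    # mid-surface mean curvature from the height map (bulge toward +z positive)
    fy, fx = np.gradient(mid_z, v, v)
    fyy, fyx = np.gradient(fy, v, v)
    _, fxx = np.gradient(fx, v, v)
    w2 = 1.0 + fx**2 + fy**2
    mean_curv = -((1 + fy**2) * fxx - 2 * fx * fy * fyx
                  + (1 + fx**2) * fyy) / (2.0 * w2**1.5)

    volume = DensityVolume(density, v, label="synthetic bilayer")
    truth = BilayerGroundTruth(x, y, mid_z, thickness, mean_curv, in_patch)
    return volume, mask, truth


def bilayer_profile_model(s: np.ndarray, separation: float, width: float,
                          depth: float = 1.0) -> np.ndarray:
    """Closed-form noiseless profile along the membrane normal.

    ``s`` is the signed distance from the mid-surface; the model is the sum of
    the two negative Gaussian leaflet troughs.  Used by tests as an analytic
    oracle for trough and inflection positions.
    """
    sig2 = 2.0 * width**2
    return -depth * (np.exp(-((s - separation / 2) ** 2) / sig2)
                     + np.exp(-((s + separation / 2) ** 2) / sig2))


# ---------------------------------------------------------------------------
# parametric meshes
# ---------------------------------------------------------------------------

@dataclass
class MeshSpec:
    """A parametric oracle surface: plane, sphere, cylinder or saddle.

    ``radius`` is the sphere/cylinder radius or the saddle scale ``c`` of
    ``z = (x^2 - y^2) / (2 c)``; ``extent`` the lateral size of plane, saddle
    and cylinder length.  ``jitter_sd`` displaces vertices (tangentially for
    plane/saddle, in 3D then re-projected for sphere/cylinder) so the analytic
    curvature stays exact at the final vertex positions.
    """

    kind: str = "sphere"
    radius: float = 10.0
    extent: float = 20.0
    target_vertex_count: int = 2562
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"plane", "sphere", "cylinder", "saddle"}:
            raise ValueError(f"unknown mesh kind {self.kind!r}")
        if self.kind != "plane" and not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def _grid_mesh(nu: int, nv: int) -> np.ndarray:
    """Faces of a regular (nu x nv) vertex grid, counterclockwise from +w."""
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = a + 1
            c = a + nv
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return np.array(faces)


def _principal_from_hk(h: np.ndarray, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    disc = np.sqrt(np.maximum(h**2 - k, 0.0))
    return h + disc, h - disc


def make_parametric_mesh(spec: MeshSpec) -> tuple[TriMesh, dict[str, np.ndarray]]:
    """Build the surface and return it with analytic per-vertex curvature.

    The returned dict has keys ``k1, k2, H, K`` (k1 >= k2, outward/upward
    normals, convex-positive convention).
    """
    rng = np.random.default_rng([_LABEL_MESH, spec.seed])

    if spec.kind == "sphere":
        subdiv = max(0, math.ceil(math.log(max(spec.target_vertex_count - 2, 1)
                                           / 10.0, 4)))
        ico = trimesh_pkg.creation.icosphere(subdivisions=subdiv)
        verts = np.asarray(ico.vertices) * spec.radius
        if spec.jitter_sd > 0:
            verts = verts + rng.normal(scale=spec.jitter_sd, size=verts.shape)
            verts *= spec.radius / np.linalg.norm(verts, axis=1, keepdims=True)
        normals = verts / spec.radius
        faces = np.asarray(ico.faces)
        h = np.full(len(verts), 1.0 / spec.radius)
        k = np.full(len(verts), 1.0 / spec.radius**2)

    elif spec.kind == "cylinder":
        n_side = max(8, round(math.sqrt(spec.target_vertex_count)))
        theta = np.linspace(0, 2 * np.pi, n_side, endpoint=False)
        zs = np.linspace(-spec.extent / 2, spec.extent / 2, n_side)
        tt, zz = np.meshgrid(theta, zs)
        verts = np.column_stack([spec.radius * np.cos(tt).ravel(),
                                 spec.radius * np.sin(tt).ravel(),
                                 zz.ravel()])
        if spec.jitter_sd > 0:
            verts = verts + rng.normal(scale=spec.jitter_sd, size=verts.shape)
            radial = np.linalg.norm(verts[:, :2], axis=1, keepdims=True)
            verts[:, :2] *= spec.radius / radial
        # closed in theta: build grid faces then wrap the seam
        faces = []
        for i in range(n_side - 1):          # rows of constant z
            for j in range(n_side):
                a = i * n_side + j
                b = i * n_side + (j + 1) % n_side
                c = a + n_side
                d = b + n_side
                faces.append([a, b, d])
                faces.append([a, d, c])
        faces = np.array(faces)
        normals = np.column_stack([verts[:, 0], verts[:, 1],
                                   np.zeros(len(verts))]) / spec.radius
        h = np.full(len(verts), 0.5 / spec.radius)
        k = np.zeros(len(verts))

    else:  # plane or saddle
        n_side = max(4, round(math.sqrt(spec.target_vertex_count)))
        coords = np.linspace(-spec.extent / 2, spec.extent / 2, n_side)
        xx, yy = np.meshgrid(coords, coords)
        xv, yv = xx.ravel(), yy.ravel()
        if spec.jitter_sd > 0:
            xv = xv + rng.normal(scale=spec.jitter_sd, size=xv.shape)
            yv = yv + rng.normal(scale=spec.jitter_sd, size=yv.shape)
        faces = _grid_mesh(n_side, n_side)
        if spec.kind == "plane":
            verts = np.column_stack([xv, yv, np.zeros_like(xv)])
            normals = np.tile([0.0, 0.0, 1.0], (len(verts), 1))
            h = np.zeros(len(verts))
            k = np.zeros(len(verts))
        else:
            c = spec.radius
            zv = (xv**2 - yv**2) / (2.0 * c)
            verts = np.column_stack([xv, yv, zv])
            fx, fy = xv / c, -yv / c
            w2 = 1.0 + fx**2 + fy**2
            normals = np.column_stack([-fx, -fy, np.ones_like(fx)]) \
                / np.sqrt(w2)[:, None]
            h = (fx**2 - fy**2) / (2.0 * c * w2**1.5)
            k = -1.0 / (c**2 * w2**2)

    k1, k2 = _principal_from_hk(h, k)
    mesh = TriMesh(verts, faces, vertex_normals=normals)
    # consistency check: face windings must agree with the analytic normals
    face_n, _ = mesh.face_normals_and_areas()
    agree = np.einsum("ij,ij->i", face_n,
                      normals[mesh.faces].mean(axis=1))
    if np.median(agree) < 0:
        mesh = TriMesh(verts, faces[:, ::-1], vertex_normals=normals)
    return mesh, {"k1": k1, "k2": k2, "H": h, "K": k}


# ---------------------------------------------------------------------------
# pose populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """A vault/ribosome pose population with known encapsulation truth.

    Encapsulated ribosomes are placed uniformly in a ball of radius
    ``encapsulation_radius`` (default 8 nm, inside the 10 nm pairing rule)
    around their vault centre; free ribosomes are kept at least twice the
    pairing cutoff away from every vault.  In ``concentrated`` mode the
    ribosome reference axis, expressed in the vault frame, follows a von
    Mises-Fisher distribution of concentration ``kappa`` about
    ``target_axis``; ``uniform`` mode draws the relative rotation uniformly.
    """

    n_vaults_cytosolic: int = 50
    n_vaults_membrane: int = 0
    encapsulation_fraction_cytosolic: float = 0.1
    encapsulation_fraction_membrane: float = 0.0
    n_free_ribosomes: int | None = None
    relative_orientation_mode: str = "concentrated"
    kappa: float = 200.0
    box_extent: float = 800.0
    min_separation: float = 80.0
    encapsulation_radius: float = 8.0
    pairing_cutoff: float = 10.0
    reference_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    target_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_vaults_cytosolic, self.n_vaults_membrane) < 0:
            raise ValueError("vault counts must be >= 0")
        for frac in (self.encapsulation_fraction_cytosolic,
                     self.encapsulation_fraction_membrane):
            if not 0 <= frac <= 1:
                raise ValueError("encapsulation fractions must be in [0, 1]")
        if self.relative_orientation_mode not in {"concentrated", "uniform"}:
            raise ValueError("mode must be 'concentrated' or 'uniform'")
        if self.relative_orientation_mode == "concentrated" and not self.kappa > 0:
            raise ValueError("kappa must be positive in concentrated mode")
        if not self.encapsulation_radius < self.pairing_cutoff:
            raise ValueError("encapsulation_radius must be below the cutoff")


def _pack_points(rng: np.random.Generator, n: int, box: float,
                 min_sep: float, margin: float) -> np.ndarray:
    if min_sep <= 0:
        return rng.uniform(margin, box - margin, size=(n, 3))
    points: list[np.ndarray] = []
    tries = 0
    limit = 2000 * max(n, 1)
    while len(points) < n:
        if tries > limit:
            raise PackingError(
                f"could not place {n} points with separation {min_sep} nm "
                f"in a {box} nm box after {limit} tries")
        tries += 1
        cand = rng.uniform(margin, box - margin, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in points):
            points.append(cand)
    return np.array(points).reshape(n, 3)


def _spin_about(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(angle * np.asarray(axis, dtype=float)).as_matrix()


def make_pose_population(
    spec: PopulationSpec,
) -> tuple[PoseSet, PoseSet, pd.DataFrame]:
    """Generate vault and ribosome pose sets plus a per-ribosome truth table.

    The truth table has one row per ribosome with columns ``encapsulated``
    (bool), ``vault_index`` (-1 for free ribosomes), ``vault_class`` and
    ``rel_angle_deg`` (angle between the vault-frame reference axis and the
    target axis; NaN for free ribosomes).
    """
    rng = np.random.default_rng([_LABEL_POSES, spec.seed])
    ref = np.asarray(spec.reference_axis, dtype=float)
    ref = ref / np.linalg.norm(ref)
    target = np.asarray(spec.target_axis, dtype=float)
    target = target / np.linalg.norm(target)

    n_vaults = spec.n_vaults_cytosolic + spec.n_vaults_membrane
    margin = spec.pairing_cutoff + spec.encapsulation_radius
    vault_pos = _pack_points(rng, n_vaults, spec.box_extent,
                             spec.min_separation, margin)
    vault_rot = random_rotations(rng, n_vaults) if n_vaults else \
        np.zeros((0, 3, 3))
    vault_classes = (["cytosolic"] * spec.n_vaults_cytosolic
                     + ["membrane"] * spec.n_vaults_membrane)

    n_enc_cyt = math.floor(spec.encapsulation_fraction_cytosolic
                           * spec.n_vaults_cytosolic)
    n_enc_mem = math.floor(spec.encapsulation_fraction_membrane
                           * spec.n_vaults_membrane)
    enc_vaults = list(rng.choice(spec.n_vaults_cytosolic, n_enc_cyt,
                                 replace=False)) if n_enc_cyt else []
    enc_vaults += list(spec.n_vaults_cytosolic
                       + rng.choice(spec.n_vaults_membrane, n_enc_mem,
                                    replace=False)) if n_enc_mem else []
    enc_vaults = sorted(int(i) for i in enc_vaults)

    rib_pos: list[np.ndarray] = []
    rib_rot: list[np.ndarray] = []
    truth_rows: list[dict] = []

    for vi in enc_vaults:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = spec.encapsulation_radius * rng.uniform() ** (1 / 3)
        rib_pos.append(vault_pos[vi] + radius * direction)
        if spec.relative_orientation_mode == "concentrated":
            axis_in_vault = vonmises_fisher(target, spec.kappa).rvs(
                1, random_state=rng)[0]
            r_rel = rotation_between(ref, axis_in_vault) @ _spin_about(
                ref, rng.uniform(0, 2 * np.pi))
        else:
            r_rel = random_rotations(rng, 1)[0]
            axis_in_vault = r_rel @ ref
        rib_rot.append(vault_rot[vi] @ r_rel)
        truth_rows.append({
            "encapsulated": True, "vault_index": vi,
            "vault_class": vault_classes[vi],
            "rel_angle_deg": float(np.degrees(np.arccos(
                np.clip(axis_in_vault @ target, -1.0, 1.0)))),
        })

    n_free = (n_vaults if spec.n_free_ribosomes is None
              else spec.n_free_ribosomes)
    tries, limit = 0, 2000 * max(n_free, 1)
    while sum(row["encapsulated"] is False for row in truth_rows) < n_free:
        if tries > limit:
            raise PackingError("could not place free ribosomes away from vaults")
        tries += 1
        cand = rng.uniform(0, spec.box_extent, size=3)
        if n_vaults and np.min(np.linalg.norm(
                vault_pos - cand, axis=1)) < 2 * spec.pairing_cutoff:
            continue
        rib_pos.append(cand)
        rib_rot.append(random_rotations(rng, 1)[0])
        truth_rows.append({"encapsulated": False, "vault_index": -1,
                           "vault_class": "", "rel_angle_deg": float("nan")})

    vaults = PoseSet(vault_pos, vault_rot, class_labels=vault_classes)
    n_rib = len(rib_pos)
    ribosomes = PoseSet(
        np.array(rib_pos).reshape(n_rib, 3),
        np.array(rib_rot).reshape(n_rib, 3, 3),
        class_labels=["ribosome"] * n_rib)
    truth = pd.DataFrame(truth_rows)
    truth.index.name = "ribosome_index"
    return vaults, ribosomes, truth


# ---------------------------------------------------------------------------
# subtomograms
# ---------------------------------------------------------------------------

@dataclass
class Subtomogram:
    """One synthetic particle volume with its generation truth."""

    volume: DensityVolume
    true_class: str
    true_rotation: np.ndarray


def make_blob_template(shape: int, voxel_size: float,
                       blobs: list[tuple[tuple[float, float, float], float, float]],
                       label: str = "") -> DensityVolume:
    """A template volume as a sum of Gaussian blobs.

    Each blob is ``(centre offset from the box centre in nm (x, y, z),
    sigma nm, amplitude)``.
    """
    coords = (np.arange(shape) + 0.5) * voxel_size - shape * voxel_size / 2.0
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    data = np.zeros((shape, shape, shape))
    for (cx, cy, cz), sigma, amp in blobs:
        data += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2
                               + (zz - cz) ** 2) / (2 * sigma**2))
    return DensityVolume(data, voxel_size, label=label)


def make_ribosome_like_templates(
    shape: int = 24, voxel_size: float = 1.0,
) -> tuple[DensityVolume, DensityVolume]:
    """Two distinguishable, chirally asymmetric blob templates.

    Template A mimics an intact two-subunit particle (large body, small
    head, exit lobe); template B the large subunit alone with one lobe.
    Both lack any rotational symmetry so that best-fit orientations are
    unambiguous.
    """
    a = make_blob_template(shape, voxel_size, [
        ((0.0, 0.0, -1.0), 3.2, 1.0),
        ((0.0, 4.2, 1.8), 2.2, 0.9),
        ((3.4, -1.5, 1.0), 1.4, 0.8),
    ], label="template A (80S-like)")
    b = make_blob_template(shape, voxel_size, [
        ((0.0, 0.0, -1.0), 3.2, 1.0),
        ((2.8, 1.8, 1.6), 1.5, 0.8),
    ], label="template B (60S-like)")
    return a, b


def make_subtomograms(
    template_a: DensityVolume,
    template_b: DensityVolume,
    n: int,
    noise_sd: float = 0.0,
    wedge_halfangle: float = 90.0,
    seed: int = 0,
    rotation_pool: np.ndarray | None = None,
    n_class_a: int | None = None,
) -> list[Subtomogram]:
    """Rotated-template subtomograms with noise and an optional missing wedge.

    ``rotation_pool`` (K, 3, 3), when given, restricts true rotations to that
    set (e.g. a rotation grid); otherwise rotations are uniform.  ``n_class_a``
    fixes how many volumes come from template A (default: half, rounded up);
    class order is shuffled deterministically.
    """
    if template_a.data.shape != template_b.data.shape:
        raise ValueError("templates must have identical shapes")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([_LABEL_SUBTOMO, seed])
    n_a = (n + 1) // 2 if n_class_a is None else n_class_a
    labels = np.array(["A"] * n_a + ["B"] * (n - n_a))
    rng.shuffle(labels)

    out: list[Subtomogram] = []
    for i in range(n):
        if rotation_pool is not None:
            rot = np.asarray(rotation_pool)[rng.integers(len(rotation_pool))]
        else:
            rot = random_rotations(rng, 1)[0]
        source = template_a if labels[i] == "A" else template_b
        data = rotate_volume(source.data, rot)
        if wedge_halfangle < 90:
            data = apply_wedge(data, wedge_halfangle)
        if noise_sd > 0:
            data = data + noise_sd * rng.standard_normal(data.shape)
        out.append(Subtomogram(
            DensityVolume(data, source.voxel_size, label=f"subtomo_{i}"),
            str(labels[i]), rot))
    return out
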