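"""Shared fixtures: expensive synthetic scenes are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import tomovault as tv

VOXEL = 0.87  # nm, the 4x-binned tomogram sampling used throughout


@pytest.fixture(scope="session")
def flat_bilayer_scene():
    """Noiseless flat bilayer: t = 6 nm, sigma = 1 nm, 0.87 nm voxels."""
    spec = tv.BilayerSpec(grid_shape=(48, 64, 64), voxel_size=VOXEL)
    return spec, *tv.make_bilayer_scene(spec)


@pytest.fixture(scope="session")
def patch_scene():
    """Bilayer with a 15 nm patch thinned by 1 nm."""
    spec = tv.BilayerSpec(grid_shape=(48, 96, 96), voxel_size=VOXEL,
                          patch_radius=15.0, patch_thinning=1.0)
    return spec, *tv.make_bilayer_scene(spec)


@pytest.fixture(scope="session")
def patch_thickness_map(patch_scene):
    """Leaflet thickness map of the patch scene (full mesh pipeline)."""
    _, _, mask, _ = patch_scene
    mesh = tv.refine_normals(tv.mask_to_mesh(mask), iterations=2)
    leaflets = tv.separate_leaflets(mesh, neighborhood_radius=18.0)
    return tv.compute_thickness_map(leaflets, max_pair_distance=15.0)


@pytest.fixture(scope="session")
def sphere_mesh():
    """2562-vertex sphere of radius 10 nm with analytic outward normals."""
    return tv.make_parametric_mesh(
        tv.MeshSpec(kind="sphere", radius=10.0, target_vertex_count=2562))


@pytest.fixture(scope="session")
def rotation_grid_15():
    return tv.rotation_grid(15.0)


@pytest.fixture(scope="session")
def template_pair():
    return tv.make_ribosome_like_templates()


@pytest.fixture(scope="session")
def template_benchmark(template_pair, rotation_grid_15):
    """40 high-SNR subtomograms (30 A / 10 B) scored against both templates."""
    tpl_a, tpl_b = template_pair
    subs = tv.make_subtomograms(
        tpl_a, tpl_b, n=40, noise_sd=0.3, seed=17,
        rotation_pool=rotation_grid_15.rotations, n_class_a=30)
    volumes = [s.volume for s in subs]
    res_a = tv.score_many(volumes, tpl_a, rotation_grid_15)
    res_b = tv.score_many(volumes, tpl_b, rotation_grid_15)
    return subs, res_a, res_b


def volume_centre(volume: tv.DensityVolume) -> np.ndarray:
    nz, ny, nx = volume.data.shape
    return volume.origin + np.array([nx, ny, nz]) * volume.voxel_size / 2.0
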