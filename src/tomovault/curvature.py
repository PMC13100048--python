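"""Per-vertex principal curvatures on irregular triangular meshes.

The estimator fits, on every face, a 2x2 symmetric curvature tensor (the
second fundamental form expressed in the face tangent frame) by least squares
over the three edges: for edge ``e`` with endpoint-normal difference ``dn``,
``II @ proj(e) ~= proj(dn)``.  Face tensors are transported into each incident
vertex's tangent frame (rotation about the cross product of the two normals)
and averaged with mixed-Voronoi-area weights; principal curvatures and
directions come from the eigen-decomposition of the accumulated tensor.

Sign convention: with normals pointing toward the reference (cytosol-facing)
side, a surface bulging toward its normal has positive curvature, so a sphere
with outward normals has H = +1/R and an indentation has negative H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .membrane_mesh import TriMesh


@dataclass
class CurvatureField:
    """Per-vertex curvature: k1 >= k2 (nm^-1), directions, H, K, Voronoi area.

    Vertices without incident faces or with non-finite normals are flagged in
    ``undefined`` and carry NaN values.
    """

    k1: np.ndarray
    k2: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    mean: np.ndarray
    gaussian: np.ndarray
    voronoi_area: np.ndarray
    undefined: np.ndarray


def _require_normals(mesh: TriMesh) -> np.ndarray:
    if mesh.vertex_normals is None:
        raise ValueError("mesh has no vertex normals; run refine_normals first")
    return np.asarray(mesh.vertex_normals, dtype=float)


def _face_frames(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal tangent frame (u, v, n) per face."""
    tri = mesh.vertices[mesh.faces]
    e2 = tri[:, 1] - tri[:, 0]
    n, areas = mesh.face_normals_and_areas()
    if np.any(areas <= 1e-12):
        raise ValueError("mesh contains (near-)zero-area faces")
    u = e2 / np.linalg.norm(e2, axis=1, keepdims=True)
    v = np.cross(n, u)
    return u, v, n


def _face_tensors(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares curvature tensor of every face.

    Returns (tensors (F,2,2), u, v, n face frames).
    """
    normals = _require_normals(mesh)
    u, v, n = _face_frames(mesh)
    tri = mesh.vertices[mesh.faces]
    tri_n = normals[mesh.faces]

    # edge i is opposite corner i
    edges = np.stack([tri[:, 2] - tri[:, 1],
                      tri[:, 0] - tri[:, 2],
                      tri[:, 1] - tri[:, 0]], axis=1)           # (F,3,3)
    dnorm = np.stack([tri_n[:, 2] - tri_n[:, 1],
                      tri_n[:, 0] - tri_n[:, 2],
                      tri_n[:, 1] - tri_n[:, 0]], axis=1)

    eu = np.einsum("fij,fj->fi", edges, u)                       # (F,3)
    ev = np.einsum("fij,fj->fi", edges, v)
    du = np.einsum("fij,fj->fi", dnorm, u)
    dv = np.einsum("fij,fj->fi", dnorm, v)

    # unknowns x = (a, b, c) of II = [[a, b], [b, c]]; per edge two equations:
    #   a*eu + b*ev = du
    #   b*eu + c*ev = dv
    zeros = np.zeros_like(eu)
    rows_a = np.stack([eu, ev, zeros], axis=2)                   # (F,3,3)
    rows_b = np.stack([zeros, eu, ev], axis=2)
    design = np.concatenate([rows_a, rows_b], axis=1)            # (F,6,3)
    rhs = np.concatenate([du, dv], axis=1)                       # (F,6)

    ata = np.einsum("fei,fej->fij", design, design)
    atb = np.einsum("fei,fe->fi", design, rhs)
    sol = np.linalg.solve(ata, atb[..., None])[..., 0]           # (F,3)

    tensors = np.empty((len(sol), 2, 2))
    tensors[:, 0, 0] = sol[:, 0]
    tensors[:, 0, 1] = tensors[:, 1, 0] = sol[:, 1]
    tensors[:, 1, 1] = sol[:, 2]
    return tensors, u, v, n


def face_curvature_tensor(mesh: TriMesh, face: int) -> np.ndarray:
    """Curvature tensor of one face in its own tangent frame (2x2 symmetric)."""
    sub = TriMesh(mesh.vertices, mesh.faces[face:face + 1],
                  mesh.vertex_normals)
    return _face_tensors(sub)[0][0]


def _mixed_voronoi_corner_areas(mesh: TriMesh) -> np.ndarray:
    """Mixed Voronoi area contribution of each face corner, (F, 3).

    Non-obtuse triangles use the cotangent Voronoi formula; obtuse ones give
    half the face area to the obtuse corner and a quarter to the others, which
    keeps all weights positive.
    """
    tri = mesh.vertices[mesh.faces]
    _, face_areas = mesh.face_normals_and_areas()
    out = np.empty((len(tri), 3))

    edge_vec = [tri[:, (i + 1) % 3] - tri[:, i] for i in range(3)]
    lengths2 = [np.einsum("ij,ij->i", e, e) for e in edge_vec]

    cos = np.empty((len(tri), 3))
    for i in range(3):
        a = tri[:, (i + 1) % 3] - tri[:, i]
        b = tri[:, (i + 2) % 3] - tri[:, i]
        cos[:, i] = np.einsum("ij,ij->i", a, b) / np.sqrt(
            np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    angles = np.arccos(np.clip(cos, -1.0, 1.0))
    obtuse_corner = np.argmax(angles, axis=1)
    is_obtuse = angles.max(axis=1) > np.pi / 2

    cot = 1.0 / np.tan(angles)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        # |edge i->j|^2 cot(angle at k) + |edge i->k|^2 cot(angle at j)
        lij = lengths2[i]                       # edge from corner i to j
        lik = lengths2[k]                       # edge from corner k to i
        out[:, i] = (lij * cot[:, k] + lik * cot[:, j]) / 8.0

    for i in range(3):
        sel = is_obtuse & (obtuse_corner == i)
        out[sel, i] = face_areas[sel] / 2.0
        for other in range(3):
            if other != i:
                out[sel, other] = face_areas[sel] / 4.0
    return out


def _rotate_about(vecs: np.ndarray, axis: np.ndarray, cos_t: np.ndarray,
                  sin_t: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of ``vecs`` about unit ``axis`` (batched)."""
    k_dot_v = np.einsum("fi,fi->f", axis, vecs)[:, None]
    return (vecs * cos_t[:, None]
            + np.cross(axis, vecs) * sin_t[:, None]
            + axis * k_dot_v * (1.0 - cos_t[:, None]))


def _vertex_frames(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(normals), 1))
    ref[np.abs(normals[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    u = np.cross(normals, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(normals, u)
    return u, v


def accumulate_vertex_tensors(
    mesh: TriMesh,
    face_tensors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average face tensors at vertices with mixed-Voronoi-area weights.

    Each face tensor is re-expressed in the incident vertex's tangent frame by
    rotating the face frame about the cross product of face and vertex normals
    before projection.  Returns (vertex tensors (N,2,2), Voronoi areas (N,),
    undefined-vertex mask).
    """
    normals = _require_normals(mesh)
    if face_tensors is None:
        face_tensors, fu, fv, fn = _face_tensors(mesh)
    else:
        fu, fv, fn = _face_frames(mesh)
    corner_areas = _mixed_voronoi_corner_areas(mesh)
    vert_u, vert_v = _vertex_frames(np.nan_to_num(normals, nan=1.0))

    n_vert = mesh.n_vertices
    acc = np.zeros((n_vert, 2, 2))
    weights = np.zeros(n_vert)

    for corner in range(3):
        vidx = mesh.faces[:, corner]
        n_p = normals[vidx]
        axis = np.cross(fn, n_p)
        sin_t = np.linalg.norm(axis, axis=1)
        cos_t = np.einsum("fi,fi->f", fn, n_p)
        safe = sin_t > 1e-12
        axis_unit = np.where(safe[:, None], axis / np.where(
            safe, sin_t, 1.0)[:, None], np.array([1.0, 0.0, 0.0]))
        cos_r = np.where(safe, cos_t, 1.0)
        sin_r = np.where(safe, sin_t, 0.0)
        fu_rot = _rotate_about(fu, axis_unit, cos_r, sin_r)
        fv_rot = _rotate_about(fv, axis_unit, cos_r, sin_r)

        # coordinates of the vertex basis in the rotated face basis
        up = np.stack([np.einsum("fi,fi->f", vert_u[vidx], fu_rot),
                       np.einsum("fi,fi->f", vert_u[vidx], fv_rot)], axis=1)
        vp = np.stack([np.einsum("fi,fi->f", vert_v[vidx], fu_rot),
                       np.einsum("fi,fi->f", vert_v[vidx], fv_rot)], axis=1)

        t_uu = np.einsum("fi,fij,fj->f", up, face_tensors, up)
        t_uv = np.einsum("fi,fij,fj->f", up, face_tensors, vp)
        t_vv = np.einsum("fi,fij,fj->f", vp, face_tensors, vp)

        w = corner_areas[:, corner]
        np.add.at(acc[:, 0, 0], vidx, w * t_uu)
        np.add.at(acc[:, 0, 1], vidx, w * t_uv)
        np.add.at(acc[:, 1, 0], vidx, w * t_uv)
        np.add.at(acc[:, 1, 1], vidx, w * t_vv)
        np.add.at(weights, vidx, w)

    undefined = (weights <= 0) | ~np.isfinite(normals).all(axis=1)
    safe_w = np.where(undefined, 1.0, weights)
    tensors = acc / safe_w[:, None, None]
    tensors[undefined] = np.nan
    return tensors, weights, undefined


def curvature_field(mesh: TriMesh) -> CurvatureField:
    """Principal/mean/Gaussian curvature at every vertex of an oriented mesh."""
    normals = _require_normals(mesh)
    finite = np.isfinite(normals).all(axis=1)
    if not finite.any():
        raise ValueError("no vertex has a finite normal")
    tensors, areas, undefined = accumulate_vertex_tensors(mesh)

    n_vert = mesh.n_vertices
    k1 = np.full(n_vert, np.nan)
    k2 = np.full(n_vert, np.nan)
    e1 = np.full((n_vert, 3), np.nan)
    e2 = np.full((n_vert, 3), np.nan)

    ok = ~undefined
    evals, evecs = np.linalg.eigh(tensors[ok])       # ascending eigenvalues
    k1[ok] = evals[:, 1]
    k2[ok] = evals[:, 0]

    vert_u, vert_v = _vertex_frames(np.nan_to_num(normals, nan=1.0))
    dir1 = (evecs[:, 0, 1, None] * vert_u[ok] + evecs[:, 1, 1, None] * vert_v[ok])
    dir2 = (evecs[:, 0, 0, None] * vert_u[ok] + evecs[:, 1, 0, None] * vert_v[ok])
    for d in (dir1, dir2):
        # deterministic sign: first component of largest magnitude positive
        lead = d[np.arange(len(d)), np.abs(d).argmax(axis=1)]
        d *= np.where(lead < 0, -1.0, 1.0)[:, None]
    e1[ok] = dir1
    e2[ok] = dir2

    return CurvatureField(k1=k1, k2=k2, e1=e1, e2=e2,
                          mean=0.5 * (k1 + k2), gaussian=k1 * k2,
                          voronoi_area=areas, undefined=undefined)
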