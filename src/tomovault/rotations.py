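"""Rotation helpers shared by the generators and the template scorer."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

#: permutation between world (x, y, z) and array (z, y, x) axes
_FLIP = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


def random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """``n`` rotations drawn uniformly from SO(3) (random unit quaternions)."""
    quat = rng.normal(size=(n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return Rotation.from_quat(quat).as_matrix()


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector ``a`` onto unit vector ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cross = np.cross(a, b)
    dot = float(a @ b)
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # antiparallel: rotate by pi about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = cross / np.linalg.norm(cross)
    angle = np.arctan2(np.linalg.norm(cross), dot)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def rotation_angle_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotations."""
    rel = r1.T @ r2
    cos = (np.trace(rel) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def rotate_volume(data: np.ndarray, rotation: np.ndarray,
                  order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Rotate a ``[z, y, x]`` volume about its centre by a world rotation.

    The output value at world position x is the input value at R^-1 x, i.e.
    the object is rotated by R.  Trilinear interpolation by default.
    """
    r_inv_idx = _FLIP @ np.asarray(rotation).T @ _FLIP
    centre = (np.array(data.shape) - 1) / 2.0
    offset = centre - r_inv_idx @ centre
    return ndimage.affine_transform(data, r_inv_idx, offset=offset,
                                    order=order, mode="constant", cval=cval)
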