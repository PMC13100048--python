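"""Volume and pose containers, MRC / pose-table I/O, and tomogram preprocessing.

Conventions used throughout the package:

* Volumes are numpy arrays indexed ``data[z, y, x]`` (the usual MRC slice
  order); all physical lengths are nanometres internally, with angstroms
  accepted and converted at the file boundary.
* Voxel indices are 0-based and the world position of the *centre* of voxel
  ``i`` along an axis is ``origin + (i + 0.5) * voxel_size``.  The half-voxel
  convention keeps masks, meshes and poses aligned exactly.
* Particle rotations are stored as proper 3x3 matrices mapping the particle
  frame into the world frame.  On-disk Euler angles default to intrinsic ZXZ
  in degrees, the dominant subtomogram-averaging convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    AnisotropicVoxelError,
    FilterParameterError,
    PoseTableError,
    VolumeIOError,
)

A_PER_NM = 10.0

POSE_TABLE_COLUMNS = [
    "tomogram_id", "x", "y", "z", "phi", "theta", "psi", "score", "class",
]

#: accepted on-disk Euler conventions (intrinsic, degrees)
EULER_CONVENTIONS = {"zxz": "ZXZ", "zyz": "ZYZ", "zyx": "ZYX"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DensityVolume:
    """A 3D intensity grid with physical voxel size.

    Parameters
    ----------
    data
        Array indexed ``[z, y, x]``, arbitrary intensity units.
    voxel_size
        Isotropic voxel edge length in nm.
    origin
        World position (nm, xyz order) of the corner of voxel ``(0, 0, 0)``;
        the voxel centre sits half a voxel further along each axis.
    label
        Free-text description.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """World xyz (nm) -> fractional array index (z, y, x order)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx_xyz = (pts - self.origin) / self.voxel_size - 0.5
        return idx_xyz[:, ::-1]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis (x, y, z)."""
        nz, ny, nx = self.data.shape
        ax = [self.origin[i] + (np.arange(n) + 0.5) * self.voxel_size
              for i, n in enumerate((nx, ny, nz))]
        return ax[0], ax[1], ax[2]


@dataclass
class SegmentationMask(DensityVolume):
    """A membrane segmentation: values in [0, 1] on the volume grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("segmentation mask values must lie in [0, 1]")


@dataclass
class Pose:
    """One particle: world position (nm) and particle->world rotation."""

    position: np.ndarray
    rotation: np.ndarray
    score: float = float("nan")
    class_label: str = ""
    tomogram_id: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("pose position must be finite")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6 or not math.isclose(
            float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-6
        ):
            raise ValueError("rotation must be proper orthonormal (det +1)")


class PoseSet:
    """An ordered collection of particle poses sharing one angle convention."""

    def __init__(
        self,
        positions: np.ndarray,
        rotations: np.ndarray,
        scores: np.ndarray | None = None,
        class_labels: Sequence[str] | None = None,
        tomogram_ids: Sequence[str] | None = None,
        voxel_size: float = 1.0,
        convention: str = "zxz",
    ) -> None:
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.rotations = np.asarray(rotations, dtype=float).reshape(n, 3, 3)
        self.scores = (np.full(n, np.nan) if scores is None
                       else np.asarray(scores, dtype=float))
        self.class_labels = (["" for _ in range(n)] if class_labels is None
                             else list(class_labels))
        self.tomogram_ids = (["tomo_0" for _ in range(n)] if tomogram_ids is None
                             else list(tomogram_ids))
        if convention not in EULER_CONVENTIONS:
            raise PoseTableError(
                f"unknown Euler convention {convention!r}; "
                f"expected one of {sorted(EULER_CONVENTIONS)}")
        self.voxel_size = float(voxel_size)
        self.convention = convention

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> Pose:
        return Pose(self.positions[i], self.rotations[i], self.scores[i],
                    self.class_labels[i], self.tomogram_ids[i])

    def __iter__(self) -> Iterator[Pose]:
        return (self[i] for i in range(len(self)))


# ---------------------------------------------------------------------------
# MRC I/O (via gemmi)
# ---------------------------------------------------------------------------

def write_volume(volume: DensityVolume, path: str | Path) -> None:
    """Write a volume as an MRC/CCP4 map (voxel size and origin in the header)."""
    nz, ny, nx = volume.data.shape
    vx_a = volume.voxel_size * A_PER_NM
    grid = gemmi.FloatGrid(
        np.ascontiguousarray(volume.data.transpose(2, 1, 0), dtype=np.float32))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    grid.set_unit_cell(gemmi.UnitCell(nx * vx_a, ny * vx_a, nz * vx_a,
                                      90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), volume.origin * A_PER_NM):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def _read_ccp4(path: str | Path) -> gemmi.Ccp4Map:
    try:
        return gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise VolumeIOError(f"cannot parse MRC file {path!s}: {exc}") from exc


def read_volume(path: str | Path, label: str = "") -> DensityVolume:
    """Read an MRC/CCP4 map into a :class:`DensityVolume` (nm units)."""
    ccp4 = _read_ccp4(path)
    spacing = np.array(ccp4.grid.spacing, dtype=float)  # angstrom, xyz
    if spacing.max() <= 0:
        raise VolumeIOError(f"{path!s}: non-positive voxel size in header")
    if (spacing.max() - spacing.min()) / spacing.max() > 1e-3:
        raise AnisotropicVoxelError(
            f"{path!s}: anisotropic voxel size {spacing} A is unsupported")
    data = np.array(ccp4.grid, copy=True).transpose(2, 1, 0).astype(np.float64)
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)]) / A_PER_NM
    return DensityVolume(data=data, voxel_size=float(spacing.mean()) / A_PER_NM,
                         origin=origin, label=label or str(path))


def read_mask(path: str | Path) -> SegmentationMask:
    vol = read_volume(path)
    return SegmentationMask(np.clip(vol.data, 0.0, 1.0), vol.voxel_size,
                            vol.origin, vol.label)


# ---------------------------------------------------------------------------
# pose-table I/O
# ---------------------------------------------------------------------------

def euler_to_matrix(phi: float, theta: float, psi: float,
                    convention: str = "zxz") -> np.ndarray:
    """Intrinsic Euler triple (degrees) -> particle->world rotation matrix."""
    seq = EULER_CONVENTIONS[convention]
    return Rotation.from_euler(seq, [phi, theta, psi], degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray, convention: str = "zxz") -> np.ndarray:
    seq = EULER_CONVENTIONS[convention]
    return Rotation.from_matrix(matrix).as_euler(seq, degrees=True)


def read_pose_table(path: str | Path, convention: str = "zxz",
                    voxel_size: float = 1.0) -> PoseSet:
    """Read a tab-separated motive-list table.

    Expected header: ``tomogram_id x y z phi theta psi score class`` with
    positions in voxels and intrinsic Euler angles in degrees.
    """
    if convention not in EULER_CONVENTIONS:
        raise PoseTableError(
            f"unknown Euler convention {convention!r}; "
            f"expected one of {sorted(EULER_CONVENTIONS)}")
    df = pd.read_csv(path, sep="\t", dtype={"tomogram_id": str, "class": str})
    missing = [c for c in POSE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PoseTableError(
            f"{path!s}: missing columns {missing}; "
            f"expected {POSE_TABLE_COLUMNS}")
    angles = df[["phi", "theta", "psi"]].to_numpy(dtype=float)
    seq = EULER_CONVENTIONS[convention]
    rots = Rotation.from_euler(seq, angles, degrees=True).as_matrix() \
        if len(df) else np.zeros((0, 3, 3))
    positions = df[["x", "y", "z"]].to_numpy(dtype=float) * voxel_size
    return PoseSet(positions, rots, df["score"].to_numpy(dtype=float),
                   df["class"].fillna("").tolist(),
                   df["tomogram_id"].tolist(), voxel_size, convention)


def write_pose_table(poses: PoseSet, path: str | Path,
                     convention: str | None = None) -> None:
    convention = convention or poses.convention
    if convention not in EULER_CONVENTIONS:
        raise PoseTableError(f"unknown Euler convention {convention!r}")
    seq = EULER_CONVENTIONS[convention]
    if len(poses):
        angles = Rotation.from_matrix(poses.rotations).as_euler(seq, degrees=True)
    else:
        angles = np.zeros((0, 3))
    df = pd.DataFrame({
        "tomogram_id": poses.tomogram_ids,
        "x": poses.positions[:, 0] / poses.voxel_size,
        "y": poses.positions[:, 1] / poses.voxel_size,
        "z": poses.positions[:, 2] / poses.voxel_size,
        "phi": angles[:, 0], "theta": angles[:, 1], "psi": angles[:, 2],
        "score": poses.scores, "class": poses.class_labels,
    })
    # default float repr is round-trip exact, so read -> write -> read is stable
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------

def _radial_frequency(shape: tuple[int, ...], voxel_size: float) -> np.ndarray:
    """|f| in cycles/nm on the FFT grid of ``shape``."""
    freqs = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij")
    return np.sqrt(fx**2 + fy**2 + fz**2)


def _apply_radial_filter(volume: DensityVolume, response: np.ndarray) -> DensityVolume:
    filtered = np.fft.ifftn(np.fft.fftn(volume.data) * response).real
    return replace(volume, data=filtered)


def lowpass_filter(volume: DensityVolume, resolution: float,
                   edge_width: float = 0.1) -> DensityVolume:
    """Low-pass filter to ``resolution`` (nm) with a raised-cosine edge.

    The response is 1 below the cutoff frequency ``1/resolution``, rolls off
    over a raised-cosine band of relative width ``edge_width`` centred on the
    cutoff, and is 0 beyond.  The DC term is untouched, so the volume mean is
    preserved.  ``resolution=None`` or ``inf`` is the identity.
    """
    if resolution is None or not np.isfinite(resolution):
        return replace(volume, data=volume.data.copy())
    nyquist = 2.0 * volume.voxel_size
    if resolution < nyquist:
        raise FilterParameterError(
            f"resolution {resolution} nm is below Nyquist ({nyquist} nm)")
    fc = 1.0 / resolution
    half_band = 0.5 * edge_width * fc
    f = _radial_frequency(volume.data.shape, volume.voxel_size)
    response = np.ones_like(f)
    rolloff = (f > fc - half_band) & (f < fc + half_band)
    response[rolloff] = 0.5 * (
        1.0 + np.cos(np.pi * (f[rolloff] - (fc - half_band)) / (2 * half_band)))
    response[f >= fc + half_band] = 0.0
    return _apply_radial_filter(volume, response)


def zscore_normalize(volume: DensityVolume) -> DensityVolume:
    """Standardize to mean 0, standard deviation 1."""
    sd = volume.data.std()
    if sd == 0:
        raise FilterParameterError("cannot z-score a constant volume")
    return replace(volume, data=(volume.data - volume.data.mean()) / sd)


def wiener_deconvolve(volume: DensityVolume, falloff: float, strength: float,
                      contrast_falloff: float | None = None) -> DensityVolume:
    """Wiener-like radial deconvolution.

    The contrast decay is modelled as ``C(f) = exp(-f / contrast_falloff)``
    (pure amplitude decay, no oscillation) and the assumed spectral SNR as
    ``SSNR(f) = strength * exp(-f / falloff)``; the applied response is
    ``W(f) = C / (C^2 + 1/SSNR)``.  Large ``strength`` approaches the inverse
    filter ``1/C``; ``strength -> 0`` suppresses the volume entirely.

    Parameters
    ----------
    falloff
        SSNR decay constant in cycles/nm.
    strength
        SSNR at zero frequency (dimensionless).
    contrast_falloff
        Contrast decay constant in cycles/nm; defaults to ``falloff``.
    """
    if not (falloff > 0 and strength > 0):
        raise FilterParameterError("falloff and strength must be positive")
    if contrast_falloff is None:
        contrast_falloff = falloff
    elif not contrast_falloff > 0:
        raise FilterParameterError("contrast_falloff must be positive")
    f = _radial_frequency(volume.data.shape, volume.voxel_size)
    contrast = np.exp(-f / contrast_falloff)
    ssnr = strength * np.exp(-f / falloff)
    response = contrast / (contrast**2 + 1.0 / ssnr)
    return _apply_radial_filter(volume, response)
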