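"""Bilayer thickness from intensity profiles along the membrane normal.

A profile through a membrane shows two minima (the leaflets, dark in cryo-ET)
separated by a central maximum.  Thickness is reported two ways: the distance
between the two minima, and the distance between the two inflection points
(positions of maximal intensity gradient between each minimum and its
adjacent maximum).  Each minimum has an inner adjacent maximum (the central
one) and an outer one; both readings are supported via ``inflection_side``
with ``outer`` — the leaflet-width-inclusive, larger readout — as default.

All extremum and gradient-maximum positions are refined to sub-sample
precision on a cubic-spline interpolant of the profile: voxel-limited
precision would otherwise dominate at ~0.9 nm sampling, and simple 3-point
parabolic refinement of the gradient maximum is biased outward by a
significant fraction of a voxel on Gaussian-like leaflet flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateProfileError,
    MeasurementError,
    NoBilayerError,
    ProfileExtentError,
)
from .volume_prep import DensityVolume


@dataclass
class IntensityProfile:
    """Intensities sampled along a line, centred on the extraction point."""

    samples: np.ndarray
    spacing: float
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        if len(self.samples) < 9:
            raise ValueError("a profile needs at least 9 samples")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if abs(np.linalg.norm(self.axis_direction) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")

    @property
    def positions(self) -> np.ndarray:
        """Signed position (nm) of each sample along the axis, 0 at centre."""
        n = len(self.samples)
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing


@dataclass
class BilayerProfileFeatures:
    """Leaflet minima, central maximum, inflection points and thicknesses."""

    minima_positions: tuple[float, float]
    center_max_position: float
    inflection_positions: tuple[float, float]
    thickness_minima: float
    thickness_inflection: float
    quality: dict = field(default_factory=dict)


@dataclass
class GroupMeasurements:
    """Thickness values per group label, on one measurement basis."""

    values: dict[str, list[float]]
    basis: str = "minima"
    n_failed: dict[str, int] = field(default_factory=dict)


def extract_profile(volume: DensityVolume, point: np.ndarray,
                    direction: np.ndarray, half_length: float,
                    spacing: float | None = None) -> IntensityProfile:
    """Sample the volume along ``point +/- half_length * direction``.

    Trilinear interpolation at ``spacing`` (default: one voxel), centred on
    ``point``.  Raises :class:`ProfileExtentError` if the segment leaves the
    volume.
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be nonzero")
    direction = direction / norm
    spacing = volume.voxel_size if spacing is None else spacing
    n_half = int(round(half_length / spacing))
    offsets = (np.arange(2 * n_half + 1) - n_half) * spacing
    points = np.asarray(point, dtype=float) + offsets[:, None] * direction
    idx = volume.world_to_voxel(points)            # (n, 3) in z, y, x order
    upper = np.array(volume.data.shape) - 1
    if (idx < 0).any() or (idx > upper).any():
        bad = ((idx < 0) | (idx > upper)).any(axis=1)
        lo, hi = offsets[bad].min(), offsets[bad].max()
        raise ProfileExtentError(
            f"profile segment leaves the volume for offsets in "
            f"[{lo:.2f}, {hi:.2f}] nm from the extraction point")
    samples = ndimage.map_coordinates(volume.data, idx.T, order=1)
    return IntensityProfile(samples, spacing, np.asarray(point, dtype=float),
                            direction)


_REFINE_SUBDIV = 64     # spline evaluations per sample interval


def _spline_extremum(spline: CubicSpline, lo: float, hi: float,
                     mode: str) -> float:
    """Position of the spline min/max/abs-derivative-max on [lo, hi]."""
    grid = np.linspace(lo, hi, max(int((hi - lo) * _REFINE_SUBDIV), 8) + 1)
    if mode == "min":
        vals = spline(grid)
        return float(grid[np.argmin(vals)])
    if mode == "max":
        vals = spline(grid)
        return float(grid[np.argmax(vals)])
    return float(grid[np.argmax(np.abs(spline(grid, 1)))])


def detect_bilayer_features(profile: IntensityProfile,
                            min_prominence: float = 0.0,
                            inflection_side: str = "outer",
                            ) -> BilayerProfileFeatures:
    """Locate the two leaflet minima and derive both thickness readouts.

    Minima are found on the inverted signal; if more than two pass the
    prominence threshold, the two most prominent are kept (ties broken toward
    the profile centre).  The profile centre maximum is the intensity maximum
    between the two minima.  Each inflection point is the position of maximal
    absolute intensity gradient between a minimum and its adjacent maximum on
    the requested side.  All positions are refined on a cubic-spline
    interpolant of the sampled profile.
    """
    if inflection_side not in {"outer", "inner"}:
        raise ValueError("inflection_side must be 'outer' or 'inner'")
    y = profile.samples
    pos = profile.positions
    peaks, props = signal.find_peaks(-y, prominence=min_prominence or None)
    if len(peaks) < 2:
        raise NoBilayerError(
            f"found {len(peaks)} leaflet minima above prominence "
            f"{min_prominence}; a bilayer needs two")
    if len(peaks) > 2:
        prominences = props["prominences"]
        centre = (len(y) - 1) / 2.0
        order = sorted(range(len(peaks)),
                       key=lambda i: (-prominences[i], abs(peaks[i] - centre)))
        peaks = np.sort(peaks[order[:2]])
    i_lo, i_hi = int(peaks[0]), int(peaks[1])
    if i_hi - i_lo < 2:
        raise DegenerateProfileError("leaflet minima are adjacent samples")

    between = y[i_lo:i_hi + 1]
    i_max = i_lo + int(np.argmax(between))
    if i_max in (i_lo, i_hi):
        raise DegenerateProfileError(
            "no interior maximum separates the two minima")

    spline = CubicSpline(np.arange(len(y), dtype=float), y)
    min_lo_idx = _spline_extremum(spline, max(i_lo - 1, 0),
                                  min(i_lo + 1, len(y) - 1), "min")
    min_hi_idx = _spline_extremum(spline, max(i_hi - 1, 0),
                                  min(i_hi + 1, len(y) - 1), "min")
    max_idx = _spline_extremum(spline, i_lo, i_hi, "max")

    def _inflection(i_min: int, outward: int) -> float:
        if inflection_side == "inner":
            lo, hi = sorted((i_min, i_max))
        else:
            # outer adjacent maximum: the highest sample outward of the minimum
            if outward < 0:
                i_adj = int(np.argmax(y[:i_min + 1]))
            else:
                i_adj = i_min + int(np.argmax(y[i_min:]))
            if i_adj == i_min:
                raise DegenerateProfileError(
                    "no adjacent maximum outward of a leaflet minimum")
            lo, hi = sorted((i_min, i_adj))
        if hi - lo < 2:
            raise DegenerateProfileError(
                "minimum and adjacent maximum are too close for a gradient peak")
        return _spline_extremum(spline, lo, hi, "grad")

    infl_lo = _inflection(i_lo, -1)
    infl_hi = _inflection(i_hi, +1)

    def to_nm(idx: float) -> float:
        return float(np.interp(idx, np.arange(len(pos)), pos))

    minima_nm = (to_nm(min_lo_idx), to_nm(min_hi_idx))
    infl_nm = (to_nm(infl_lo), to_nm(infl_hi))
    return BilayerProfileFeatures(
        minima_positions=minima_nm,
        center_max_position=to_nm(max_idx),
        inflection_positions=infl_nm,
        thickness_minima=abs(minima_nm[1] - minima_nm[0]),
        thickness_inflection=abs(infl_nm[1] - infl_nm[0]),
        quality={"n_candidate_minima": int(len(peaks)),
                 "inflection_side": inflection_side},
    )


def measure_group_thickness(volume: DensityVolume,
                            sites: list[tuple[np.ndarray, np.ndarray, str]],
                            half_length: float = 10.0,
                            basis: str = "minima",
                            min_prominence: float = 0.0,
                            inflection_side: str = "outer",
                            spacing: float | None = None) -> GroupMeasurements:
    """One thickness per measurement site, grouped by site label.

    Sites that fail (profile leaves the volume, no bilayer found) are counted
    and excluded; a group with zero successful measurements raises
    :class:`MeasurementError`.
    """
    if basis not in {"minima", "inflection"}:
        raise ValueError("basis must be 'minima' or 'inflection'")
    values: dict[str, list[float]] = {}
    failed: dict[str, int] = {}
    for point, direction, group in sites:
        values.setdefault(group, [])
        failed.setdefault(group, 0)
        try:
            prof = extract_profile(volume, point, direction, half_length,
                                   spacing=spacing)
            feats = detect_bilayer_features(prof, min_prominence,
                                            inflection_side)
        except (ProfileExtentError, NoBilayerError, DegenerateProfileError):
            failed[group] += 1
            continue
        values[group].append(feats.thickness_minima if basis == "minima"
                             else feats.thickness_inflection)
    empty = [g for g, vals in values.items() if not vals]
    if empty:
        raise MeasurementError(
            f"groups {empty} produced no valid thickness measurement "
            f"(failures: {failed})")
    return GroupMeasurements(values, basis, failed)
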