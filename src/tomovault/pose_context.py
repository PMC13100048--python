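"""Ribosome-vault spatial and orientational context statistics.

A ribosome counts as encapsulated when its centre lies within a cutoff
(10 nm by default) of its nearest vault centre in the same tomogram.  The
relative rotation of a pair is ``R_rel = R_vault^-1 @ R_ribosome``, and the
plotted orientational quantity is a designated ribosome reference axis
expressed in the vault frame, summarised on a near-equal-area spherical
histogram (subdivided-icosahedron faces).  Pairs whose vault-frame axis lies
within ``theta_rtc`` of a target axis are labelled RTC-like (the membrane
ribosome-translocon-compatible configuration); printed-count contingency
tables feed the exact tests in :mod:`tomovault.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh as trimesh_pkg

from .errors import DegenerateStatisticsError
from .stats import ContingencyTable2x2, TestResult, fisher_exact_two_sided
from .volume_prep import PoseSet


@dataclass
class PairAssignment:
    """A ribosome paired with its enclosing vault."""

    ribosome_index: int
    vault_index: int
    distance: float
    relative_rotation: np.ndarray     # R_vault^-1 @ R_ribosome


@dataclass
class SphericalHistogram:
    """Direction counts on the faces of a subdivided icosahedron."""

    bin_directions: np.ndarray        # unit face centroids (F, 3)
    counts: np.ndarray
    total: int

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / max(self.total, 1)


def pair_nearest(ribosomes: PoseSet, vaults: PoseSet,
                 cutoff: float = 10.0) -> list[PairAssignment]:
    """Assign each ribosome to its nearest vault within ``cutoff`` nm.

    Matching is per tomogram (a ribosome is never paired across tomogram
    ids); equidistant vaults are broken toward the lower vault index.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    vault_ids = set(vaults.tomogram_ids)
    rib_ids = set(ribosomes.tomogram_ids)
    if rib_ids - vault_ids and len(vault_ids | rib_ids) > 1:
        raise ValueError(
            f"tomogram ids do not match between sets: ribosomes have "
            f"{sorted(rib_ids - vault_ids)} with no vault counterpart")
    pairs: list[PairAssignment] = []
    vault_idx_by_tomo: dict[str, np.ndarray] = {}
    for tomo in vault_ids:
        vault_idx_by_tomo[tomo] = np.flatnonzero(
            [t == tomo for t in vaults.tomogram_ids])
    for ri in range(len(ribosomes)):
        vidx = vault_idx_by_tomo.get(ribosomes.tomogram_ids[ri])
        if vidx is None or len(vidx) == 0:
            continue
        dists = np.linalg.norm(vaults.positions[vidx]
                               - ribosomes.positions[ri], axis=1)
        best = int(np.argmin(dists))          # argmin takes the lowest index on ties
        if dists[best] <= cutoff:
            vi = int(vidx[best])
            r_rel = vaults.rotations[vi].T @ ribosomes.rotations[ri]
            pairs.append(PairAssignment(ri, vi, float(dists[best]), r_rel))
    return pairs


def relative_axis(pair: PairAssignment, reference_axis) -> np.ndarray:
    """The ribosome reference axis expressed in the vault frame.

    Equivariant under global rotations: pre-rotating both poses by the same
    rotation leaves the result unchanged.
    """
    ref = np.asarray(reference_axis, dtype=float)
    if abs(np.linalg.norm(ref) - 1.0) > 1e-9:
        raise ValueError("reference_axis must be a unit vector")
    return pair.relative_rotation @ ref


def _icosphere_bins(n_subdiv: int) -> tuple[np.ndarray, np.ndarray]:
    """Face edge-plane normals (F, 3, 3) and unit centroids (F, 3)."""
    ico = trimesh_pkg.creation.icosphere(subdivisions=n_subdiv)
    v = np.asarray(ico.vertices)
    f = np.asarray(ico.faces)
    edge_normals = np.stack([np.cross(v[f[:, 0]], v[f[:, 1]]),
                             np.cross(v[f[:, 1]], v[f[:, 2]]),
                             np.cross(v[f[:, 2]], v[f[:, 0]])], axis=1)
    centroids = v[f].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    return edge_normals, centroids


def histogram_bin_directions(n_subdiv: int = 1) -> np.ndarray:
    """Unit centroids of the spherical-histogram bins at a subdivision level."""
    return _icosphere_bins(n_subdiv)[1]


def spherical_histogram(axes, n_subdiv: int = 1) -> SphericalHistogram:
    """Count unit vectors in the faces of a subdivided icosahedron.

    A direction belongs to the spherical triangle whose three edge-plane
    signed distances are all non-negative; numerically, the face maximising
    the minimum signed distance.  Bins are near-equal-area and cover the
    sphere without overlap.
    """
    if n_subdiv < 0:
        raise ValueError("n_subdiv must be >= 0")
    edge_normals, centroids = _icosphere_bins(n_subdiv)
    axes = np.asarray(axes, dtype=float).reshape(-1, 3)
    counts = np.zeros(len(centroids), dtype=int)
    if len(axes):
        norms = np.linalg.norm(axes, axis=1)
        if (norms == 0).any():
            raise ValueError("zero-length direction vector in input")
        axes = axes / norms[:, None]
        for start in range(0, len(axes), 4096):
            chunk = axes[start:start + 4096]
            signed = np.einsum("fek,nk->nfe", edge_normals, chunk).min(axis=2)
            counts += np.bincount(signed.argmax(axis=1),
                                  minlength=len(centroids))
    return SphericalHistogram(centroids, counts, int(counts.sum()))


def classify_rtc(pairs: list[PairAssignment], reference_axis, target_axis,
                 theta_rtc: float = 30.0) -> list[str]:
    """Label each pair RTC-like iff its vault-frame axis lies within
    ``theta_rtc`` degrees (inclusive) of ``target_axis``."""
    if not 0 < theta_rtc < 90:
        raise ValueError("theta_rtc must be in (0, 90) degrees")
    target = np.asarray(target_axis, dtype=float)
    target = target / np.linalg.norm(target)
    labels = []
    for pair in pairs:
        axis = relative_axis(pair, reference_axis)
        angle = np.degrees(np.arccos(np.clip(axis @ target, -1.0, 1.0)))
        # boundary is inclusive; absorb arccos round-off at exactly theta_rtc
        labels.append("RTC-like" if angle <= theta_rtc + 1e-9 else "other")
    return labels


def orientation_contingency(
    labels_membrane: list[str], labels_cytosolic: list[str],
) -> tuple[ContingencyTable2x2, TestResult]:
    """2x2 table (rows: membrane/cytosolic, columns: RTC-like/other) + Fisher."""
    if not labels_membrane or not labels_cytosolic:
        raise DegenerateStatisticsError("both label lists must be non-empty")
    table = ContingencyTable2x2(
        labels_membrane.count("RTC-like"),
        len(labels_membrane) - labels_membrane.count("RTC-like"),
        labels_cytosolic.count("RTC-like"),
        len(labels_cytosolic) - labels_cytosolic.count("RTC-like"))
    return table, fisher_exact_two_sided(table)


@dataclass
class EncapsulationSummary:
    """Per-class encapsulation counts, percentages and the Fisher comparison."""

    counts: dict[str, tuple[int, int]]       # class -> (encapsulated, not)
    percentages: dict[str, float]            # rounded to the nearest integer
    table: ContingencyTable2x2
    test: TestResult


def encapsulation_summary(vault_classes: list[str],
                          pairs: list[PairAssignment]) -> EncapsulationSummary:
    """Summarise which vaults of each class hold a ribosome.

    ``vault_classes`` assigns every vault (by index) to one of exactly two
    classes.  Percentages are ``100 * encapsulated / class total`` rounded to
    the nearest integer, as printed in per-class bar charts.
    """
    if any(not c for c in vault_classes):
        raise ValueError("every vault must carry a class label")
    classes = sorted(set(vault_classes))
    if len(classes) != 2:
        raise DegenerateStatisticsError(
            f"need exactly two vault classes, got {classes}")
    encapsulated = {p.vault_index for p in pairs}
    counts: dict[str, tuple[int, int]] = {}
    for cls in classes:
        idx = [i for i, c in enumerate(vault_classes) if c == cls]
        if not idx:
            raise DegenerateStatisticsError(f"class {cls!r} is empty")
        n_enc = sum(1 for i in idx if i in encapsulated)
        counts[cls] = (n_enc, len(idx) - n_enc)
    percentages = {cls: round(100.0 * enc / (enc + non))
                   for cls, (enc, non) in counts.items()}
    (enc0, non0), (enc1, non1) = counts[classes[0]], counts[classes[1]]
    table = ContingencyTable2x2(enc0, non0, enc1, non1)
    return EncapsulationSummary(counts, percentages, table,
                                fisher_exact_two_sided(table))


def class_fraction_summary(vault_classes: list[str]) -> dict[str, dict]:
    """Count and one-decimal percentage of each class among all vaults."""
    if not vault_classes:
        raise ValueError("need at least one vault")
    total = len(vault_classes)
    out: dict[str, dict] = {}
    for cls in sorted(set(vault_classes)):
        n = vault_classes.count(cls)
        out[cls] = {"count": n, "total": total,
                    "percent": round(100.0 * n / total, 1)}
    return out
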