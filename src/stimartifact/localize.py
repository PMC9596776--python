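"""Electrode localization from CT-like intensity volumes.

Bright metal electrodes appear as compact intensity clusters in a
post-implantation CT.  Localization proceeds by (1) thresholding the
intensity volume, (2) density-based clustering (DBSCAN) of the retained
voxels, one cluster per electrode, (3) centroiding each cluster, and
(4) scaling centroids by the voxel dimensions to obtain mm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import DBSCAN

from .core import ElectrodeSet
from .synth import CTVolume

__all__ = ["CTVolume", "Cluster", "threshold_volume", "cluster_electrodes",
           "to_physical", "localize_electrodes", "default_threshold"]


@dataclass(eq=False)
class Cluster:
    centroid: np.ndarray  # voxel space
    members: np.ndarray  # (m, 3) voxel coordinates

    @property
    def size(self) -> int:
        return len(self.members)


def threshold_volume(vol: CTVolume, threshold: float) -> np.ndarray:
    """Integer voxel coordinates with intensity strictly above threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.argwhere(vol.intensities > threshold)


def default_threshold(vol: CTVolume, n_sigma: float = 5.0) -> float:
    """Background mean + n_sigma * SD, a robust cut for blob-on-noise volumes."""
    flat = vol.intensities.ravel()
    med = np.median(flat)
    # robust SD from the MAD so the bright electrode voxels do not inflate it
    mad = np.median(np.abs(flat - med))
    sd = 1.4826 * mad
    return float(med + n_sigma * sd)


def cluster_electrodes(points: np.ndarray, eps: float = 2.0,
                       min_pts: int = 4,
                       intensity_weighted: bool = False,
                       vol: Optional[CTVolume] = None) -> List[Cluster]:
    """DBSCAN-cluster suprathreshold voxels; one centroid per cluster.

    Noise points (DBSCAN label -1) are discarded.  The centroid is the
    unweighted mean of member voxels, or the intensity-weighted mean when
    ``intensity_weighted`` is set (requires ``vol``).  Clusters are
    returned sorted lexicographically by centroid, which makes the result
    independent of input point ordering for well-separated clusters.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    points = np.asarray(points)
    if len(points) == 0:
        return []
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(points)
    clusters: List[Cluster] = []
    for lab in sorted(set(labels) - {-1}):
        members = points[labels == lab]
        if intensity_weighted:
            if vol is None:
                raise ValueError("intensity weighting requires the volume")
            w = vol.intensities[tuple(members.T)]
            centroid = (members * w[:, None]).sum(axis=0) / w.sum()
        else:
            centroid = members.mean(axis=0)
        clusters.append(Cluster(centroid=centroid, members=members))
    clusters.sort(key=lambda c: tuple(c.centroid))
    return clusters


def _row_major_order(positions: np.ndarray) -> np.ndarray:
    """Order points row-major along their two principal in-plane axes."""
    n = len(positions)
    if n < 3:
        return np.lexsort(positions.T[::-1])
    centered = positions - positions.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    major = centered @ vt[0]
    minor = centered @ vt[1]
    # quantize the minor-axis coordinate into rows using the nearest-neighbour
    # spacing as the natural pitch
    d = positions[:, None, :] - positions[None, :, :]
    dist = np.linalg.norm(d, axis=2)
    np.fill_diagonal(dist, np.inf)
    pitch = np.median(dist.min(axis=0))
    rows = np.round((minor - minor.min()) / max(pitch, 1e-9)).astype(int)
    return np.lexsort((major, rows))


def to_physical(centroids: Sequence[np.ndarray],
                voxel_dims: Sequence[float],
                label_prefix: str = "E") -> ElectrodeSet:
    """Scale voxel-space centroids to mm and assign row-major labels.

    Physical position is the componentwise product of the centroid and the
    voxel dimensions (the volume origin sits at voxel (0,0,0)).  Labels are
    ``prefix + i`` with i starting at 1 in row-major order along the point
    set's principal axes.
    """
    voxel_dims = np.asarray(voxel_dims, dtype=float).reshape(3)
    if np.any(voxel_dims <= 0):
        raise ValueError("voxel dimensions must be positive")
    cents = np.asarray(list(centroids), dtype=float).reshape(-1, 3)
    if len(cents) == 0:
        return ElectrodeSet([], np.empty((0, 3)))
    positions = cents * voxel_dims
    order = _row_major_order(positions)
    labels = [f"{label_prefix}{i + 1}" for i in range(len(positions))]
    return ElectrodeSet(labels, positions[order])


def localize_electrodes(vol: CTVolume, threshold: Optional[float] = None,
                        eps: float = 2.0, min_pts: int = 4,
                        label_prefix: str = "E",
                        ) -> Tuple[ElectrodeSet, List[Cluster]]:
    """Full pipeline: threshold -> DBSCAN -> centroids -> mm coordinates."""
    if threshold is None:
        threshold = default_threshold(vol)
    pts = threshold_volume(vol, threshold)
    clusters = cluster_electrodes(pts, eps=eps, min_pts=min_pts)
    es = to_physical([c.centroid for c in clusters], vol.voxel_dims,
                     label_prefix=label_prefix)
    return es, clusters
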