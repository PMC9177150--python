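"""Spike-cluster density volume in a common space.

All accepted clusters and all recording sites are pooled in the left
hemisphere of the common space (right-hemisphere coordinates mirrored).  On
a 0.22 mm isotropic grid, each voxel holds the number of clusters divided by
the number of recordings within 1 mm of its center; voxels never probed by a
recording are undefined.  The suprathreshold density volume is then compared
with the atlas nucleus as a percent overlap.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .models import AnatomyModel, DensityGrid

__all__ = ["mirror_to_left", "density_volume", "overlap_at_threshold"]

#: Default density-grid spacing, mm (isotropic).
DENSITY_SPACING_MM = 0.22
#: Neighborhood radius around each voxel center, mm (closed ball).
NEIGHBORHOOD_MM = 1.0


def mirror_to_left(points: np.ndarray, flip_field=None) -> np.ndarray:
    """Map right-hemisphere points (x > 0) onto the left hemisphere.

    In the identity/synthetic mode this is the midsagittal mirror x → −x
    about the x = 0 plane; left-hemisphere points pass through unchanged.
    A supplied nonlinear ``flip_field`` (callable points → points) is applied
    instead when provided.
    """
    points = np.atleast_2d(np.asarray(points, float)).copy()
    right = points[:, 0] > 0
    if flip_field is not None:
        points[right] = flip_field(points[right])
    else:
        points[right, 0] *= -1.0
    return points


def density_volume(cluster_points: np.ndarray, recording_points: np.ndarray,
                   radius_mm: float = NEIGHBORHOOD_MM,
                   spacing_mm: float = DENSITY_SPACING_MM,
                   margin_mm: float | None = None) -> DensityGrid:
    """Cluster density on an isotropic grid covering the recording sites.

    Per voxel center c: ``density(c) = #clusters within radius of c /
    #recordings within radius of c``, undefined where no recording falls
    within the radius.  With at most one cluster per recording segment the
    density lies in [0, 1].
    """
    rec = np.atleast_2d(np.asarray(recording_points, float))
    clu = np.atleast_2d(np.asarray(cluster_points, float)) if len(cluster_points) else np.empty((0, 3))
    if len(rec) == 0:
        raise ValueError("at least one recording point required")
    # margin is a whole number of voxels so the minimal recording point
    # falls exactly on a voxel center
    margin = (np.ceil(radius_mm / spacing_mm) * spacing_mm
              if margin_mm is None else margin_mm)
    lo = rec.min(axis=0) - margin
    hi = rec.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing_mm).astype(int) + 1, 1)
    affine = np.eye(4)
    affine[:3, :3] *= spacing_mm
    affine[:3, 3] = lo
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * spacing_mm + lo
    rec_tree = cKDTree(rec)
    n_rec = rec_tree.query_ball_point(centers, radius_mm, return_length=True)
    if len(clu):
        n_clu = cKDTree(clu).query_ball_point(centers, radius_mm, return_length=True)
    else:
        n_clu = np.zeros(len(centers), int)
    return DensityGrid(affine,
                       np.asarray(n_clu).reshape(shape),
                       np.asarray(n_rec).reshape(shape))


def overlap_at_threshold(grid: DensityGrid, region: AnatomyModel, tau: float) -> float:
    """Percent of the suprathreshold density volume lying inside the region.

    ``S = {defined voxels with density ≥ tau}``; returns 100·|S ∩ region|/|S|.
    NaN when S is empty (threshold above all observed densities).
    """
    mask = np.isfinite(grid.density) & (grid.density >= tau)
    if not mask.any():
        return float("nan")
    idx = np.argwhere(mask)
    centers = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    inside = region.contains(centers)
    return 100.0 * float(inside.sum()) / float(len(centers))
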