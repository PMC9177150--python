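"""Mapping electrophysiology into anatomical space.

Depth profiles are resampled onto a uniform 0.1 mm distance-to-target grid;
trajectories are intersected with an atlas nucleus to find entry/exit depths
and the trajectory-to-region distance; trajectories from different patients
are aligned on a normalized depth axis anchored to a common target point;
and contact coordinates are projected back onto the nearest trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SchemaError
from .models import DEPTH_GRID_MM, AnatomyModel, DepthProfile, TrajectoryPlan
from .stereotaxy import electrode_position

__all__ = [
    "SampledTrajectory",
    "sample_trajectory",
    "resample_profile",
    "stn_entry_exit",
    "trajectory_stn_distance",
    "normalized_depth_alignment",
    "project_point_to_trajectory",
]

#: Line sampling step for inside/outside tests, mm.
LINE_STEP_MM = 0.01


@dataclass
class SampledTrajectory:
    """A trajectory line sampled over its recorded depth range."""

    trajectory_id: str
    dtt_mm: np.ndarray  # descending
    points_mm: np.ndarray  # (n, 3) world positions


def sample_trajectory(plan: TrajectoryPlan, channel: str,
                      dtt_range: tuple[float, float] = (10.0, -4.0),
                      step_mm: float = LINE_STEP_MM,
                      trajectory_id: str = "") -> SampledTrajectory:
    """Sample a channel's line at fixed depth steps over the drive range."""
    hi, lo = max(dtt_range), min(dtt_range)
    n = int(round((hi - lo) / step_mm)) + 1
    dtt = hi - step_mm * np.arange(n)
    base = electrode_position(plan, channel, 0.0)
    points = base + dtt[:, None] * plan.direction_up
    return SampledTrajectory(trajectory_id or channel, dtt, points)


def resample_profile(depths_mm: np.ndarray, values: np.ndarray,
                     grid_mm: float = DEPTH_GRID_MM) -> DepthProfile:
    """Linear resampling of an irregular depth series onto the 0.1 mm grid.

    Grid points outside the measured depth range are NaN (no extrapolation).
    Duplicate depths with conflicting values raise; exact duplicates are
    merged.
    """
    depths_mm = np.asarray(depths_mm, float)
    values = np.asarray(values, float)
    if len(depths_mm) < 2:
        raise ValueError("at least two distinct depths required")
    order = np.argsort(depths_mm)[::-1]
    d, v = depths_mm[order], values[order]
    dup = np.isclose(np.diff(d), 0)
    if dup.any():
        if not np.allclose(v[:-1][dup], v[1:][dup]):
            raise SchemaError("duplicate depths with conflicting values")
        keep = np.append(True, ~dup)
        d, v = d[keep], v[keep]
    hi = np.floor(d[0] / grid_mm) * grid_mm
    lo = np.ceil(d[-1] / grid_mm) * grid_mm
    n = int(round((hi - lo) / grid_mm)) + 1
    grid = hi - grid_mm * np.arange(n)
    # np.interp wants ascending x
    out = np.interp(grid[::-1], d[::-1], v[::-1])[::-1]
    return DepthProfile(grid, out)


def stn_entry_exit(traj: SampledTrajectory, region: AnatomyModel) -> tuple[float, float] | None:
    """Imaging-defined nucleus boundaries along a trajectory.

    Samples the line at its depth grid, tests each point for containment and
    returns ``(entry_dtt, exit_dtt)`` — the largest and smallest depths
    inside — or ``None`` when the line misses the region.
    """
    inside = region.contains(traj.points_mm)
    if not inside.any():
        return None
    d = traj.dtt_mm[inside]
    return float(d.max()), float(d.min())


def trajectory_stn_distance(traj: SampledTrajectory, region: AnatomyModel) -> float:
    """Minimum Euclidean distance (mm) from a trajectory to a region; 0 if intersecting."""
    if stn_entry_exit(traj, region) is not None:
        return 0.0
    return float(region.distance(traj.points_mm).min())


def normalized_depth_alignment(trajectories: list[SampledTrajectory],
                               mni_target: np.ndarray) -> np.ndarray:
    """Per-trajectory depth shifts aligning all trajectories on a shared axis.

    Each trajectory's reference depth r_i is the dtt of its point nearest
    the common target coordinate; the shift is r_i minus the cohort mean, so
    normalized dtt = dtt − shift_i and the mean shift is zero.
    """
    if not trajectories:
        raise ValueError("at least one trajectory required")
    target = np.asarray(mni_target, float)
    refs = np.array([
        t.dtt_mm[np.argmin(np.linalg.norm(t.points_mm - target, axis=1))]
        for t in trajectories
    ])
    return refs - refs.mean()


def project_point_to_trajectory(point: np.ndarray,
                                trajectories: list[SampledTrajectory]) -> tuple[str, np.ndarray, float]:
    """Project a coordinate onto the nearest point of the closest trajectory.

    The projection is orthogonal onto each trajectory's line segment,
    clamped to its recorded depth range; returns ``(trajectory_id,
    foot_point, dtt)`` for the globally nearest foot point.
    """
    if not trajectories:
        raise ValueError("at least one trajectory required")
    point = np.asarray(point, float)
    best = None
    for t in trajectories:
        a, b = t.points_mm[0], t.points_mm[-1]  # highest and lowest dtt
        ab = b - a
        denom = float(ab @ ab)
        s = 0.0 if denom == 0 else float(np.clip((point - a) @ ab / denom, 0.0, 1.0))
        foot = a + s * ab
        dtt = t.dtt_mm[0] + s * (t.dtt_mm[-1] - t.dtt_mm[0])
        dist = float(np.linalg.norm(point - foot))
        if best is None or dist < best[0]:
            best = (dist, t.trajectory_id, foot, dtt)
    return best[1], best[2], best[3]
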