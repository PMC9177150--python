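"""Stereotactic coordinate chain.

A surgical plan defines a line in frame space from a target coordinate,
ring and arc angles, and the frame mounting.  AC, PC and a midsagittal
point, known in both image and frame coordinates, tie the patient image to
the frame through a rigid transform.  Up to five parallel microelectrodes
sit on a Ben-Gun cross, 2 mm from the central trajectory, in orthogonal
(0°) or rotated (45°) configuration.

Angle convention (``angle_convention="ras"``, the package default): with
ring angle α and arc angle β in degrees, the unit direction from target
toward entry is

    v = (cos β,  sin β · cos α,  sin β · sin α)

in RAS-aligned frame axes, so ring=arc=90° is vertical (superior) and
arc rotates the trajectory out of the coronal plane.  Frame vendors differ
here; the convention is explicit and configurable rather than inferred.

Mounting tokens apply documented sign flips to the direction: a
``lateral-left`` mounting negates the lateral (first) component;
``lateral-right`` is the identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeometryError, RangeError
from .models import PlanRecord, RigidTransform, TrajectoryPlan

__all__ = [
    "fit_frame_transform",
    "trajectory_direction",
    "bengun_offsets",
    "electrode_position",
    "build_trajectory",
    "trajectory_table",
]

#: mounting token -> per-axis direction sign flips (RAS)
MOUNTING_SIGNS: dict[str, np.ndarray] = {
    "lateral-right": np.array([1.0, 1.0, 1.0]),
    "lateral-left": np.array([-1.0, 1.0, 1.0]),
}

#: Ben-Gun channel spacing from the central trajectory, mm.
BENGUN_SPACING_MM = 2.0


def fit_frame_transform(pairs: list[tuple[np.ndarray, np.ndarray]]) -> RigidTransform:
    """Least-squares rigid (rotation + translation, no scaling) image->frame fit.

    Parameters
    ----------
    pairs
        Sequence of ``(point_image, point_frame)`` fiducial pairs in mm;
        at least three non-collinear pairs (typically AC, PC, MS).

    Returns
    -------
    RigidTransform
        Orthonormal rotation (det = +1), translation, and the RMS fiducial
        registration error over the input pairs.
    """
    img = np.asarray([p[0] for p in pairs], float)
    frm = np.asarray([p[1] for p in pairs], float)
    if len(img) < 3:
        raise DegenerateGeometryError("at least 3 fiducial pairs required")
    ci, cf = img.mean(axis=0), frm.mean(axis=0)
    a, b = img - ci, frm - cf
    # collinear points leave rotation about the common axis unconstrained
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
        raise DegenerateGeometryError("fiducial points are collinear")
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ ci
    resid = frm - (img @ rot.T + trans)
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(rot, trans, fre)


def trajectory_direction(ring_deg: float, arc_deg: float,
                         mounting: str = "lateral-right",
                         angle_convention: str = "ras") -> np.ndarray:
    """Unit vector from target toward entry for given frame angles."""
    if not (0.0 <= ring_deg <= 180.0 and 0.0 <= arc_deg <= 180.0):
        raise RangeError("ring and arc angles must lie in [0, 180] degrees")
    if angle_convention != "ras":
        raise ValueError(f"unknown angle_convention {angle_convention!r}")
    try:
        signs = MOUNTING_SIGNS[mounting]
    except KeyError:
        raise ValueError(
            f"unknown mounting {mounting!r}; allowed: {sorted(MOUNTING_SIGNS)}") from None
    a, b = np.deg2rad(ring_deg), np.deg2rad(arc_deg)
    v = np.array([np.cos(b), np.sin(b) * np.cos(a), np.sin(b) * np.sin(a)]) * signs
    return v / np.linalg.norm(v)


def bengun_offsets(direction_up: np.ndarray, configuration: str = "orthogonal",
                   channels: tuple[str, ...] = ("central", "anterior", "posterior",
                                                "medial", "lateral"),
                   side: str = "left") -> dict[str, np.ndarray]:
    """Channel offsets of the Ben-Gun cross, each ⊥ the trajectory, 2 mm long.

    The anterior reference axis is the unit projection of frame +Y onto the
    plane perpendicular to ``direction_up``; medial/lateral are resolved per
    hemisphere (medial points toward the midline, x = 0).  The rotated
    configuration turns all offsets 45° about ``direction_up`` (right-hand
    rule).
    """
    d = np.asarray(direction_up, float)
    d = d / np.linalg.norm(d)
    y = np.array([0.0, 1.0, 0.0])
    ant = y - (y @ d) * d
    n = np.linalg.norm(ant)
    if n < 1e-9:
        raise DegenerateGeometryError("trajectory parallel to the anterior axis")
    ant /= n
    right = np.cross(ant, d)  # unit, ⊥ both, points toward +x for a vertical line
    medial = right if side == "left" else -right
    if configuration == "rotated":
        from scipy.spatial.transform import Rotation

        rot45 = Rotation.from_rotvec(np.deg2rad(45.0) * d)
        ant, medial = rot45.apply(ant), rot45.apply(medial)
    elif configuration != "orthogonal":
        raise ValueError(f"configuration must be orthogonal|rotated, got {configuration!r}")
    table = {
        "central": np.zeros(3),
        "anterior": BENGUN_SPACING_MM * ant,
        "posterior": -BENGUN_SPACING_MM * ant,
        "medial": BENGUN_SPACING_MM * medial,
        "lateral": -BENGUN_SPACING_MM * medial,
    }
    unknown = set(channels) - set(table)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    return {c: table[c] for c in channels}


def build_trajectory(plan: PlanRecord) -> TrajectoryPlan:
    """Resolve a plan record into a trajectory line plus channel offsets."""
    direction = trajectory_direction(plan.ring_deg, plan.arc_deg, plan.mounting)
    offsets = bengun_offsets(direction, plan.bengun_config, plan.channels, plan.side)
    return TrajectoryPlan(plan.target_frame, direction, offsets)


def electrode_position(plan: TrajectoryPlan, channel: str, dtt_mm: float) -> np.ndarray:
    """World position of a channel's electrode tip at a given distance to target.

    dtt is positive above the target (toward entry) and negative below.
    """
    if channel not in plan.channel_offsets:
        raise KeyError(f"channel {channel!r} not in plan ({sorted(plan.channel_offsets)})")
    return plan.target + dtt_mm * plan.direction_up + plan.channel_offsets[channel]


def trajectory_table(plan: TrajectoryPlan, dtt_grid: np.ndarray) -> pd.DataFrame:
    """Geometry table (channel, dtt, world xyz) for export and downstream mapping."""
    rows = []
    for channel in plan.channel_offsets:
        for dtt in np.asarray(dtt_grid, float):
            x, y, z = electrode_position(plan, channel, dtt)
            rows.append({"channel": channel, "dtt_mm": dtt, "x_mm": x, "y_mm": y, "z_mm": z})
    return pd.DataFrame(rows)
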