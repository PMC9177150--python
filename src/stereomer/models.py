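"""Shared domain types.

All spatial quantities are in world millimetres, RAS orientation.  Distance
to target (dtt) is signed along the planned trajectory: positive above the
planned target (toward the entry point), negative below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import RangeError, SchemaError

CHANNEL_NAMES = ("central", "anterior", "posterior", "medial", "lateral")
FIDUCIAL_NAMES = ("AC", "PC", "MS")

#: Uniform grid spacing of depth profiles, mm.
DEPTH_GRID_MM = 0.1


@dataclass(frozen=True)
class Fiducial:
    """A paired anatomical landmark given in both image and frame space."""

    name: str
    point_image: np.ndarray  # (3,) mm
    point_frame: np.ndarray  # (3,) mm

    def __post_init__(self):
        if self.name not in FIDUCIAL_NAMES:
            raise SchemaError(f"fiducial name must be one of {FIDUCIAL_NAMES}, got {self.name!r}")
        object.__setattr__(self, "point_image", np.asarray(self.point_image, float))
        object.__setattr__(self, "point_frame", np.asarray(self.point_frame, float))


@dataclass
class PlanRecord:
    """A stereotactic plan: target, ring/arc angles, mounting, fiducials, Ben-Gun layout."""

    patient_id: str
    side: str  # left | right
    target_frame: np.ndarray  # (3,) mm, frame space
    ring_deg: float
    arc_deg: float
    mounting: str
    fiducials: list[Fiducial]
    bengun_config: str  # orthogonal | rotated
    channels: tuple[str, ...]

    def __post_init__(self):
        self.target_frame = np.asarray(self.target_frame, float)
        if self.side not in ("left", "right"):
            raise SchemaError(f"side must be 'left' or 'right', got {self.side!r}")
        for angle, name in ((self.ring_deg, "ring_deg"), (self.arc_deg, "arc_deg")):
            if not 0.0 <= angle <= 180.0:
                raise RangeError(f"{name} must be in [0, 180] degrees, got {angle}")
        names = sorted(f.name for f in self.fiducials)
        if names != sorted(FIDUCIAL_NAMES):
            raise SchemaError(f"plan requires exactly one each of {FIDUCIAL_NAMES}, got {names}")
        if self.bengun_config not in ("orthogonal", "rotated"):
            raise SchemaError(f"bengun_config must be orthogonal|rotated, got {self.bengun_config!r}")
        bad = set(self.channels) - set(CHANNEL_NAMES)
        if bad:
            raise SchemaError(f"unknown channel names {sorted(bad)}; allowed: {CHANNEL_NAMES}")
        if not 1 <= len(self.channels) <= 5:
            raise SchemaError("between 1 and 5 channels required")
        self.channels = tuple(self.channels)

    def fiducial(self, name: str) -> Fiducial:
        return next(f for f in self.fiducials if f.name == name)


@dataclass
class SegmentRecord:
    """One MER segment: a fixed microdrive depth on one channel."""

    channel: str
    dtt_mm: float
    fs_hz: float
    samples: np.ndarray  # µV

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.fs_hz <= 0:
            raise RangeError(f"fs_hz must be positive, got {self.fs_hz}")
        if not np.all(np.isfinite(self.samples)):
            raise SchemaError("segment samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass(frozen=True)
class RigidTransform:
    """Rigid (6-DOF) map image -> frame with its fiducial registration error."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,) mm
    fre_mm: float  # RMS fiducial registration error

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        if self.fre_mm < 0:
            raise RangeError("fre_mm must be >= 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation, self.fre_mm)


@dataclass
class TrajectoryPlan:
    """A fully resolved trajectory: line in frame space plus Ben-Gun channel offsets."""

    target: np.ndarray  # (3,) mm
    direction_up: np.ndarray  # unit vector target -> entry
    channel_offsets: dict[str, np.ndarray]  # channel -> (3,) mm, each ⊥ direction_up

    def __post_init__(self):
        self.target = np.asarray(self.target, float)
        self.direction_up = np.asarray(self.direction_up, float)
        n = np.linalg.norm(self.direction_up)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise RangeError(f"direction_up must be a unit vector (norm {n})")
        if not 1 <= len(self.channel_offsets) <= 5:
            raise SchemaError("between 1 and 5 channels required")


@dataclass
class StableWindow:
    """The retained stationary portion of a segment, in seconds from segment start."""

    start_s: float
    end_s: float
    reason: str | None = None  # why prefix/suffix was rejected, if any

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class NRMSProfile:
    """Per-depth normalized RMS along one trajectory."""

    dtt_mm: np.ndarray
    nrms: np.ndarray
    baseline_rms: float  # µV; median RMS of the first five stable steps
    n_baseline_steps: int = 5
    baseline_warning: bool = False  # fewer than five stable steps available

    def __post_init__(self):
        self.dtt_mm = np.asarray(self.dtt_mm, float)
        self.nrms = np.asarray(self.nrms, float)
        if self.dtt_mm.shape != self.nrms.shape:
            raise SchemaError("dtt_mm and nrms must have the same length")


@dataclass
class SpikeCluster:
    """An accepted single-unit spike cluster for one segment."""

    spike_times_s: np.ndarray
    mean_waveform: np.ndarray  # µV
    snr: float
    dtt_mm: float = np.nan
    channel: str | None = None
    position_mm: np.ndarray | None = None  # filled by the mapping stage

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, float)
        self.mean_waveform = np.asarray(self.mean_waveform, float)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)

    @property
    def isi_s(self) -> np.ndarray:
        return np.diff(self.spike_times_s)


@dataclass
class DepthProfile:
    """A scalar series on the uniform 0.1 mm distance-to-target grid.

    The grid runs in drive direction (descending dtt).  ``values`` is NaN
    where the profile is missing (outside the measured depth range).
    """

    dtt_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.dtt_mm = np.asarray(self.dtt_mm, float)
        self.values = np.asarray(self.values, float)
        if self.dtt_mm.shape != self.values.shape:
            raise SchemaError("grid and values must have the same length")
        if len(self.dtt_mm) >= 2:
            steps = np.diff(self.dtt_mm)
            if not np.allclose(steps, -DEPTH_GRID_MM, atol=1e-9):
                raise SchemaError("depth grid must descend in exact 0.1 mm steps")

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


class AnatomyModel:
    """A named anatomical region as a binary label volume or a closed mesh.

    Provides point-in-region and point-to-region-distance queries in world mm
    (RAS).  Volumes use nearest-voxel label lookup for the inside test and a
    KD-tree over boundary-voxel centers for distances (accurate to about half
    a voxel); meshes use a generalized winding number for containment and
    dense surface sampling for distances.
    """

    def __init__(self, name: str, *, volume: np.ndarray | None = None,
                 affine: np.ndarray | None = None, mesh=None, space: str = "patient"):
        if (volume is None) == (mesh is None):
            raise SchemaError("provide exactly one of volume or mesh")
        self.name = name
        self.space = space
        self.mesh = mesh
        if mesh is not None and not mesh.is_watertight:
            raise SchemaError(f"mesh for region {name!r} is not closed")
        self.affine = None if affine is None else np.asarray(affine, float)
        if volume is not None:
            if affine is None:
                raise SchemaError("a label volume requires an affine")
            volume = np.asarray(volume)
            uniq = np.unique(volume)
            if not np.all(np.isin(uniq, (0, 1))):
                raise SchemaError(f"label volume for {name!r} is not binary")
            self.volume = volume.astype(bool)
            self._inv_affine = np.linalg.inv(self.affine)
        else:
            self.volume = None
        self._surface_tree = None  # lazy boundary/surface KD-tree

    # -- queries ---------------------------------------------------------
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside test for an (n, 3) array of world-mm points."""
        points = np.atleast_2d(np.asarray(points, float))
        if self.volume is not None:
            ijk = (points @ self._inv_affine[:3, :3].T) + self._inv_affine[:3, 3]
            idx = np.rint(ijk).astype(int)
            ok = np.all((idx >= 0) & (idx < self.volume.shape), axis=1)
            out = np.zeros(len(points), bool)
            out[ok] = self.volume[tuple(idx[ok].T)]
            return out
        return _winding_contains(self.mesh, points)

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance (mm) to the region; 0 for points inside."""
        points = np.atleast_2d(np.asarray(points, float))
        if self.volume is not None:
            if not self.volume.any():
                raise SchemaError(f"region {self.name!r} is empty")
            if self._surface_tree is None:
                from scipy.spatial import cKDTree

                boundary = self.volume & ~ndimage.binary_erosion(self.volume)
                ijk = np.argwhere(boundary)
                centers = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
                self._surface_tree = cKDTree(centers)
            d = self._surface_tree.query(points)[0]
            d[self.contains(points)] = 0.0
            return d
        if self._surface_tree is None:
            from scipy.spatial import cKDTree

            # area-weighted dense surface sampling; distance error is of
            # the order of the mean inter-sample spacing (< 0.1 mm here)
            samples, _ = self.mesh.sample(50_000, return_index=True)
            self._surface_tree = cKDTree(np.vstack([samples, self.mesh.vertices]))
        d = self._surface_tree.query(points)[0]
        d[self.contains(points)] = 0.0
        return d

    @property
    def voxel_size_mm(self) -> float | None:
        if self.affine is None:
            return None
        return float(np.mean(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))))


def _winding_contains(mesh, points: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Point-in-mesh test by generalized winding number (watertight meshes).

    The solid angle subtended by every face is summed per point; the total
    is ~4π for interior points and ~0 for exterior ones.  Exact up to
    floating point for closed, consistently oriented meshes and requires no
    spatial index.
    """
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    out = np.empty(len(points), bool)
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        a = tri[None, :, 0] - p[:, None]  # (n, m, 3)
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("nmi,nmi->nm", a, np.cross(b, c))
        denom = (la * lb * lc + np.einsum("nmi,nmi->nm", a, b) * lc
                 + np.einsum("nmi,nmi->nm", b, c) * la
                 + np.einsum("nmi,nmi->nm", c, a) * lb)
        omega = 2.0 * np.arctan2(det, denom)
        out[s:s + chunk] = np.abs(omega.sum(axis=1)) > 2.0 * np.pi
    return out


@dataclass
class ShiftEstimate:
    """Per-trajectory electrophysiology-based brain-shift estimate."""

    trajectory_id: str
    max_xcorr: float  # in [-1, 1]
    lag_mm: float  # on the 0.1 mm grid; positive = physiological pattern above imaging
    imaging_shift_mm: float = np.nan  # imaging-derived estimate, when available

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.max_xcorr <= 1.0 + 1e-9:
            raise RangeError(f"max_xcorr must lie in [-1, 1], got {self.max_xcorr}")


@dataclass
class DensityGrid:
    """Cluster-density volume: per voxel, clusters / recordings within 1 mm."""

    affine: np.ndarray  # (4, 4); 0.22 mm isotropic by default
    n_clusters: np.ndarray
    n_recordings: np.ndarray
    density: np.ndarray = field(init=False)  # NaN where no recordings

    def __post_init__(self):
        self.affine = np.asarray(self.affine, float)
        self.n_clusters = np.asarray(self.n_clusters)
        self.n_recordings = np.asarray(self.n_recordings)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = self.n_clusters / self.n_recordings
        self.density = np.where(self.n_recordings > 0, d, np.nan)

    def voxel_centers(self) -> np.ndarray:
        """World-mm centers of all voxels, shape (n_voxels, 3), C order."""
        shape = self.density.shape
        idx = np.indices(shape).reshape(3, -1).T
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class VTASpec:
    """Spherical volume-of-tissue-activated specification."""

    center: np.ndarray
    amplitude_ma: float
    pulse_width_us: float
    k2: float = 0.8

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        if self.amplitude_ma < 0:
            raise RangeError("amplitude must be >= 0 mA")
        if self.pulse_width_us <= 0:
            raise RangeError("pulse width must be > 0 µs")
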