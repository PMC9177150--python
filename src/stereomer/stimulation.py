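"""Test-stimulation sphere model and streamline filtering.

The volume of tissue activated (VTA) during intraoperative test stimulation
is approximated as a sphere whose radius grows with stimulation amplitude
and pulse width and shrinks with the tissue constant k2.  Streamlines from a
normative bundle are kept when any of their segments passes through the
sphere, mimicking live activation tractography.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np

from .models import VTASpec

__all__ = ["vta_radius", "filter_streamlines", "vta_sphere"]

#: Reference pulse width for the default radius model, µs.
REFERENCE_PW_US = 90.0


def _default_radius_model(amplitude_ma: float, pulse_width_us: float, k2: float) -> float:
    # simplified sphere heuristic: radius^2 grows with charge per pulse,
    # inversely with the tissue activation constant k2
    return float(np.sqrt(amplitude_ma * (pulse_width_us / REFERENCE_PW_US) / k2))


def vta_radius(amplitude_ma: float, pulse_width_us: float, k2: float = 0.8,
               model: Callable[[float, float, float], float] | None = None) -> float:
    """Sphere radius (mm) of the activated volume.

    The radius model is pluggable; any replacement must satisfy the same
    contract as the default: zero radius at zero amplitude, strictly
    increasing in amplitude and pulse width, strictly decreasing in k2
    (k2 sits in the denominator).  k2 is conventionally explored in
    [0.5, 1.0]; values outside are allowed but logged, since the constant
    remains to be titrated against clinical observations.
    """
    if amplitude_ma < 0:
        raise ValueError("amplitude must be >= 0 mA")
    if pulse_width_us <= 0:
        raise ValueError("pulse width must be > 0 µs")
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    if not 0.5 <= k2 <= 1.0:
        warnings.warn(f"k2 = {k2} outside the conventional range [0.5, 1.0]", stacklevel=2)
    return (model or _default_radius_model)(amplitude_ma, pulse_width_us, k2)


def vta_sphere(spec: VTASpec, model=None) -> tuple[np.ndarray, float]:
    """Center and radius of the activated sphere for a stimulation setting."""
    return spec.center, vta_radius(spec.amplitude_ma, spec.pulse_width_us, spec.k2, model)


def _min_dist_to_segments(points: np.ndarray, center: np.ndarray) -> float:
    """Minimum distance from ``center`` to the polyline's segments (not just vertices)."""
    a, b = points[:-1], points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.zeros(len(a))
    nz = denom > 0
    t[nz] = np.einsum("ij,ij->i", center - a[nz], ab[nz]) / denom[nz]
    t = np.clip(t, 0.0, 1.0)
    feet = a + t[:, None] * ab
    return float(np.linalg.norm(feet - center, axis=1).min())


def filter_streamlines(polylines: list[np.ndarray], center: np.ndarray,
                       radius_mm: float) -> list[int]:
    """Indices of streamlines passing through the sphere.

    A streamline is kept iff any of its *segments* comes within the radius
    of the center — a vertex-only test would miss sparse polylines whose
    chord crosses the sphere between vertices.  Zero-length polylines are
    skipped with a warning.
    """
    center = np.asarray(center, float)
    kept = []
    for i, line in enumerate(polylines):
        pts = np.asarray(line, float)
        if len(pts) < 2 or np.allclose(pts.max(axis=0), pts.min(axis=0)):
            warnings.warn(f"skipping degenerate streamline {i}", stacklevel=2)
            continue
        if _min_dist_to_segments(pts, center) <= radius_mm:
            kept.append(i)
    return kept
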