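"""Focused bowl transducer model and Rayleigh-Sommerfeld free-field solver.

The source is an ideal, uniformly vibrating spherical-cap (bowl) radiator
described by its aperture diameter D and radius of curvature R.  The cap
is discretized into quasi-uniform surface patches; the free-field complex
pressure at any point r is then the Rayleigh-Sommerfeld summation

    p(r) = -i rho c k u0 / (2 pi) * sum_j A_j exp(i k d_j) / d_j,

with u0 the normal surface velocity, A_j the patch areas and d_j the
patch-to-field-point distances.  This serves both as a standalone
free-field simulator and as the independent reference for the FDTD
solver in :mod:`tfus.fdtd`.

Geometry convention: ``position`` is the bowl apex (deepest point);
``axis`` is the unit emission direction, so the geometric centre of
curvature sits at ``position + R * axis`` and the *exit plane* (the
plane through the bowl rim) at axial depth ``h = R - sqrt(R^2 - (D/2)^2)``
from the apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sonication import MediumConstants
from .volume import Volume

__all__ = [
    "TransducerGeometry",
    "SourcePatch",
    "discretize_bowl",
    "rayleigh_pressure",
    "freefield_pressure",
]


@dataclass(frozen=True)
class TransducerGeometry:
    """Single-element focused bowl.

    Parameters
    ----------
    aperture_diameter : float
        Aperture (rim) diameter D in metres.
    curvature_radius : float
        Radius of curvature R in metres; the geometric focus is at this
        distance from the apex along ``axis``.
    position : tuple
        Apex coordinates in metres.
    axis : tuple
        Emission direction (normalized internally).
    """

    aperture_diameter: float = 28e-3
    curvature_radius: float = 22e-3
    position: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.aperture_diameter <= 0 or self.curvature_radius <= 0:
            raise ValueError("aperture and curvature radius must be > 0")
        if self.aperture_diameter > 2 * self.curvature_radius + 1e-12:
            raise ValueError("aperture_diameter must be <= 2 * curvature_radius")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("axis must be non-zero")
        object.__setattr__(self, "axis", tuple(ax / n))
        object.__setattr__(self, "position", tuple(float(p) for p in self.position))

    @property
    def half_aperture_angle(self) -> float:
        """Polar half-angle of the cap rim seen from the centre of curvature."""
        return float(np.arcsin(0.5 * self.aperture_diameter / self.curvature_radius))

    @property
    def cap_depth(self) -> float:
        """Bowl depth h = R - sqrt(R^2 - (D/2)^2) (apex to exit plane)."""
        a = 0.5 * self.aperture_diameter
        return self.curvature_radius - float(np.sqrt(self.curvature_radius**2 - a**2))

    @property
    def cap_area(self) -> float:
        """Spherical-cap surface area 2 pi R h."""
        return 2.0 * np.pi * self.curvature_radius * self.cap_depth

    @property
    def focus(self) -> np.ndarray:
        """Geometric focus (= centre of curvature), metres."""
        return np.asarray(self.position) + self.curvature_radius * np.asarray(self.axis)

    @property
    def exit_plane_offset(self) -> float:
        """Axial distance from apex to the exit plane (= cap depth)."""
        return self.cap_depth

    def orthonormal_frame(self) -> tuple:
        """(e1, e2, axis) right-handed frame with axis last."""
        ax = np.asarray(self.axis)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, ax)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(ax, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(ax, e1)
        return e1, e2, ax


@dataclass(frozen=True)
class SourcePatch:
    """One element of the discretized radiating surface."""

    center: tuple
    area: float
    normal: tuple


def discretize_bowl(
    geom: TransducerGeometry,
    wavelength: float,
    patches_per_wavelength: int = 6,
) -> list[SourcePatch]:
    """Split the spherical cap into quasi-uniform-area patches.

    The cap is divided into polar rings of equal angular width sized so
    the patch edge is at most ``wavelength / patches_per_wavelength``;
    each ring is subdivided azimuthally to keep patches roughly square.
    Ring-band areas are computed exactly (2 pi R^2 (cos t0 - cos t1)), so
    the patch areas sum to the closed-form cap area to rounding error.
    """
    if patches_per_wavelength < 4:
        raise ValueError("patches_per_wavelength must be >= 4")
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    R = geom.curvature_radius
    theta_max = geom.half_aperture_angle
    target = wavelength / patches_per_wavelength
    n_rings = max(1, int(np.ceil(R * theta_max / target)))
    e1, e2, ax = geom.orthonormal_frame()
    center_of_curvature = geom.focus
    patches: list[SourcePatch] = []
    edges = np.linspace(0.0, theta_max, n_rings + 1)
    for t0, t1 in zip(edges[:-1], edges[1:]):
        tm = 0.5 * (t0 + t1)
        band_area = 2.0 * np.pi * R**2 * (np.cos(t0) - np.cos(t1))
        circumference = 2.0 * np.pi * R * np.sin(tm)
        n_phi = max(1, int(np.ceil(circumference / target)))
        phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
        # cap points: at angle tm from the -axis direction seen from the
        # centre of curvature (tm = 0 is the apex)
        radial = np.sin(tm) * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
        pts = center_of_curvature - R * np.cos(tm) * ax + R * radial
        normals = (center_of_curvature - pts) / R
        a = band_area / n_phi
        for p, n in zip(pts, normals):
            patches.append(SourcePatch(center=tuple(p), area=float(a), normal=tuple(n)))
    return patches


def rayleigh_pressure(
    patches: list[SourcePatch],
    points: np.ndarray,
    frequency: float,
    medium: MediumConstants,
    source_velocity: float = 1.0,
    chunk: int = 32,
) -> np.ndarray:
    """Complex Rayleigh-Sommerfeld pressure (Pa) at arbitrary points.

    ``points`` is (N, 3) in metres.  Field points closer than a tenth of
    the typical patch radius to a patch centre are regularized by
    clamping the distance (they are on the source surface, where the
    integral representation is singular anyway).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k = 2.0 * np.pi * frequency / medium.sound_speed
    coeff = -1j * medium.impedance * k * source_velocity / (2.0 * np.pi)
    centers = np.array([p.center for p in patches])
    areas = np.array([p.area for p in patches])
    d_min = 0.1 * np.sqrt(areas.mean() / np.pi)
    out = np.zeros(len(pts), dtype=np.complex128)
    for i0 in range(0, len(centers), chunk):
        c = centers[i0 : i0 + chunk]
        a = areas[i0 : i0 + chunk]
        d = np.linalg.norm(pts[:, None, :] - c[None, :, :], axis=-1)
        np.maximum(d, d_min, out=d)
        out += (np.exp(1j * k * d) / d) @ a
    return coeff * out


def freefield_pressure(
    geom: TransducerGeometry,
    frequency: float,
    medium: MediumConstants,
    shape: tuple,
    spacing: float,
    origin: tuple = (0.0, 0.0, 0.0),
    source_velocity: float = 1.0,
    patches_per_wavelength: int = 6,
) -> Volume:
    """Free-field pressure-amplitude volume (Pa) on a regular 3D grid.

    The grid spacing must resolve the field (<= lambda / 6).  The result
    is linear in ``source_velocity``; to hit a target focal pressure or
    I_SPPA, scale the returned field (or the drive) accordingly.
    """
    lam = medium.sound_speed / frequency
    if spacing > lam / 6 + 1e-12:
        raise ValueError("grid spacing must be <= lambda / 6")
    patches = discretize_bowl(geom, lam, patches_per_wavelength)
    axes = [origin[i] + spacing * np.arange(shape[i]) for i in range(3)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    amp = np.abs(
        rayleigh_pressure(patches, mesh, frequency, medium, source_velocity)
    ).reshape(shape)
    return Volume(data=amp, spacing=(spacing,) * 3, origin=origin)
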