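"""CT calibration and Hounsfield-unit to acoustic-property mapping.

A micro-CT scan of a skull, calibrated so that a water reference reads
0 HU, is converted voxel-by-voxel into the acoustic material fields the
wave solver needs: mass density, longitudinal sound speed and an
attenuation coefficient.  Voxels at or below a soft-tissue threshold take
soft-tissue (or water) constants; voxels at the cortical-bone ceiling
``hu_max`` take the cortical endpoints; in between, properties are
interpolated on the pseudo-porosity

    phi = 1 - HU / hu_max,

with density and sound speed linear in (1 - phi) and attenuation rising
with porosity as ``alpha_min + phi**beta * (alpha_max - alpha_min)``
(dense cortical bone attenuates least; porous, partial-volume bone
scatters most).  The endpoint constants are configurable; the defaults
are generic cortical-bone values at 200 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .sonication import MediumConstants, WATER_24C
from .volume import Volume

__all__ = [
    "PropertyMapping",
    "MaterialGrid",
    "LABEL_WATER",
    "LABEL_BRAIN",
    "LABEL_SKULL",
    "calibrate_hu",
    "resample_isotropic",
    "hu_to_properties",
    "build_material_grid",
]

LABEL_WATER = 0
LABEL_BRAIN = 1
LABEL_SKULL = 2


@dataclass(frozen=True)
class PropertyMapping:
    """Endpoints of the piecewise HU -> (rho, c, alpha) mapping.

    All attenuation values are in Np/m at the mapping's reference
    frequency (200 kHz by default).  ``alpha_bone_min`` applies to dense
    cortical bone (phi = 0) and ``alpha_bone_max`` to fully porous bone
    (phi = 1); ``beta`` shapes the porosity power law.
    """

    soft_threshold_hu: float = 300.0
    hu_max: float = 2000.0
    water: MediumConstants = WATER_24C
    soft: MediumConstants = MediumConstants(density=1040.0, sound_speed=1546.0)
    bone_density: float = 2100.0
    bone_speed: float = 2800.0
    alpha_water: float = 0.0
    alpha_soft: float = 0.25
    alpha_bone_min: float = 23.0
    alpha_bone_max: float = 60.0
    beta: float = 0.5
    reference_frequency: float = 200e3

    def __post_init__(self) -> None:
        if not 0 <= self.soft_threshold_hu < self.hu_max:
            raise ValueError("need 0 <= soft_threshold_hu < hu_max")
        if self.bone_density <= self.water.density:
            raise ValueError("bone density must exceed water density")
        if self.bone_speed <= self.soft.sound_speed:
            raise ValueError("bone speed must exceed soft-tissue speed")
        if self.alpha_bone_max < self.alpha_bone_min:
            raise ValueError("alpha_bone_max must be >= alpha_bone_min")


@dataclass
class MaterialGrid:
    """Voxelized acoustic properties on a regular grid.

    ``attenuation`` is in Np/m at the drive frequency.  ``tissue_label``
    uses LABEL_WATER / LABEL_BRAIN / LABEL_SKULL.
    """

    density: np.ndarray
    sound_speed: np.ndarray
    attenuation: np.ndarray
    tissue_label: np.ndarray
    spacing: float
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {
            self.density.shape,
            self.sound_speed.shape,
            self.attenuation.shape,
            self.tissue_label.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all material channels must share one shape")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.density <= 0) or np.any(self.sound_speed <= 0):
            raise ValueError("density and sound speed must be positive")
        if np.any(self.attenuation < 0):
            raise ValueError("attenuation must be non-negative")
        if self.origin is None:
            self.origin = (0.0,) * self.density.ndim

    @property
    def shape(self):
        return self.density.shape

    @property
    def ndim(self) -> int:
        return self.density.ndim

    @property
    def max_sound_speed(self) -> float:
        return float(self.sound_speed.max())

    @property
    def min_sound_speed(self) -> float:
        return float(self.sound_speed.min())

    @classmethod
    def homogeneous(
        cls,
        shape: tuple,
        spacing: float,
        medium: MediumConstants = WATER_24C,
        attenuation: float = 0.0,
        origin: tuple | None = None,
    ) -> "MaterialGrid":
        """Uniform water-like medium (free-field runs, 1D oracles)."""
        return cls(
            density=np.full(shape, medium.density, dtype=np.float32),
            sound_speed=np.full(shape, medium.sound_speed, dtype=np.float32),
            attenuation=np.full(shape, attenuation, dtype=np.float32),
            tissue_label=np.full(shape, LABEL_WATER, dtype=np.uint8),
            spacing=spacing,
            origin=origin if origin is not None else (0.0,) * len(shape),
        )


def calibrate_hu(ct: Volume, water_roi: np.ndarray) -> Volume:
    """Shift CT values so the water reference region averages 0 HU.

    The calibration is the affine offset ``HU -> HU - mean(water_roi)``;
    applying it twice is a no-op, and offsets between tissues (e.g. bone
    minus water) are preserved exactly.
    """
    water_roi = np.asarray(water_roi, dtype=bool)
    if water_roi.shape != ct.data.shape:
        raise ValueError("water_roi shape must match the CT volume")
    if not water_roi.any():
        raise ValueError("water_roi is empty")
    offset = float(np.mean(ct.data[water_roi]))
    return ct.copy(data=ct.data - offset)


def resample_isotropic(ct: Volume, target_spacing: float) -> Volume:
    """Trilinear down-sample to an isotropic grid of ``target_spacing`` (m).

    Intended for coarsening micro-CT voxels (tens of microns) to the
    simulation resolution (0.25 mm gives 30 voxels per 7.5 mm wavelength
    at 200 kHz in water).
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if any(target_spacing < s - 1e-12 for s in ct.spacing):
        raise ValueError("target_spacing must be >= the native spacing")
    factors = [s / target_spacing for s in ct.spacing]
    out = ndimage.zoom(np.asarray(ct.data, dtype=np.float32), factors, order=1)
    return Volume(data=out, spacing=(target_spacing,) * ct.data.ndim, origin=ct.origin)


def hu_to_properties(hu, mapping: PropertyMapping = PropertyMapping()):
    """Map calibrated HU values to (density, sound_speed, attenuation).

    Accepts scalars or arrays.  Density and sound speed are non-decreasing
    in HU; attenuation follows the porosity power law inside the bone
    range and is clamped to the cortical endpoints outside it.
    """
    hu_arr = np.asarray(hu, dtype=np.float64)
    m = mapping
    phi = np.clip(1.0 - hu_arr / m.hu_max, 0.0, 1.0)
    density = phi * m.water.density + (1.0 - phi) * m.bone_density
    speed = m.soft.sound_speed + (1.0 - phi) * (m.bone_speed - m.soft.sound_speed)
    atten = m.alpha_bone_min + phi**m.beta * (m.alpha_bone_max - m.alpha_bone_min)
    soft = hu_arr <= m.soft_threshold_hu
    density = np.where(soft, m.soft.density, density)
    speed = np.where(soft, m.soft.sound_speed, speed)
    atten = np.where(soft, m.alpha_soft, atten)
    water = hu_arr <= 0.0
    density = np.where(water, m.water.density, density)
    speed = np.where(water, m.water.sound_speed, speed)
    atten = np.where(water, m.alpha_water, atten)
    if np.isscalar(hu) or hu_arr.ndim == 0:
        return float(density), float(speed), float(atten)
    return density, speed, atten


def build_material_grid(
    ct: Volume,
    mapping: PropertyMapping = PropertyMapping(),
    labels: np.ndarray | None = None,
    frequency: float | None = None,
    brain_alpha_exponent: float = 2.0,
    bone_alpha_exponent: float = 1.0,
) -> MaterialGrid:
    """Build the :class:`MaterialGrid` for the wave solver from a
    calibrated, isotropically resampled CT volume.

    Voxels above the soft-tissue threshold are labelled skull; everything
    else is water unless a ground-truth ``labels`` array marks it brain.
    Water voxels carry the water constants exactly.  If ``frequency``
    differs from the mapping's reference frequency, attenuation is scaled
    by the power law ``alpha(f) = alpha0 * (f / f0)**b`` with separate
    exponents for soft tissue (default quadratic) and bone (default
    linear).
    """
    if not ct.is_isotropic:
        raise ValueError("material grid requires an isotropic CT volume")
    density, speed, atten = hu_to_properties(ct.data, mapping)
    skull = ct.data > mapping.soft_threshold_hu
    label = np.full(ct.data.shape, LABEL_WATER, dtype=np.uint8)
    label[skull] = LABEL_SKULL
    if labels is not None:
        brain = (np.asarray(labels) == LABEL_BRAIN) & ~skull
        label[brain] = LABEL_BRAIN
        density[brain] = mapping.soft.density
        speed[brain] = mapping.soft.sound_speed
        atten[brain] = mapping.alpha_soft
    water = label == LABEL_WATER
    density[water] = mapping.water.density
    speed[water] = mapping.water.sound_speed
    atten[water] = mapping.alpha_water
    if frequency is not None and frequency != mapping.reference_frequency:
        ratio = frequency / mapping.reference_frequency
        atten = np.where(
            label == LABEL_SKULL,
            atten * ratio**bone_alpha_exponent,
            atten * ratio**brain_alpha_exponent,
        )
    return MaterialGrid(
        density=density.astype(np.float32),
        sound_speed=speed.astype(np.float32),
        attenuation=atten.astype(np.float32),
        tissue_label=label,
        spacing=ct.spacing[0],
        origin=ct.origin,
    )
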