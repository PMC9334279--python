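"""Regular-grid volume container with NIfTI I/O.

A thin wrapper around a numpy array plus isotropic-or-not voxel spacing,
with read/write through nibabel.  Every gridded quantity in the package
(CT volumes, material property channels, pressure/intensity fields,
temperature snapshots) travels in this container so that spacing and
origin metadata survive each pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "load_volume", "save_volume"]


@dataclass
class Volume:
    """A scalar field sampled on a regular grid.

    Parameters
    ----------
    data : ndarray
        Voxel values, any dimensionality (typically 3D).
    spacing : tuple of float
        Voxel edge length per axis, in metres.
    origin : tuple of float
        World coordinate of voxel (0, 0, ...) centre, metres.
    """

    data: np.ndarray
    spacing: tuple
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match data dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = (0.0,) * self.data.ndim
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        return np.allclose(self.spacing, self.spacing[0], rtol=1e-6)

    def index_to_world(self, idx) -> np.ndarray:
        """World coordinates (m) of a (possibly fractional) voxel index."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else np.asarray(data),
            spacing=self.spacing,
            origin=self.origin,
        )


def save_volume(vol: Volume, path: str | Path) -> None:
    """Write a 3D volume as NIfTI; the affine encodes spacing (in mm) and
    origin, following the neuroimaging convention of millimetre units."""
    if vol.data.ndim != 3:
        raise ValueError("NIfTI export supports 3D volumes only")
    affine = np.diag([vol.spacing[0] * 1e3, vol.spacing[1] * 1e3, vol.spacing[2] * 1e3, 1.0])
    affine[:3, 3] = np.asarray(vol.origin) * 1e3
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; spacing/origin are taken from the affine and
    converted from millimetres to metres."""
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(s) * 1e-3 for s in nib.affines.voxel_sizes(affine)[:3])
    origin = tuple(float(v) * 1e-3 for v in affine[:3, 3])
    return Volume(data=np.asarray(img.dataobj, dtype=np.float32), spacing=spacing, origin=origin)
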