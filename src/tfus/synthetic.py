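"""Seeded synthetic-data generators with machine-readable ground truth.

Three generators cover every input the pipelines consume:

* :func:`make_phantom_ct` — a rat-scale skull phantom CT: an ellipsoidal
  bone shell of elevated Hounsfield units around a soft-tissue interior,
  air outside, and a cylindrical water calibration tube in the same
  volume.  The cavity defaults to ~14 x 18 x 12 mm so that, at a 7.5 mm
  wavelength (200 kHz in water), intracavity reverberation is
  geometrically plausible.

* :func:`make_section_set` — five coronal fluorescence sections with
  controllable per-section tracer-uptake fractions, placed around
  ventricle-like seeds, plus the exact ground-truth masks.

* :func:`make_foam_scan` — front and mid-section flatbed-scanner images
  of a dye-infiltrated foam block with known inlet diameter and depth.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .image_quant import FoamScan, SectionImage
from .skull_model import LABEL_BRAIN, LABEL_SKULL, LABEL_WATER
from .volume import Volume

__all__ = [
    "PhantomSpec",
    "SectionSetSpec",
    "make_phantom_ct",
    "phantom_tube_mask",
    "make_section_set",
    "make_foam_scan",
    "study_uptake_fractions",
    "make_study_sections",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Skull-phantom geometry and CT texture parameters."""

    outer_semiaxes_mm: tuple = (7.8, 9.8, 6.8)
    shell_thickness_mm: float = 0.8
    shell_hu_mean: float = 1700.0
    shell_hu_sigma: float = 80.0
    interior_hu: float = 30.0
    interior_hu_sigma: float = 10.0
    air_hu: float = -1000.0
    air_hu_sigma: float = 15.0
    tube_radius_mm: float = 1.5
    tube_hu_sigma: float = 3.0
    spacing_mm: float = 0.25
    margin_mm: float = 5.0
    hu_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_thickness_mm >= min(self.outer_semiaxes_mm):
            raise ValueError("shell thickness must be smaller than every semi-axis")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.tube_radius_mm + 1.0 > self.margin_mm:
            raise ValueError("margin too small to host the water tube")


def make_phantom_ct(spec: PhantomSpec = PhantomSpec()):
    """Generate (ct, labels, ground_truth) for a skull phantom.

    ``ct`` is the HU volume (including any global ``hu_offset`` to
    exercise water calibration), ``labels`` the ground-truth tissue
    labels (water/soft = 0 incl. the tube and exterior, brain = 1,
    skull = 2), and ``ground_truth`` a JSON-serializable dict with the
    geometry, the water-tube mask bounding box and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    dx = spec.spacing_mm
    a = np.asarray(spec.outer_semiaxes_mm, dtype=float)
    inner = a - spec.shell_thickness_mm
    half = a + spec.margin_mm
    shape = tuple(int(np.ceil(2 * h / dx)) + 1 for h in half)
    center = np.array([(n - 1) / 2 * dx for n in shape])
    grids = np.meshgrid(
        *[np.arange(n) * dx for n in shape], indexing="ij"
    )
    rel = [g - c for g, c in zip(grids, center)]

    r_out = sum((r / s) ** 2 for r, s in zip(rel, a))
    r_in = sum((r / s) ** 2 for r, s in zip(rel, inner))
    shell = (r_out <= 1.0) & (r_in > 1.0)
    interior = r_in <= 1.0

    # water tube: cylinder along axis 2, centred in the +x margin
    tube_x = a[0] + spec.margin_mm / 2.0
    tube_r2 = (rel[0] - tube_x) ** 2 + rel[1] ** 2
    tube = tube_r2 <= spec.tube_radius_mm**2

    hu = rng.normal(spec.air_hu, spec.air_hu_sigma, shape)
    hu[interior] = rng.normal(spec.interior_hu, spec.interior_hu_sigma, int(interior.sum()))
    hu[shell] = rng.normal(spec.shell_hu_mean, spec.shell_hu_sigma, int(shell.sum()))
    hu[tube] = rng.normal(0.0, spec.tube_hu_sigma, int(tube.sum()))
    hu += spec.hu_offset

    labels = np.full(shape, LABEL_WATER, dtype=np.uint8)
    labels[interior] = LABEL_BRAIN
    labels[shell] = LABEL_SKULL

    truth = {
        "outer_semiaxes_mm": list(spec.outer_semiaxes_mm),
        "inner_semiaxes_mm": [float(v) for v in inner],
        "shell_thickness_mm": spec.shell_thickness_mm,
        "center_mm": [float(c) for c in center],
        "tube_center_xy_mm": [float(center[0] + tube_x), float(center[1])],
        "tube_radius_mm": spec.tube_radius_mm,
        "hu_offset": spec.hu_offset,
        "spacing_mm": dx,
        "seed": spec.seed,
    }
    spacing_m = dx * 1e-3
    ct = Volume(data=hu.astype(np.float32), spacing=(spacing_m,) * 3)
    lab = Volume(data=labels, spacing=(spacing_m,) * 3)
    return ct, lab, truth


def phantom_tube_mask(ct: Volume, truth: dict) -> np.ndarray:
    """Ground-truth water-tube mask rebuilt from the sidecar geometry."""
    dx = truth["spacing_mm"]
    shape = ct.shape
    gx, gy = np.meshgrid(
        np.arange(shape[0]) * dx, np.arange(shape[1]) * dx, indexing="ij"
    )
    cx, cy = truth["tube_center_xy_mm"]
    disk = (gx - cx) ** 2 + (gy - cy) ** 2 <= truth["tube_radius_mm"] ** 2
    return np.broadcast_to(disk[:, :, None], shape).copy()


@dataclass(frozen=True)
class SectionSetSpec:
    """Synthetic fluorescence section set (five coronal planes)."""

    uptake_fractions: dict = field(
        default_factory=lambda: {
            "oa": (0.08, 0.12, 0.30, 0.12, 0.08),
            "fitc": (0.01, 0.01, 0.01, 0.01, 0.01),
        }
    )
    shape: tuple = (192, 240)
    brain_semiaxes_px: tuple = (80, 108)
    background_level: float = 40.0
    background_sigma: float = 2.0
    blob_intensity: float = 200.0
    blob_sigma: float = 10.0
    outside_level: float = 2.0
    periventricular: bool = True
    section_offsets_mm: tuple = (-2.0, -1.0, 0.0, 1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for fr in self.uptake_fractions.values():
            if len(fr) != len(self.section_offsets_mm):
                raise ValueError("need one uptake fraction per section")
            if any(not 0 <= f <= 1 for f in fr):
                raise ValueError("uptake fractions must lie in [0, 1]")
        if len(set(self.section_offsets_mm)) != len(self.section_offsets_mm):
            raise ValueError("section offsets must be unique")


def _uptake_mask(brain: np.ndarray, fraction: float, seeds, rng) -> np.ndarray:
    """Grow a mask of exactly round(fraction * brain area) pixels outward
    from the seed points (distance-rank growth, ties broken by jitter)."""
    target = int(round(fraction * brain.sum()))
    if target == 0:
        return np.zeros_like(brain, dtype=bool)
    yy, xx = np.mgrid[: brain.shape[0], : brain.shape[1]]
    d = np.full(brain.shape, np.inf)
    for sy, sx in seeds:
        d = np.minimum(d, np.hypot(yy - sy, xx - sx))
    d = d + rng.uniform(0, 1e-3, brain.shape)
    d[~brain] = np.inf
    flat = np.argsort(d, axis=None)[:target]
    mask = np.zeros(brain.size, dtype=bool)
    mask[flat] = True
    return mask.reshape(brain.shape)


def make_section_set(spec: SectionSetSpec = SectionSetSpec()):
    """Generate (sections, truth): five :class:`SectionImage` objects and
    per-section ground-truth uptake masks/fractions.

    Tracer pixels are placed around two ventricle-like seeds (or random
    in-brain seeds when ``periventricular`` is off) to the exact target
    pixel count, so the achieved fraction matches the request to within
    one pixel.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    cy, cx = (h - 1) / 2, (w - 1) / 2
    by, bx = spec.brain_semiaxes_px
    yy, xx = np.mgrid[:h, :w]
    brain = ((yy - cy) / by) ** 2 + ((xx - cx) / bx) ** 2 <= 1.0
    if spec.periventricular:
        seeds = [(cy, cx - 0.3 * bx), (cy, cx + 0.3 * bx)]
    else:
        iy, ix = np.argwhere(brain)[rng.integers(0, brain.sum(), 2)].T
        seeds = list(zip(iy.astype(float), ix.astype(float)))

    sections = []
    truth = []
    for i, offset in enumerate(spec.section_offsets_mm):
        channels = {}
        masks = {}
        achieved = {}
        for tracer, fracs in spec.uptake_fractions.items():
            mask = _uptake_mask(brain, fracs[i], seeds, rng)
            img = rng.normal(spec.outside_level, spec.background_sigma, (h, w))
            img[brain] = rng.normal(
                spec.background_level, spec.background_sigma, int(brain.sum())
            )
            img[mask] = rng.normal(spec.blob_intensity, spec.blob_sigma, int(mask.sum()))
            channels[tracer] = np.clip(img, 0, 255)
            masks[tracer] = mask
            achieved[tracer] = float(mask.sum() / brain.sum())
        sections.append(
            SectionImage(channels=channels, section_offset_mm=offset, brain_mask=brain)
        )
        truth.append(
            {
                "section_offset_mm": offset,
                "target_fractions": {t: spec.uptake_fractions[t][i] for t in channels},
                "achieved_fractions": achieved,
                "uptake_masks": masks,
                "brain_mask": brain,
            }
        )
    return sections, truth


def study_uptake_fractions(group: str, rng) -> dict:
    """Per-animal uptake fractions emulating the study conditions.

    Sonicated animals (groups ``V`` and ``D``) show ~30% ovalbumin
    uptake at the sonicated plane vs ~18% for unsonicated controls
    (``C``); neighbouring sections are unaffected, and the 2000 kDa
    dextran stays at ~1% everywhere.  Between-animal scatter is 2.5
    percentage points (s.d.).
    """
    if group not in ("C", "V", "D"):
        raise ValueError("group must be 'C', 'V' or 'D'")
    oa_base = np.array([0.08, 0.12, 0.18, 0.12, 0.08])
    if group in ("V", "D"):
        oa_base = oa_base.copy()
        oa_base[2] = 0.30
    oa = np.clip(oa_base + rng.normal(0, 0.025, 5), 0.0, 0.95)
    fitc = np.clip(0.01 + rng.normal(0, 0.003, 5), 0.0, 0.05)
    return {"oa": tuple(oa), "fitc": tuple(fitc)}


def make_study_sections(group: str, seed: int):
    """One animal's five-section set drawn from the study conditions."""
    rng = np.random.default_rng(seed)
    fractions = study_uptake_fractions(group, rng)
    spec = SectionSetSpec(uptake_fractions=fractions, seed=int(rng.integers(0, 2**31)))
    return make_section_set(spec)


def make_foam_scan(
    diameter_mm: float = 16.5,
    depth_mm: float = 6.1,
    mm_per_pixel: float = 0.25,
    shape: tuple = (160, 200),
    foam_level: float = 220.0,
    foam_sigma: float = 8.0,
    dye_level: float = 90.0,
    dye_sigma: float = 10.0,
    seed: int = 0,
):
    """Generate (front, section, truth): dye-infiltration scans of a foam
    block with a dark dye blob on a light textured background.

    Front view: a disk of the given inlet diameter.  Mid-section view: a
    half-ellipse hanging from the sonicated surface (row 0 side) with
    the given depth.  Pixels are counted by their centres, so recovered
    extents match the requested dimensions to within one pixel.
    """
    if diameter_mm <= 0 or depth_mm <= 0:
        raise ValueError("dimensions must be positive")
    h, w = shape
    r_px = diameter_mm / mm_per_pixel / 2.0
    depth_px = depth_mm / mm_per_pixel
    if 2 * r_px >= min(h, w) - 4 or depth_px >= h - 12:
        raise ValueError("blob exceeds the image")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[:h, :w]

    front_img = rng.normal(foam_level, foam_sigma, shape)
    disk = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2) <= r_px - 0.5
    front_img[disk] = rng.normal(dye_level, dye_sigma, int(disk.sum()))
    front = FoamScan(
        image=np.clip(front_img, 0, 255).astype(np.uint8),
        mm_per_pixel=mm_per_pixel,
        view="front",
    )

    section_img = rng.normal(foam_level, foam_sigma, shape)
    r0 = 8  # sonicated surface row
    half = (((yy - r0 + 0.5) / depth_px) ** 2 + ((xx - (w - 1) / 2) / r_px) ** 2 <= 1.0) & (
        yy >= r0
    )
    section_img[half] = rng.normal(dye_level, dye_sigma, int(half.sum()))
    section = FoamScan(
        image=np.clip(section_img, 0, 255).astype(np.uint8),
        mm_per_pixel=mm_per_pixel,
        view="mid-section",
    )
    truth = {
        "diameter_mm": diameter_mm,
        "depth_mm": depth_mm,
        "mm_per_pixel": mm_per_pixel,
        "seed": seed,
    }
    return front, section, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Sidecar JSON writer (masks are reduced to pixel counts)."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return int(obj.sum()) if obj.dtype == bool else obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    Path(path).write_text(json.dumps(clean(truth), indent=1))
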