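"""Linear acoustic FDTD solver on heterogeneous material grids.

First-order coupled pressure-velocity equations on a staggered grid,

    dv/dt = -(1/rho) grad p - gamma v,        gamma = 2 alpha c,
    dp/dt = -rho c^2 div v + rho c^2 q_m,

with attenuation (alpha in Np/m at the drive frequency) entering as an
exponential loss on the velocity update, and sources injected as a
distribution of volume-velocity monopoles (``q_m``).  A baffled surface
patch of area A vibrating at normal velocity u0 is equivalent to a free
monopole of volume velocity Q = 2 u0 A, which makes the discretized bowl
source consistent with the Rayleigh-Sommerfeld reference in
:mod:`tfus.transducer` by construction.

The engine is dimension-agnostic (1D validation lines, 2D planar
desk-scale runs, full 3D volumes).  Boundaries are absorbing sponge
layers (quadratic damping ramp, >= one wavelength thick by default).
The run continues until the per-period peak pressure at a monitor voxel
changes by less than a steady-state tolerance between consecutive
periods, then records the peak-to-peak pressure per voxel over one full
period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .skull_model import MaterialGrid
from .sonication import MediumConstants, PulseTrain, duty_cycle
from .transducer import TransducerGeometry, discretize_bowl
from .volume import Volume

__all__ = [
    "FDTDConfig",
    "SourceTerm",
    "FDTDResult",
    "IntensityField",
    "bowl_source",
    "arc_source_2d",
    "point_source",
    "run_fdtd",
    "run_fdtd_1d",
    "transmission_1d",
    "intensity_map",
    "cfl_time_step",
]


class StabilityError(RuntimeError):
    """Raised when the configuration violates the CFL bound."""


def cfl_time_step(spatial_step: float, max_sound_speed: float, ndim: int = 3) -> float:
    """CFL bound dt <= dx / (sqrt(ndim) * c_max) for the explicit scheme."""
    return spatial_step / (math.sqrt(ndim) * max_sound_speed)


@dataclass
class FDTDConfig:
    """Numerical controls for :func:`run_fdtd`.

    ``time_step=None`` picks 90% of the CFL bound, rounded so an integer
    number of steps fits one carrier period.  ``sponge_thickness=None``
    defaults to one wavelength in the fastest medium's *slowest* water
    path (i.e. lambda at the drive frequency in the slowest medium).
    """

    time_step: float | None = None
    cfl_number: float = 0.9
    steady_tolerance: float = 0.005
    min_periods: int | None = None
    max_periods: int = 400
    ramp_periods: float = 2.0
    sponge_thickness: float | None = None
    sponge_db: float = 60.0
    points_per_wavelength_min: float = 6.0


@dataclass
class SourceTerm:
    """Monopole source distribution.

    ``indices`` is a tuple of per-axis integer arrays (voxel bins) and
    ``volume_velocity`` the monopole strengths Q (m^3/s per monopole in
    3D, per-unit-length in 2D).  All monopoles are driven in phase at
    ``frequency`` with a cosine-tapered onset over ``ramp_periods``.
    """

    indices: tuple
    volume_velocity: np.ndarray
    frequency: float

    def __post_init__(self) -> None:
        self.volume_velocity = np.asarray(self.volume_velocity, dtype=np.float64)
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")


@dataclass
class FDTDResult:
    """Steady-state output of a run.

    ``p_pp`` holds the per-voxel peak-to-peak pressure (Pa) over the
    final recorded period, zeroed inside the sponge margin.  ``probe_amplitudes``
    are complex demodulated pressures at the requested probe voxels.
    """

    p_pp: Volume
    converged: bool
    n_periods: int
    monitor_history: np.ndarray
    probe_amplitudes: dict = field(default_factory=dict)
    sponge_voxels: int = 0


def point_source(index: tuple, volume_velocity: float, frequency: float) -> SourceTerm:
    idx = tuple(np.array([i]) for i in index)
    return SourceTerm(idx, np.array([volume_velocity]), frequency)


def bowl_source(
    geom: TransducerGeometry,
    mat: MaterialGrid,
    frequency: float,
    surface_velocity: float = 1.0,
    patches_per_wavelength: int | None = None,
) -> SourceTerm:
    """Bin the bowl's Rayleigh patches into grid voxels as monopoles.

    Each patch of area A contributes Q = 2 * u0 * A (baffled-radiator
    equivalence).  Patch size targets the voxel size so each source voxel
    receives ~one patch.
    """
    medium_speed = float(np.median(mat.sound_speed))
    lam = medium_speed / frequency
    if patches_per_wavelength is None:
        patches_per_wavelength = max(4, int(round(lam / mat.spacing)))
    patches = discretize_bowl(geom, lam, patches_per_wavelength)
    centers = np.array([p.center for p in patches])
    areas = np.array([p.area for p in patches])
    idx = np.round((centers - np.asarray(mat.origin)) / mat.spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(mat.shape)):
        raise ValueError("bowl source extends outside the material grid")
    # accumulate Q per voxel
    flat = np.ravel_multi_index(tuple(idx.T), mat.shape)
    uniq, inv = np.unique(flat, return_inverse=True)
    q = np.zeros(len(uniq))
    np.add.at(q, inv, 2.0 * surface_velocity * areas)
    return SourceTerm(np.unravel_index(uniq, mat.shape), q, frequency)


def arc_source_2d(
    apex: tuple,
    axis: tuple,
    aperture_diameter: float,
    curvature_radius: float,
    mat: MaterialGrid,
    frequency: float,
    surface_velocity: float = 1.0,
) -> SourceTerm:
    """2D planar analogue of the bowl: a focused circular arc.

    Segments of length ds contribute per-unit-length monopoles
    Q = 2 * u0 * ds.  Used for desk-scale qualitative runs; absolute
    calibration against the 3D Rayleigh integral does not apply in 2D.
    """
    if mat.ndim != 2:
        raise ValueError("arc source requires a 2D material grid")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    perp = np.array([-ax[1], ax[0]])
    theta_max = math.asin(0.5 * aperture_diameter / curvature_radius)
    center = np.asarray(apex, dtype=float) + curvature_radius * ax
    ds_target = mat.spacing
    n = max(5, int(math.ceil(2 * theta_max * curvature_radius / ds_target)))
    thetas = np.linspace(-theta_max, theta_max, n)
    ds = curvature_radius * (2 * theta_max / (n - 1))
    pts = center[None, :] - curvature_radius * (
        np.cos(thetas)[:, None] * ax[None, :] - np.sin(thetas)[:, None] * perp[None, :]
    )
    idx = np.round((pts - np.asarray(mat.origin)) / mat.spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(mat.shape)):
        raise ValueError("arc source extends outside the material grid")
    flat = np.ravel_multi_index(tuple(idx.T), mat.shape)
    uniq, inv = np.unique(flat, return_inverse=True)
    q = np.zeros(len(uniq))
    np.add.at(q, inv, 2.0 * surface_velocity * ds)
    return SourceTerm(np.unravel_index(uniq, mat.shape), q, frequency)


def _sponge_weights(shape, n_sp, s_max, dt):
    """Per-step multiplicative damping field (1 in the interior)."""
    total = np.zeros(shape, dtype=np.float64)
    for ax, n in enumerate(shape):
        coord = np.arange(n, dtype=np.float64)
        depth = np.maximum(n_sp - coord, coord - (n - 1 - n_sp))
        depth = np.clip(depth / max(n_sp, 1), 0.0, 1.0)
        prof = s_max * depth**2
        sl = [None] * len(shape)
        sl[ax] = slice(None)
        total += prof[tuple(sl)]
    return np.exp(-total * dt).astype(np.float32)


def run_fdtd(
    mat: MaterialGrid,
    source: SourceTerm,
    cfg: FDTDConfig | None = None,
    monitor_index: tuple | None = None,
    probe_indices: dict | None = None,
) -> FDTDResult:
    """Drive the material grid to harmonic steady state and record P_pp.

    Raises :class:`StabilityError` on CFL violation or if the grid does
    not resolve the wavelength in the slowest medium (>= 6 points per
    wavelength required); aborts with diagnostics on NaN.
    """
    cfg = cfg or FDTDConfig()
    dx = mat.spacing
    ndim = mat.ndim
    f = source.frequency
    period = 1.0 / f
    c_max = mat.max_sound_speed
    c_min = mat.min_sound_speed
    lam_min = c_min / f
    if dx > lam_min / cfg.points_per_wavelength_min + 1e-12:
        raise StabilityError(
            f"dx={dx} gives {lam_min / dx:.1f} points per wavelength; "
            f">= {cfg.points_per_wavelength_min} required"
        )
    dt_cfl = cfl_time_step(dx, c_max, ndim)
    dt = cfg.time_step if cfg.time_step is not None else cfg.cfl_number * dt_cfl
    if dt > dt_cfl + 1e-18:
        raise StabilityError(f"time step {dt} exceeds CFL bound {dt_cfl}")
    steps_per_period = int(math.ceil(period / dt))
    dt = period / steps_per_period

    rho = np.asarray(mat.density, dtype=np.float32)
    c = np.asarray(mat.sound_speed, dtype=np.float32)
    kappa = rho * c * c
    p = np.zeros(mat.shape, dtype=np.float32)

    # face-centred inverse density and attenuation damping per axis
    inv_rho_face = []
    damp_face = []
    gamma = 2.0 * np.asarray(mat.attenuation, dtype=np.float32) * c
    for ax in range(ndim):
        s0 = [slice(None)] * ndim
        s1 = [slice(None)] * ndim
        s0[ax] = slice(0, -1)
        s1[ax] = slice(1, None)
        rf = 0.5 * (rho[tuple(s0)] + rho[tuple(s1)])
        gf = 0.5 * (gamma[tuple(s0)] + gamma[tuple(s1)])
        inv_rho_face.append((1.0 / rf).astype(np.float32))
        damp_face.append(np.exp(-gf * dt).astype(np.float32))
    v = [np.zeros(inv_rho_face[ax].shape, dtype=np.float32) for ax in range(ndim)]

    # sponge
    sponge_m = cfg.sponge_thickness if cfg.sponge_thickness is not None else lam_min
    n_sp = int(math.ceil(sponge_m / dx))
    amp_ln = math.log(10.0 ** (cfg.sponge_db / 20.0))
    s_max = 3.0 * amp_ln * c_max / (n_sp * dx) if n_sp > 0 else 0.0
    w_p = _sponge_weights(mat.shape, n_sp, s_max, dt)
    w_v = []
    for ax in range(ndim):
        s0 = [slice(None)] * ndim
        s1 = [slice(None)] * ndim
        s0[ax] = slice(0, -1)
        s1[ax] = slice(1, None)
        w_v.append(0.5 * (w_p[tuple(s0)] + w_p[tuple(s1)]))
    sponge_active = bool(np.any(w_p < 1.0))

    # source coefficients: dp += dt * kappa * Q * s(t) / V_cell
    cell_volume = dx**ndim
    src_idx = source.indices
    src_coef = (kappa[src_idx] * source.volume_velocity / cell_volume).astype(np.float64)
    omega = 2.0 * math.pi * f
    ramp_steps = int(round(cfg.ramp_periods * steps_per_period))

    if monitor_index is None:
        monitor_index = tuple(int(np.mean(ix)) for ix in src_idx)
    probe_indices = probe_indices or {}

    if cfg.min_periods is None:
        diag = math.sqrt(sum((n * dx) ** 2 for n in mat.shape))
        min_periods = int(math.ceil(diag / (c_min * period))) + int(math.ceil(cfg.ramp_periods)) + 3
    else:
        min_periods = cfg.min_periods

    def envelope(step: int) -> float:
        if step >= ramp_steps:
            return 1.0
        x = step / ramp_steps
        return 0.5 * (1.0 - math.cos(math.pi * x))

    monitor_history: list[float] = []
    step = 0
    converged = False
    prev_peak = None
    n_periods = 0
    while n_periods < cfg.max_periods:
        peak = 0.0
        for _ in range(steps_per_period):
            t = (step + 0.5) * dt
            # velocity update
            for ax in range(ndim):
                dp = np.diff(p, axis=ax)
                v[ax] *= damp_face[ax]
                v[ax] -= (dt / dx) * inv_rho_face[ax] * dp
                if sponge_active:
                    v[ax] *= w_v[ax]
            # pressure update
            for ax in range(ndim):
                pad = [(0, 0)] * ndim
                pad[ax] = (1, 1)
                dv = np.diff(np.pad(v[ax], pad), axis=ax)
                p -= (dt / dx) * kappa * dv
            drive = math.sin(omega * t) * envelope(step)
            p[src_idx] += dt * src_coef * drive
            if sponge_active:
                p *= w_p
            peak = max(peak, abs(float(p[monitor_index])))
            step += 1
        n_periods += 1
        if not math.isfinite(peak):
            raise RuntimeError(
                f"FDTD diverged (NaN/inf) at period {n_periods}; "
                f"dt={dt:.3e}, dx={dx:.3e}, c_max={c_max}"
            )
        monitor_history.append(peak)
        if prev_peak is not None and n_periods >= min_periods and peak > 0:
            if abs(peak - prev_peak) / peak < cfg.steady_tolerance:
                converged = True
                break
        prev_peak = peak

    # record one full period: per-voxel min/max and probe demodulation
    pmin = p.copy()
    pmax = p.copy()
    demod = {name: 0.0 + 0.0j for name in probe_indices}
    for _ in range(steps_per_period):
        t = (step + 0.5) * dt
        for ax in range(ndim):
            dp = np.diff(p, axis=ax)
            v[ax] *= damp_face[ax]
            v[ax] -= (dt / dx) * inv_rho_face[ax] * dp
            if sponge_active:
                v[ax] *= w_v[ax]
        for ax in range(ndim):
            pad = [(0, 0)] * ndim
            pad[ax] = (1, 1)
            dv = np.diff(np.pad(v[ax], pad), axis=ax)
            p -= (dt / dx) * kappa * dv
        drive = math.sin(omega * t) * envelope(step)
        p[src_idx] += dt * src_coef * drive
        if sponge_active:
            p *= w_p
        np.minimum(pmin, p, out=pmin)
        np.maximum(pmax, p, out=pmax)
        for name, idx in probe_indices.items():
            demod[name] += float(p[idx]) * np.exp(-1j * omega * t)
        step += 1
    for name in demod:
        demod[name] *= 2.0 / steps_per_period

    p_pp = (pmax - pmin).astype(np.float32)
    if n_sp > 0:
        margin = np.zeros(mat.shape, dtype=bool)
        for ax in range(ndim):
            sl = [slice(None)] * ndim
            sl[ax] = slice(0, n_sp)
            margin[tuple(sl)] = True
            sl[ax] = slice(mat.shape[ax] - n_sp, None)
            margin[tuple(sl)] = True
        p_pp[margin] = 0.0

    return FDTDResult(
        p_pp=Volume(data=p_pp, spacing=(dx,) * ndim, origin=mat.origin),
        converged=converged,
        n_periods=n_periods,
        monitor_history=np.asarray(monitor_history),
        probe_amplitudes=demod,
        sponge_voxels=n_sp,
    )


def run_fdtd_1d(
    mat: MaterialGrid,
    frequency: float,
    source_index: int,
    probe_indices: dict,
    volume_velocity: float = 1e-6,
    cfg: FDTDConfig | None = None,
) -> FDTDResult:
    """1D validation variant: returns demodulated complex probe amplitudes."""
    if mat.ndim != 1:
        raise ValueError("run_fdtd_1d requires a 1D material grid")
    src = point_source((source_index,), volume_velocity, frequency)
    probes = {k: (v,) if np.isscalar(v) else v for k, v in probe_indices.items()}
    return run_fdtd(mat, src, cfg, monitor_index=(source_index,), probe_indices=probes)


def transmission_1d(
    medium1: MediumConstants,
    medium2: MediumConstants,
    frequency: float,
    layer_wavelengths: float = 6.0,
    points_per_wavelength: int = 24,
) -> dict:
    """Measure steady-state pressure transmission/reflection at a planar
    interface between two half-spaces and compare with the Fresnel
    coefficients T = 2 Z2 / (Z1 + Z2), R = (Z2 - Z1) / (Z1 + Z2).

    Runs a reference homogeneous line (for the incident amplitude at the
    interface position) and the two-layer line, then demodulates probe
    pressures.  Returns measured and analytic coefficients.
    """
    lam1 = medium1.sound_speed / frequency
    dx = lam1 / points_per_wavelength
    n_layer = int(round(layer_wavelengths * lam1 / dx))
    n_sp = int(math.ceil(lam1 / dx))
    n = 2 * n_layer + 2 * n_sp
    interface = n_sp + n_layer

    def make(two_layer: bool) -> MaterialGrid:
        m = MaterialGrid.homogeneous((n,), dx, medium1)
        if two_layer:
            m.density[interface:] = medium2.density
            m.sound_speed[interface:] = medium2.sound_speed
        return m

    src_i = n_sp + 2
    probe_t = interface + n_layer // 2
    cfg = FDTDConfig(min_periods=int(3 * layer_wavelengths) + 6)
    ref = run_fdtd_1d(
        make(False), frequency, src_i, {"inc": interface, "t": probe_t}, cfg=cfg
    )
    lay = run_fdtd_1d(
        make(True), frequency, src_i, {"inc": interface, "t": probe_t}, cfg=cfg
    )
    a_inc = abs(ref.probe_amplitudes["inc"])
    a_t = abs(lay.probe_amplitudes["t"])
    z1, z2 = medium1.impedance, medium2.impedance
    return {
        "T_measured": a_t / a_inc,
        "T_analytic": 2.0 * z2 / (z1 + z2),
        "R_analytic": (z2 - z1) / (z1 + z2),
        "converged": ref.converged and lay.converged,
    }


@dataclass
class IntensityField:
    """Per-voxel intensity maps derived from a steady-state pressure field.

    ``isppa`` and ``ispta`` are in W/cm^2 (the conventional reporting
    unit); ``relative`` is isppa normalized to its maximum.
    """

    isppa: Volume
    ispta: Volume
    relative: Volume


def intensity_map(p_pp: Volume, mat: MaterialGrid, pulse: PulseTrain) -> IntensityField:
    """I_SPPA = (P_pp / 2)^2 / (2 rho c) with the local density and sound
    speed; I_SPTA = I_SPPA * duty cycle.  Output in W/cm^2."""
    if p_pp.data.shape != mat.shape:
        raise ValueError("pressure field and material grid shapes differ")
    amp = np.asarray(p_pp.data, dtype=np.float64) / 2.0
    isppa = amp**2 / (2.0 * mat.density * mat.sound_speed) / 1e4
    dc = duty_cycle(pulse)
    peak = isppa.max()
    rel = isppa / peak if peak > 0 else isppa
    mk = lambda d: Volume(data=d, spacing=p_pp.spacing, origin=p_pp.origin)
    return IntensityField(
        isppa=mk(isppa), ispta=mk(isppa * dc), relative=mk(rel)
    )
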