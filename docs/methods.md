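# Methods

`tfus` models the physics and analysis chain of a low-intensity pulsed
transcranial focused ultrasound (tFUS) experiment in the rat: the pulsed
sonication scheme, the acoustic field the focused bowl creates through
the skull, the temperature rise that field can produce, and the image
quantification used to measure dye transport in foam blocks and
fluorescent CSF-tracer uptake in brain sections.  This note records the
models, their assumptions, the tunable constants and the deliberate
design choices; everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`, not asserted from memory.

## Sonication parameter algebra

A pulse train is specified by carrier frequency (200 kHz default
throughout), pulse duration PD, pulse repetition frequency PRF and total
duration.  Duty cycle is DC = PD·PRF ∈ (0, 1], with DC = 1 the
continuous-wave limit; overlapping pulses (PD·PRF > 1) are rejected.
Intensities follow I_SPTA = I_SPPA·DC, and the plane-wave link between
pulse-average intensity and peak pressure is

    I_SPPA = P_r² / (2 ρ c),    P (peak-to-peak) = 2 P_r,

valid in the linear regime.  Every conversion site names its pressure
convention explicitly, because bench reports mix peak-rarefactional and
peak-to-peak conventions freely.  Default water constants are
ρ = 997 kg/m³, c = 1494 m/s (≈24 °C, a room-temperature degassed bath);
with them, I_SPPA = 5 W/cm² ↔ P_r ≈ 386 kPa.  Display rounding is two
decimals; internal values are never rounded.

## Focused bowl source and free field

The transducer is an ideal uniformly vibrating spherical cap, aperture
D = 28 mm and radius of curvature R = 22 mm by default, with no
apodization.  The cap is discretized into quasi-uniform-area patches
(ring decomposition with exact band areas), and the free-field complex
pressure is the Rayleigh–Sommerfeld sum over patches.  An independent
1D polar-angle quadrature of the same integral serves as the on-axis
oracle; patch summation agrees with it to better than 2% at six patches
per wavelength, and halving the patch size changes the focal pressure
by well under 1%.

The *exit plane* is the plane through the bowl rim, a cap depth
h = R − sqrt(R² − (D/2)²) ≈ 5.03 mm beyond the apex.  Diffraction pulls
the axial pressure maximum inward from the centre of curvature: with
the default geometry the peak sits ≈15.5 mm from the apex, i.e. ≈10.5 mm
from the exit plane, and the −6 dB focal spot measures ≈6.7 mm across
and ≈25 mm long.  These are free-field predictions of an ideal cap; a
physical element with a non-ideal velocity distribution will differ at
the ten-percent level, which is why field metrics carry wide
comparisons, not exact ones.

## CT to acoustic properties

CT volumes are calibrated by an affine shift so a water reference region
averages 0 HU (idempotent, contrast-preserving), then down-sampled
trilinearly to an isotropic simulation grid — 0.25 mm by default, i.e.
30 voxels per 7.5 mm wavelength.  Voxel properties follow a
piecewise-linear map on the pseudo-porosity φ = 1 − HU/HU_max:

* HU ≤ 0: water constants exactly; 0 < HU ≤ soft threshold (300 HU):
  soft-tissue constants (1040 kg/m³, 1546 m/s, 0.25 Np/m);
* soft threshold < HU < HU_max (2000): ρ and c linear in (1 − φ) between
  water/soft and cortical endpoints (2100 kg/m³, 2800 m/s); attenuation
  α = α_min + φ^β (α_max − α_min) with α_min = 23 Np/m (dense cortical
  bone), α_max = 60 Np/m (porous bone), β = 0.5 — porous bone scatters
  more than dense bone, so attenuation *falls* toward the cortical
  endpoint;
* HU ≥ HU_max: cortical endpoints.

All endpoints are configuration values, not measurements: the mapping
constants published for skull at these frequencies vary widely, and the
defaults here are generic stand-ins chosen once.  Attenuation scales
with frequency as a power law (exponent 1 for bone, 2 for soft tissue
by default) from its 200 kHz reference.

## Acoustic FDTD

First-order pressure–velocity equations on a staggered grid, attenuation
as an exponential loss on the velocity update (γ = 2αc, exact for a
single frequency), explicit leapfrog stepping under the CFL bound
dt ≤ dx/(√d·c_max).  At dx = 0.25 mm and c_max = 2800 m/s the 3D bound
is ≈0.0515 µs, which is why a 0.05 µs step is a natural choice at this
resolution.  A minimum of six grid points per wavelength in the slowest
medium is enforced.

The source is injected as a distribution of volume-velocity monopoles:
a baffled surface patch of area A vibrating at u₀ is equivalent to a
free monopole of volume velocity Q = 2u₀A, so the discretized bowl in
the FDTD grid is, by construction, the same source the
Rayleigh–Sommerfeld reference integrates.  This makes the free-field
comparison between the two solvers a genuine two-route check (they agree
within 3% at the focus on a 15-points-per-wavelength grid), limited by
numerical dispersion and voxel binning rather than source calibration.
The drive ramps on with a two-period cosine taper to limit the startup
transient.

Boundaries are absorbing sponge layers: one wavelength thick by
default, quadratic damping profile scaled for ≈60 dB one-way
attenuation.  The run is declared steady when the per-period peak
pressure at a monitor voxel changes by <0.5% between consecutive
periods (with a minimum period count derived from the domain transit
time); one further period is then recorded for the per-voxel
peak-to-peak pressure, and probe pressures are demodulated at the drive
frequency for complex amplitudes.  The engine is dimension-agnostic:
1D lines validate against the Fresnel transmission coefficient
T = 2Z₂/(Z₁+Z₂) (≤1% error) and Beer–Lambert decay e^{−αL} (≤2%); 2D
planar scenes support fast desk-scale exploration; 3D volumes are used
wherever quantitative structure matters.

Intensity maps use the local impedance: I_SPPA = (P_pp/2)²/(2ρc),
I_SPTA = I_SPPA·DC, plus a max-normalized relative map.  Reported
percent transmission is relative to the free-water focal I_SPPA from an
otherwise identical run without the skull.

### Transcranial scene and reverberation

The packaged scene places the bowl above a rat-scale skull phantom
(ellipsoidal bone shell, outer semi-axes 7.8 × 9.8 × 6.8 mm, 0.8 mm
thick, i.e. an interior cavity of roughly 14 × 18 × 12 mm) with the
geometric focus targeted 1 mm below the outer skull surface — the
in-vivo targeting depth.  Because the cavity is only ≈1.6 wavelengths
tall at 200 kHz, reflections from the skull base interfere with the
incident field and produce standing-wave antinodes inside the cavity.
In the coarse-3D runs the strongest intracavity antinode sits near the
cavity midpoint and exceeds the antinode nearest the geometric focus,
and the overall maximum lies at the outer skull surface facing the
transducer (evaluated, like the tabulated bench convention, on the
coupling-water side of the interface where the impedance is water's).
A 2D planar slice of the same scene shows the same qualitative standing
wave pattern but *underestimates* the mid-cavity maximum relative to
the focal one: the curved shell refocuses reflected energy toward the
cavity interior far more effectively in 3D.  Qualitative reverberation
conclusions are therefore drawn from the 3D runs only.

## Pennes bioheat solver

Explicit FDTD for ρc_t ∂T/∂t = ∇·(k∇T) + q − w_b c_b (T − T_a), with
face-averaged conductivity, fixed-temperature (default) or insulated
outer boundary, and a stability bound combining conduction and
perfusion.  Tissue constants: brain c_t = 3600 J/kg/K, k = 0.528 W/K/m,
perfusion 8.24 kg/m³/s; skull c_t = 1300 J/kg/K, k = 0.4 W/K/m, no
perfusion; blood ρ = 1030 kg/m³, c_b = 3620 J/kg/K; arterial and
initial temperature 37.5 °C.  Densities for brain (1040 kg/m³) and
skull (1900 kg/m³) are conventional values, configurable.  CSF
pulsation and thermoregulation are deliberately not modelled, which
overestimates heating.

The acoustic heat source is q = 2αI.  In *duty-averaged* mode
I = I_SPTA and q is constant — valid because the equation is linear and
thermal time constants (perfusion τ = ρc_t/(w_b c_b) ≈ 125 s) dwarf the
pulse period; *pulse-resolved* mode gates q = 2αI_SPPA with the binary
pulse envelope at a 0.5 ms default step and is used to validate the
averaging on short windows.  Brain amplitude absorption at 200 kHz is
the single most result-sensitive free constant; the default 0.25 Np/m
(≈0.022 dB/cm) corresponds to quadratic-in-frequency scaling of a
≈0.55 dB/cm/MHz soft-tissue attenuation, and it is exposed in the
configuration.

Oracles: with conduction off, every voxel follows the lumped perfusion
ODE (steady ΔT = q/(w_b c_b), t₉₅ = 2.996τ); without perfusion the
centre of a Gaussian source follows the closed form
ΔT(0,t) = (q₀σ²/k)(1 − (1 + 2κt/σ²)^{−1/2}), whose t→∞ limit is the
Green's-function value q₀σ²/k; with perfusion the steady centre value
is the screened integral ∫q e^{−r/L}/(4πkr) d³r with
L = sqrt(k/(w_b c_b)) ≈ 4.2 mm, evaluated by quadrature.  The solver
matches all three within 3% on the grids the tests use.

The thermal-safety scene deposits a duty-averaged Gaussian source
(σ = 2.1 mm, focal in-situ I_SPTA = 0.65 W/cm², α = 0.25 Np/m — peak
q₀ = 3250 W/m³) in a 40 mm brain cube at dx = 0.5 mm, dt = 0.1 s for a
30 min sonication.  σ is the Gaussian equivalent of the measured ≈5 mm
lateral focal diameter at the 90% pressure level; the in-situ I_SPTA
corresponds to an intracavity I_SPPA of 6.5 W/cm² at 10% duty cycle.
The computed peak elevation is ≈0.015 °C — comfortably below the 0.03 °C
scale that marks the exposure as non-thermal — and the focal temperature
reaches 95% of its steady value in ≈2 min, well inside the sonication
duration.

## Image quantification

**Foam dye infiltration.**  Dye is darker than foam on a flatbed scan,
so segmentation keeps pixels ≤150 (8-bit scale; the polarity is
configurable for scanners that invert).  The largest connected
component is measured: front views report the maximal Feret extent as
the inlet diameter (robust to ragged blobs); mid-section views report
the extent along the sonication axis (image rows, surface at the top)
as the depth.  An empty segmentation reports zero with a flag.

**Tracer uptake.**  Each fluorescence channel is min–max normalized to
0–255.  The brain mask is supplied externally when available; the
automatic fallback takes the per-pixel maximum across channels, applies
the lowest multi-Otsu threshold (which separates the dark exterior from
tissue even when a bright tracer deposit makes the histogram trimodal),
keeps the largest component and fills holes.  The background is the
minimum normalized intensity inside the brain mask, floored at one grey
level so the threshold 1.7×background can never degenerate to zero;
pixels above that threshold inside the brain count as uptake, and the
result is the percent of brain area covered.  The measure is invariant
to affine intensity rescaling up to quantization.

**Statistics.**  Group comparisons are one-way ANOVA followed by Tukey
HSD at α = 0.05 (statsmodels), and two-tailed paired t-tests (scipy).
Monte-Carlo null calibration of the family-wise error uses the
balanced-design form of the same decision rule — the studentized range
statistic against a critical value computed once from scipy's
studentized-range distribution — because running the per-dataset Tukey
machinery 10⁴ times is needlessly slow; a test asserts the two routes
make identical decisions on sampled datasets.  The observed family-wise
error over 10⁴ null triples is within ±0.01 of the nominal 0.05.

## Synthetic data: what it does and does not emulate

The generators are seeded and deterministic, and every output carries
machine-readable ground truth.

* The skull phantom emulates the gross acoustic geometry that drives
  low-frequency reverberation — a closed thin bone shell with elevated,
  textured HU around soft tissue, with a water calibration tube — but
  not trabecular microstructure, sutures, or the true HU→property
  relation of any individual skull.
* The fluorescence sections emulate per-section uptake fractions with
  peri-ventricular placement and realistic group structure (sonicated
  ≈30% vs control ≈18% ovalbumin at the target plane, ≈1% dextran
  everywhere, 2.5-point between-animal scatter) but not anatomy,
  perivascular detail or imaging artefacts.
* The foam scans emulate blob geometry and scanner texture, not real
  dye diffusion profiles.

Passing tests on these inputs therefore demonstrates that the pipelines
recover known ground truth and reproduce the *structure* of the
reported effects, not that they would return the same numbers on the
original data.

## Numerical choices

* FDTD defaults: CFL number 0.9, steady tolerance 0.5%/period, sponge
  one wavelength at 60 dB, ramp two periods.  float32 fields.
* Bioheat: explicit step at half the stability bound (duty-averaged) or
  0.5 ms (pulse-resolved); compiled with numba, with a vectorized numpy
  fallback.
* Profile widths interpolate level crossings linearly between samples;
  local maxima use a full 26-neighbourhood filter, a prominence floor of
  25% of the global maximum and a 2 mm minimum separation, both
  configurable since the underlying identification is visual in bench
  practice.
* Label classification of intracranial maxima projects candidates onto
  the beam axis, splits the skull into the entry and far shells, and
  assigns: iv = strongest candidate in the entry-shell band, iii =
  strongest near the far brain–bone interface (1-voxel erosion rule),
  i = intracavity candidate nearest the geometric focus, ii =
  remaining intracavity candidate nearest the cavity midpoint.

## Known limitations

* Linear acoustics only: no nonlinearity, cavitation or shear waves in
  bone; single-frequency harmonic steady state, no broadband pulses.
* The ideal-cap transducer model ignores the element's real velocity
  distribution; measured focal positions and widths of a physical
  device can deviate by tens of percent.
* The HU→property mapping constants are stand-ins; per-skull acoustic
  truth requires calibrated measurements.
* Acoustic streaming and CSF solute transport are *not* modelled: the
  package quantifies fields, heating and images, not the fluid dynamics
  linking them.
* Not reproducible here, and documented as such rather than simulated:
  the in-vivo uptake percentages (they require the original animal
  imaging data), the per-skull simulated intensity/pressure tables
  (they require the original ex-vivo skull CT volumes), and the wet-lab
  foam infiltration distances (16.5 ± 1.6 mm diameter, 6.1 ± 1.0 mm
  depth are empirical outcomes of real dye transport; the synthetic
  foam scans only verify that the measurement recovers known geometry).
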