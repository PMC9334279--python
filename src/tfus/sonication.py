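"""Pulsed-sonication parameter algebra and pressure-intensity conversions.

Low-intensity pulsed focused ultrasound protocols are specified by a small
set of temporal parameters: the fundamental frequency (FF) of the carrier,
the pulse duration (PD), the pulse repetition frequency (PRF), and the
overall sonication duration.  PD and PRF jointly fix the duty cycle
DC = PD * PRF, the fraction of time the transducer is actively emitting.
Acoustic dose is expressed either as the spatial-peak pulse-average
intensity (I_SPPA, intensity while the pulse is on) or the spatial-peak
temporal-average intensity (I_SPTA = I_SPPA * DC).

In the linear plane-wave regime, intensity and peak pressure in a medium
with characteristic impedance rho*c are related by

    I_SPPA = P_r**2 / (2 * rho * c),

with P_r the peak-rarefactional pressure and P = 2 * P_r the peak-to-peak
pressure.  These conversions are the single source of truth for every
other module in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "PulseTrain",
    "MediumConstants",
    "WATER_24C",
    "WATER_20C",
    "duty_cycle",
    "isppa_for_ispta",
    "ispta_from_isppa",
    "pressure_from_intensity",
    "intensity_from_pressure",
    "pulse_envelope",
    "wavelength",
]

PressureConvention = Literal["peak-rarefactional", "peak-to-peak"]


class InvalidParameterError(ValueError):
    """Raised when sonication parameters violate their physical constraints."""


@dataclass(frozen=True)
class MediumConstants:
    """Acoustic constants of a homogeneous medium.

    Parameters
    ----------
    density : float
        Mass density ``rho`` in kg/m^3.
    sound_speed : float
        Longitudinal sound speed ``c`` in m/s.
    """

    density: float
    sound_speed: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.sound_speed <= 0:
            raise InvalidParameterError("density and sound_speed must be > 0")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance ``rho * c`` in Rayl (kg/m^2/s)."""
        return self.density * self.sound_speed


#: Degassed water near 24 degC, the bath temperature of a typical benchtop
#: calibration (rho = 997 kg/m^3, c = 1494 m/s).
WATER_24C = MediumConstants(density=997.0, sound_speed=1494.0)

#: Water at 20 degC, for convenience.
WATER_20C = MediumConstants(density=998.0, sound_speed=1482.0)


@dataclass(frozen=True)
class PulseTrain:
    """Temporal scheme of a pulsed (or continuous-wave) sonication.

    Parameters
    ----------
    fundamental_frequency : float
        Carrier frequency FF in Hz.
    pulse_duration : float
        Pulse duration PD in seconds (active burst length).
    pulse_repetition_frequency : float
        PRF in Hz; one pulse is emitted at the start of each 1/PRF period.
    sonication_duration : float
        Total sonication time in seconds.
    amplitude : float
        Amplitude value; interpretation given by ``amplitude_kind``.
    amplitude_kind : str
        One of ``"isppa_w_cm2"``, ``"ispta_w_cm2"``, ``"pr_pa"``
        (peak-rarefactional pressure) or ``"pp_pa"`` (peak-to-peak).

    Notes
    -----
    Pulses must not overlap: ``PD * PRF <= 1``, with equality the
    continuous-wave (CW) limit.
    """

    fundamental_frequency: float
    pulse_duration: float
    pulse_repetition_frequency: float
    sonication_duration: float
    amplitude: float = 1.0
    amplitude_kind: str = "isppa_w_cm2"

    _AMPLITUDE_KINDS = ("isppa_w_cm2", "ispta_w_cm2", "pr_pa", "pp_pa")

    def __post_init__(self) -> None:
        for name in (
            "fundamental_frequency",
            "pulse_duration",
            "pulse_repetition_frequency",
            "sonication_duration",
            "amplitude",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.pulse_duration * self.pulse_repetition_frequency > 1.0 + 1e-12:
            raise InvalidParameterError(
                "pulse_duration * pulse_repetition_frequency > 1: pulses overlap"
            )
        if self.amplitude_kind not in self._AMPLITUDE_KINDS:
            raise InvalidParameterError(
                f"amplitude_kind must be one of {self._AMPLITUDE_KINDS}"
            )

    @property
    def duty_cycle(self) -> float:
        return duty_cycle(self)

    @property
    def is_continuous_wave(self) -> bool:
        return math.isclose(self.duty_cycle, 1.0, rel_tol=0, abs_tol=1e-12)

    def isppa_w_cm2(self, medium: MediumConstants = WATER_24C) -> float:
        """Resolve the amplitude specification to I_SPPA in W/cm^2."""
        kind, a = self.amplitude_kind, self.amplitude
        if kind == "isppa_w_cm2":
            return a
        if kind == "ispta_w_cm2":
            return isppa_for_ispta(a, self.duty_cycle)
        if kind == "pr_pa":
            return intensity_from_pressure(a, medium, convention="peak-rarefactional")
        return intensity_from_pressure(a, medium, convention="peak-to-peak")

    def ispta_w_cm2(self, medium: MediumConstants = WATER_24C) -> float:
        """Resolve the amplitude specification to I_SPTA in W/cm^2."""
        return ispta_from_isppa(self.isppa_w_cm2(medium), self.duty_cycle)


def duty_cycle(pt: PulseTrain) -> float:
    """Duty cycle DC = PD * PRF as a fraction in (0, 1].

    1.0 is the continuous-wave limit (e.g. PD = 1 s at PRF = 1 Hz).
    """
    dc = pt.pulse_duration * pt.pulse_repetition_frequency
    if dc > 1.0 + 1e-12:
        raise InvalidParameterError("PD * PRF > 1: pulses overlap")
    return min(dc, 1.0)


def isppa_for_ispta(ispta: float, dc: float) -> float:
    """Pulse-average intensity needed to hold a temporal-average intensity.

    ``I_SPPA = I_SPTA / DC``: e.g. holding I_SPTA at 0.5 W/cm^2 at a 10%
    duty cycle requires I_SPPA = 5 W/cm^2.
    """
    _check_dc(dc)
    if ispta <= 0:
        raise InvalidParameterError("ispta must be > 0")
    return ispta / dc


def ispta_from_isppa(isppa: float, dc: float) -> float:
    """Temporal-average intensity ``I_SPTA = I_SPPA * DC`` (inverse of
    :func:`isppa_for_ispta`)."""
    _check_dc(dc)
    if isppa <= 0:
        raise InvalidParameterError("isppa must be > 0")
    return isppa * dc


def _check_dc(dc: float) -> None:
    if not 0 < dc <= 1.0 + 1e-12:
        raise InvalidParameterError(f"duty cycle {dc} outside (0, 1]")


def pressure_from_intensity(
    intensity_w_cm2: float,
    medium: MediumConstants = WATER_24C,
    convention: PressureConvention = "peak-rarefactional",
) -> float:
    """Peak pressure (Pa) of a plane wave carrying a given I_SPPA (W/cm^2).

    Uses ``P_r = sqrt(2 rho c I)`` with I converted to W/m^2; the
    peak-to-peak convention returns ``2 * P_r`` (linear, symmetric
    waveform).  At I_SPPA = 5 W/cm^2 in 24 degC water this gives
    P_r ~= 386 kPa.
    """
    if intensity_w_cm2 <= 0:
        raise InvalidParameterError("intensity must be > 0")
    i_w_m2 = intensity_w_cm2 * 1e4
    pr = math.sqrt(2.0 * medium.impedance * i_w_m2)
    if convention == "peak-rarefactional":
        return pr
    if convention == "peak-to-peak":
        return 2.0 * pr
    raise InvalidParameterError(f"unknown pressure convention {convention!r}")


def intensity_from_pressure(
    pressure_pa: float,
    medium: MediumConstants = WATER_24C,
    convention: PressureConvention = "peak-rarefactional",
) -> float:
    """Exact inverse of :func:`pressure_from_intensity`; returns W/cm^2."""
    if pressure_pa <= 0:
        raise InvalidParameterError("pressure must be > 0")
    if convention == "peak-to-peak":
        pressure_pa = pressure_pa / 2.0
    elif convention != "peak-rarefactional":
        raise InvalidParameterError(f"unknown pressure convention {convention!r}")
    return pressure_pa**2 / (2.0 * medium.impedance) / 1e4


def pulse_envelope(pt: PulseTrain, t):
    """Binary on/off envelope of the pulse train at time(s) ``t`` (s).

    Returns 1 during the first PD of each PRF period and 0 otherwise.
    The time average over one full period equals the duty cycle.  ``t``
    may be a scalar or array; values outside [0, sonication_duration]
    raise.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > pt.sonication_duration):
        raise InvalidParameterError("t outside [0, sonication_duration]")
    phase = np.mod(t_arr * pt.pulse_repetition_frequency, 1.0)
    on = (phase < pt.pulse_duration * pt.pulse_repetition_frequency).astype(np.uint8)
    if np.isscalar(t) or t_arr.ndim == 0:
        return int(on)
    return on


def wavelength(frequency_hz: float, sound_speed_m_s: float) -> float:
    """Acoustic wavelength ``c / f`` in metres (7.5 mm at 200 kHz in water)."""
    if frequency_hz <= 0 or sound_speed_m_s <= 0:
        raise InvalidParameterError("frequency and sound speed must be > 0")
    return sound_speed_m_s / frequency_hz
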