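"""Pulsed-parameter algebra: duty cycles, intensity tables, pressure links."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tfus.config import pulse_train_from_config
from tfus.sonication import (
    InvalidParameterError,
    MediumConstants,
    PulseTrain,
    WATER_20C,
    WATER_24C,
    duty_cycle,
    intensity_from_pressure,
    isppa_for_ispta,
    ispta_from_isppa,
    pressure_from_intensity,
    pulse_envelope,
    wavelength,
)


def make_pt(pd, prf, **kw):
    kw.setdefault("fundamental_frequency", 200e3)
    kw.setdefault("sonication_duration", 600.0)
    return PulseTrain(pulse_duration=pd, pulse_repetition_frequency=prf, **kw)


class TestDutyCycle:
    @pytest.mark.parametrize(
        "pd, prf, expected",
        [(0.1, 1.0, 0.10), (0.1, 5.0, 0.50), (1.0, 1.0, 1.0), (0.25, 1.0, 0.25)],
    )
    def test_examples(self, pd, prf, expected):
        assert duty_cycle(make_pt(pd, prf)) == pytest.approx(expected)

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_pt(0.6, 2.0)

    def test_nonpositive_fields_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_pt(-0.1, 1.0)
        with pytest.raises(InvalidParameterError):
            make_pt(0.1, 1.0, sonication_duration=0.0)


class TestIntensityTables:
    # both benchtop parameter sweeps hold I_SPTA at 0.5 W/cm^2
    PD_SWEEP = [(0.10, 5.0), (0.25, 2.0), (0.50, 1.0), (0.75, 0.67), (1.00, 0.5)]
    DC_SWEEP = [(0.10, 5.0), (0.20, 2.5), (0.30, 1.67), (0.40, 1.25), (0.50, 1.0)]

    @pytest.mark.parametrize("dc, isppa", PD_SWEEP + DC_SWEEP)
    def test_reference_tables_reproduced(self, dc, isppa):
        assert round(isppa_for_ispta(0.5, dc), 2) == isppa

    def test_cw_identity(self):
        assert isppa_for_ispta(1.7, 1.0) == pytest.approx(1.7)

    def test_dc_out_of_range(self):
        for dc in (0.0, -0.2, 1.5):
            with pytest.raises(InvalidParameterError):
                isppa_for_ispta(0.5, dc)

    @given(
        isppa=st.floats(1e-3, 1e3),
        dc=st.floats(1e-3, 1.0, exclude_min=False),
    )
    def test_roundtrip(self, isppa, dc):
        assert ispta_from_isppa(isppa_for_ispta(isppa, dc), dc) == pytest.approx(
            isppa, rel=1e-12
        )


class TestPressureIntensity:
    def test_peak_rarefactional_at_5w_cm2(self, water):
        # 386 kPa at I_SPPA = 5 W/cm^2 in 24 degC water
        assert pressure_from_intensity(5.0, water) == pytest.approx(386e3, rel=0.01)

    def test_peak_to_peak_is_twice_pr(self, water):
        pr = pressure_from_intensity(3.0, water, "peak-rarefactional")
        pp = pressure_from_intensity(3.0, water, "peak-to-peak")
        assert pp == pytest.approx(2 * pr)

    def test_derived_peak_to_peak_magnitude(self):
        # 6.5 W/cm^2 corresponds to ~877 kPa peak-to-peak in cool water,
        # the magnitude of the largest simulated intracranial maxima
        pp = pressure_from_intensity(6.5, WATER_20C, "peak-to-peak")
        assert pp == pytest.approx(873.7e3, rel=0.02)

    @given(intensity=st.floats(1e-6, 1e4))
    def test_roundtrip_machine_precision(self, intensity):
        for conv in ("peak-rarefactional", "peak-to-peak"):
            p = pressure_from_intensity(intensity, WATER_24C, conv)
            assert intensity_from_pressure(p, WATER_24C, conv) == pytest.approx(
                intensity, rel=1e-12
            )

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            pressure_from_intensity(-1.0)
        with pytest.raises(InvalidParameterError):
            pressure_from_intensity(1.0, convention="rms")
        with pytest.raises(InvalidParameterError):
            MediumConstants(density=-1, sound_speed=1500)


class TestPulseEnvelope:
    def test_inside_and_between_pulses(self):
        pt = make_pt(0.1, 1.0)
        assert pulse_envelope(pt, 0.05) == 1
        assert pulse_envelope(pt, 0.5) == 0
        assert pulse_envelope(pt, 1.02) == 1  # second pulse

    def test_mean_equals_duty_cycle(self):
        pt = make_pt(0.1, 1.0, sonication_duration=10.0)
        t = np.arange(0, 10.0, 1e-3)
        mean = float(np.mean(pulse_envelope(pt, t)))
        # within one sample per pulse period at 1 kHz sampling
        assert mean == pytest.approx(0.10, abs=1e-3)

    def test_out_of_range(self):
        pt = make_pt(0.1, 1.0, sonication_duration=10.0)
        with pytest.raises(InvalidParameterError):
            pulse_envelope(pt, 11.0)


class TestWavelength:
    @pytest.mark.parametrize(
        "f, c, lam",
        [(200e3, 1500.0, 7.5e-3), (1e6, 1500.0, 1.5e-3), (200e3, 2800.0, 14e-3)],
    )
    def test_values(self, f, c, lam):
        assert wavelength(f, c) == pytest.approx(lam)


class TestAmplitudeResolution:
    def test_pulse_train_resolves_ispta(self, pulse_10pct, water):
        assert pulse_10pct.isppa_w_cm2(water) == pytest.approx(5.0)
        assert pulse_10pct.ispta_w_cm2(water) == pytest.approx(0.5)

    def test_pressure_spec_roundtrip(self, water):
        pr = pressure_from_intensity(5.0, water)
        pt = make_pt(0.1, 1.0, amplitude=pr, amplitude_kind="pr_pa")
        assert pt.isppa_w_cm2(water) == pytest.approx(5.0)

    def test_config_block_requires_one_amplitude(self):
        block = dict(ff_hz=200e3, pd_s=0.1, prf_hz=1.0, duration_s=1800.0)
        with pytest.raises(InvalidParameterError):
            pulse_train_from_config(block)
        pt = pulse_train_from_config({**block, "ispta_w_cm2": 0.5})
        assert pt.duty_cycle == pytest.approx(0.1)
        with pytest.raises(InvalidParameterError):
            pulse_train_from_config({**block, "ispta_w_cm2": 0.5, "pr_kpa": 386.0})
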