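"""Pennes bioheat solver against analytic oracles."""

import numpy as np
import pytest

from tfus.bioheat import (
    BLOOD,
    BRAIN_THERMAL,
    BioheatConfig,
    HeatSource,
    ThermalGrid,
    heat_source,
    solve_bioheat,
    steady_state_time,
)
from tfus.sonication import PulseTrain
from tfus.volume import Volume

WCB = BRAIN_THERMAL.perfusion_rate * BLOOD.specific_heat  # perfusion sink coefficient
TAU = BRAIN_THERMAL.density * BRAIN_THERMAL.specific_heat / WCB  # ~125 s


def uniform_source(shape, q0, dx):
    return Volume(np.full(shape, q0), (dx,) * 3)


class TestEquilibriumAndBounds:
    def test_zero_source_stays_at_baseline(self):
        grid = ThermalGrid.homogeneous((9, 9, 9), 0.5e-3)
        res = solve_bioheat(
            grid, uniform_source((9, 9, 9), 0.0, 0.5e-3), BioheatConfig(duration=30.0)
        )
        assert res.peak_delta_t == 0.0
        assert np.all(res.final.data == 37.5)

    def test_maximum_principle(self):
        grid = ThermalGrid.homogeneous((11, 11, 11), 0.5e-3)
        q = np.zeros((11, 11, 11))
        q[5, 5, 5] = 5e4
        res = solve_bioheat(grid, Volume(q, (0.5e-3,) * 3), BioheatConfig(duration=60.0))
        assert float(res.final.data.min()) >= 37.5 - 1e-12

    def test_stability_guard(self):
        grid = ThermalGrid.homogeneous((9, 9, 9), 0.5e-3)
        cfg = BioheatConfig(duration=1.0, time_step=10 * grid.max_stable_dt())
        with pytest.raises(RuntimeError):
            solve_bioheat(grid, uniform_source((9, 9, 9), 1.0, 0.5e-3), cfg)


@pytest.fixture(scope="module")
def lumped():
    grid = ThermalGrid.homogeneous((5, 5, 5), 0.5e-3)
    grid.conductivity[:] = 0.0
    q0 = 1000.0
    res = solve_bioheat(
        grid,
        uniform_source((5, 5, 5), q0, 0.5e-3),
        BioheatConfig(duration=900.0, time_step=0.05, boundary="insulated"),
    )
    return res, q0


class TestLumpedPerfusionOracle:
    """With conduction off, every voxel follows the perfusion ODE
    rho c dT/dt = q - w_b c_b dT: exponential approach to q/(w_b c_b)
    with time constant tau = rho c / (w_b c_b)."""

    def test_steady_state_value(self, lumped):
        res, q0 = lumped
        assert res.peak_delta_t == pytest.approx(q0 / WCB, rel=2e-3)

    def test_t95_is_three_time_constants(self, lumped):
        res, _ = lumped
        t95 = steady_state_time(res.times, res.probe_series["center"])
        assert t95 == pytest.approx(2.996 * TAU, rel=0.02)

    def test_exponential_time_course(self, lumped):
        res, q0 = lumped
        t = res.times
        dT = res.probe_series["center"] - res.baseline
        analytic = q0 / WCB * (1 - np.exp(-t / TAU))
        assert np.max(np.abs(dT - analytic)) < 5e-4 * q0 / WCB + 1e-9


class TestConductionOracle:
    def test_gaussian_source_transient_closed_form(self):
        """No perfusion: the center temperature under an isotropic
        Gaussian source follows q0 sigma^2 / k * (1 - (1+2 kappa t/sigma^2)^-1/2),
        approaching the Green's-function steady state q0 sigma^2 / k."""
        dx, n, sigma, q0 = 0.5e-3, 61, 2.1e-3, 3000.0
        grid = ThermalGrid.homogeneous((n,) * 3, dx)
        grid.perfusion_rate[:] = 0.0
        c = (n - 1) / 2 * dx
        xs = np.arange(n) * dx - c
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        q = q0 * np.exp(-(X**2 + Y**2 + Z**2) / (2 * sigma**2))
        t_end = 120.0
        res = solve_bioheat(
            grid, Volume(q, (dx,) * 3), BioheatConfig(duration=t_end, time_step=0.1),
            probes={"c": (n // 2,) * 3},
        )
        kappa = BRAIN_THERMAL.conductivity / (
            BRAIN_THERMAL.density * BRAIN_THERMAL.specific_heat
        )
        analytic = (
            q0 * sigma**2 / BRAIN_THERMAL.conductivity
            * (1 - (1 + 2 * kappa * t_end / sigma**2) ** -0.5)
        )
        sim = res.probe_series["c"][-1] - res.baseline
        assert sim == pytest.approx(analytic, rel=0.03)


class TestHeatSource:
    def test_duty_averaged_value(self, pulse_10pct):
        # alpha = 0.25 Np/m, I_SPPA = 6.5 W/cm^2, DC = 10%:
        # q = 2 * 0.25 * 6.5e4 W/m^2 * 0.1 = 3250 W/m^3
        vol = Volume(np.full((3, 3, 3), 6.5), (0.5e-3,) * 3)
        src = heat_source(vol, 0.25, pulse_10pct, mode="duty-averaged")
        assert np.allclose(src.q.data, 3250.0)
        assert src.envelope is None

    def test_period_integrals_agree_between_modes(self, pulse_10pct):
        vol = Volume(np.full((2, 2, 2), 5.0), (0.5e-3,) * 3)
        avg = heat_source(vol, 0.25, pulse_10pct, mode="duty-averaged")
        res = heat_source(vol, 0.25, pulse_10pct, mode="pulse-resolved")
        period = 1.0 / pulse_10pct.pulse_repetition_frequency
        t = np.arange(0, period, 1e-4)
        env_integral = np.mean([res.envelope(ti) for ti in t]) * period
        assert res.q.data[0, 0, 0] * env_integral == pytest.approx(
            avg.q.data[0, 0, 0] * period, rel=2e-3
        )

    def test_negative_absorption_rejected(self, pulse_10pct):
        vol = Volume(np.ones((2, 2, 2)), (0.5e-3,) * 3)
        with pytest.raises(ValueError):
            heat_source(vol, -0.1, pulse_10pct)


class TestLinearity:
    def test_temperature_scales_with_source(self):
        dx, n = 1e-3, 21
        grid = ThermalGrid.homogeneous((n,) * 3, dx)
        q = np.zeros((n,) * 3)
        q[10, 10, 10] = 1e4
        cfg = BioheatConfig(duration=60.0, time_step=0.2)
        r1 = solve_bioheat(grid, Volume(q, (dx,) * 3), cfg)
        r2 = solve_bioheat(grid, Volume(3 * q, (dx,) * 3), cfg)
        assert r2.peak_delta_t == pytest.approx(3 * r1.peak_delta_t, rel=1e-9)


class TestSteadyStateTime:
    def test_step_series_first_sample(self):
        t = np.arange(10.0)
        y = np.concatenate([[0.0], np.full(9, 2.0)])
        assert steady_state_time(t, y, baseline=0.0) == 1.0

    def test_nonconverged_series_flagged(self):
        t = np.arange(100.0)
        y = t.copy()  # still rising linearly
        with pytest.warns(RuntimeWarning):
            steady_state_time(t, y, baseline=0.0)

    def test_zero_elevation(self):
        assert steady_state_time(np.arange(5.0), np.zeros(5)) == 0.0
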