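"""Electrical analysis: impedance formulas, spectrum summaries,
frequency response and electrode calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import lfilter

from crystalgate.electrochem import (CalciumCalibration, CapacitanceSpectrum,
                                     HarmonicStimulus, ImpedanceSpectrum,
                                     calibrate_calcium, capacitance_summary,
                                     capacitor_impedance,
                                     concentration_from_pca,
                                     frequency_response, harmonic_frequencies,
                                     pca_from_concentration,
                                     potential_from_concentration,
                                     response_distribution, sine_stimulus,
                                     specific_capacitance, spectrum_summary)
from crystalgate.signals import TimeSeries


class TestCapacitorImpedance:
    def test_unit_case(self):
        z = capacitor_impedance(1.0, 1.0 / (2 * np.pi))
        assert abs(z) == pytest.approx(1.0)
        assert np.angle(z, deg=True) == pytest.approx(-90.0)

    def test_magnitude_decreases_with_frequency(self):
        f = np.logspace(0, 6, 50)
        mags = [abs(capacitor_impedance(1e-6, fi)) for fi in f]
        assert np.all(np.diff(mags) < 0)

    def test_arithmetic(self):
        z = capacitor_impedance(40.389e-6, 1.0)
        assert abs(z) == pytest.approx(3940.6, rel=1e-4)

    @given(st.floats(1e-12, 1e3), st.floats(1e-3, 1e9))
    @settings(max_examples=100, deadline=None)
    def test_reciprocal_identity(self, c, f):
        z = capacitor_impedance(c, f)
        assert abs(z) * (2 * np.pi * f * c) == pytest.approx(1.0, rel=1e-12)
        assert np.angle(z, deg=True) == pytest.approx(-90.0, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            capacitor_impedance(1e-6, 0.0)
        with pytest.raises(ValueError):
            capacitor_impedance(0.0, 1.0)


class TestSpecificCapacitance:
    def test_disk_geometry(self):
        out = specific_capacitance(40.389e-6, diameter_cm=7.0,
                                   thickness_cm=0.42)
        assert out["area_cm2"] == pytest.approx(38.5, abs=0.05)
        assert out["volume_cm3"] == pytest.approx(16.16, abs=0.02)
        assert out["area_cm2"] * 0.42 == pytest.approx(out["volume_cm3"])

    def test_per_area_division(self):
        out = specific_capacitance(40.389e-6, 7.0, 0.42)
        assert out["per_area_f_cm2"] == pytest.approx(1.0496e-6, rel=1e-3)

    def test_flag_fires_on_tenfold_expectation(self):
        # A tenfold-larger expected per-area value must trip the
        # consistency flag.
        out = specific_capacitance(40.389e-6, 7.0, 0.42,
                                   expected_per_area=10.5e-6)
        assert out["consistent"] is False

    def test_flag_quiet_when_consistent(self):
        out = specific_capacitance(40.389e-6, 7.0, 0.42,
                                   expected_per_area=1.05e-6)
        assert out["consistent"] is True

    def test_domain_error(self):
        with pytest.raises(ValueError):
            specific_capacitance(1e-6, -1.0, 0.42)


class TestSpectrumSummaries:
    def test_single_point(self):
        s = ImpedanceSpectrum([10.0], [5.0], [-30.0])
        out = spectrum_summary(s)
        assert out["mean_z_ohm"] == 5.0
        assert out["mean_phase_deg"] == -30.0

    def test_two_point_mean(self):
        s = ImpedanceSpectrum([1.0, 2.0], [1.0, 3.0], [0.0, 0.0])
        assert spectrum_summary(s)["mean_z_ohm"] == 2.0

    def test_constant_capacitance(self):
        f = np.logspace(0, 6, 61)
        s = CapacitanceSpectrum(f, np.full(61, 3.3e-6))
        assert capacitance_summary(s) == pytest.approx(3.3e-6)

    def test_plateau_uses_lowest_decade(self):
        f = np.logspace(0, 6, 61)
        cap = np.where(f <= 10.0, 2.0e-6, 99.0)
        s = CapacitanceSpectrum(f, cap)
        assert capacitance_summary(s) == pytest.approx(2.0e-6)


class TestHarmonics:
    def test_frequencies(self):
        assert harmonic_frequencies(0.5, [1, 2]) == [0.5, 1.0]
        assert harmonic_frequencies(1 / 60, [16])[0] == pytest.approx(
            0.26667, abs=1e-5)

    def test_invalid_harmonic(self):
        with pytest.raises(ValueError):
            harmonic_frequencies(1.0, [0])

    def test_sine_values(self):
        stim = HarmonicStimulus(amplitude=2.0, fundamental_f=0.1, harmonic=5)
        quarter = 1.0 / (4 * stim.frequency)
        s = sine_stimulus(stim, [0.0, quarter])
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)
        assert s.values[1] == pytest.approx(2.0)

    def test_sine_rms(self):
        stim = HarmonicStimulus(amplitude=1.5, fundamental_f=1.0, harmonic=2)
        t = np.arange(0, 10, 0.001)      # whole periods of 2 Hz
        s = sine_stimulus(stim, t)
        rms = np.sqrt(np.mean(s.values ** 2))
        assert rms == pytest.approx(1.5 / np.sqrt(2), rel=1e-3)


class TestFrequencyResponse:
    def _broadband(self, n=4096, dt=0.01, seed=7):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * dt
        return TimeSeries(t, rng.standard_normal(n))

    def test_identity_system(self):
        vin = self._broadband()
        fr = frequency_response(vin, vin)
        assert np.allclose(fr.gain, 1.0, atol=1e-9)
        assert np.allclose(fr.phase, 0.0, atol=1e-9)

    def test_pure_gain(self):
        vin = self._broadband()
        vout = TimeSeries(vin.timestamps, 2.0 * vin.values)
        fr = frequency_response(vin, vout)
        assert np.allclose(fr.gain, 2.0, atol=1e-9)

    def test_single_pole_lowpass_cutoff(self):
        # Discrete single-pole IIR y[k] = a·y[k−1] + (1−a)·x[k] with
        # analytic −3 dB cutoff f_c; steady-state sine at f_c (bin
        # aligned, transient discarded) must come back with gain 1/√2.
        dt, fc, n = 0.001, 20.0, 10_000    # f_c on bin 200 of 0.1 Hz grid
        a = np.exp(-2 * np.pi * fc * dt)
        t_full = np.arange(3 * n) * dt
        x = np.sin(2 * np.pi * fc * t_full)
        y = lfilter([1 - a], [1, -a], x)
        t = np.arange(n) * dt
        fr = frequency_response(TimeSeries(t, x[-n:]),
                                TimeSeries(t, y[-n:]))
        # analytic gain of the discrete filter at frequency f
        def g(f):
            w = 2 * np.pi * f * dt
            return (1 - a) / abs(1 - a * np.exp(-1j * w))
        k = np.abs(fr.frequencies - fc).argmin()
        assert fr.frequencies[k] == pytest.approx(fc)
        assert fr.gain[k] == pytest.approx(g(fc), rel=1e-6)
        assert fr.gain[k] == pytest.approx(0.7071, abs=0.01)

    def test_grid_mismatch_rejected(self):
        vin = self._broadband(n=64)
        vout = TimeSeries(vin.timestamps + 0.5, vin.values)
        with pytest.raises(ValueError):
            frequency_response(vin, vout)

    def test_zero_input_rejected(self):
        t = np.arange(64) * 0.1
        with pytest.raises(ValueError):
            frequency_response(TimeSeries(t, np.zeros(64)),
                               TimeSeries(t, np.ones(64)))


class TestResponseDistribution:
    def test_constant(self):
        t = np.arange(10, dtype=float)
        ds = response_distribution(TimeSeries(t, np.full(10, 0.7)))
        assert ds.min == ds.q1 == ds.median == ds.q3 == ds.max == 0.7

    def test_uniform_median(self, rng):
        n = 20_000
        v = rng.uniform(-1, 1, n)
        ds = response_distribution(TimeSeries(np.arange(n, dtype=float), v))
        se = 1.0 / np.sqrt(n) * np.sqrt(np.pi / 2) * (2 / np.sqrt(12))
        assert abs(ds.median) < 3 * se + 1e-3

    def test_sinusoid_quartiles_arcsine(self):
        # quantiles of A·sin(U): q1/q3 = ∓A·sin(π/4) = ∓A/√2
        a = 0.8
        t = np.arange(0, 1000, 0.01)
        v = a * np.sin(2 * np.pi * 0.05 * t)
        ds = response_distribution(TimeSeries(t, v))
        assert ds.q1 == pytest.approx(-a / np.sqrt(2), abs=0.01)
        assert ds.q3 == pytest.approx(a / np.sqrt(2), abs=0.01)

    @given(st.floats(0.1, 5.0), st.floats(-2.0, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_equivariance(self, a, b):
        v = np.random.default_rng(42).standard_normal(200)
        t = np.arange(200, dtype=float)
        d0 = response_distribution(TimeSeries(t, v))
        d1 = response_distribution(TimeSeries(t, a * v + b))
        for attr in ("median", "q1", "q3", "min", "max"):
            assert getattr(d1, attr) == pytest.approx(
                a * getattr(d0, attr) + b, rel=1e-9, abs=1e-9)


class TestCalciumCalibration:
    def test_intercept_is_unit_concentration(self):
        calib = CalciumCalibration(intercept=12.0, valid_range=(1e-6, 10.0))
        assert calibrate_calcium(12.0, calib) == pytest.approx(1.0)

    def test_decade_law(self):
        calib = CalciumCalibration(valid_range=(1e-9, 10.0))
        c0 = calibrate_calcium(0.0, calib)
        c1 = calibrate_calcium(calib.slope, calib)
        assert c1 / c0 == pytest.approx(10.0)

    def test_round_trip(self):
        calib = CalciumCalibration(valid_range=(1e-4, 1e-1))
        for c in (3e-3, 3.53e-3, 4.75e-3):
            v = potential_from_concentration(c, calib)
            assert calibrate_calcium(v, calib) == pytest.approx(
                c, rel=1e-12)

    def test_out_of_range_warns(self):
        calib = CalciumCalibration()
        with pytest.warns(UserWarning):
            calibrate_calcium(500.0, calib)

    @pytest.mark.parametrize("c,expected", [
        (1.0, 0.0), (1e-3, 3.0), (3.53e-3, 2.452),
    ])
    def test_pca_convention(self, c, expected):
        assert pca_from_concentration(c) == pytest.approx(expected, abs=5e-4)
        assert concentration_from_pca(
            pca_from_concentration(c)) == pytest.approx(c, rel=1e-12)
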