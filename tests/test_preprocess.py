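"""FIR design, zero-phase band filtering, decimation, epoching, optics."""
import numpy as np
import pytest
from scipy.signal import freqz

from isocouple.preprocess import (Epoch, FilterSpec, OpticalCalibration,
                                  decimate_to, design_fir,
                                  extract_state_epochs, filter_band,
                                  mbll_concentrations)

FS = 10.0


def _gain(taps, f, fs=FS):
    _, h = freqz(taps, worN=[2 * np.pi * f / fs], fs=2 * np.pi)
    return abs(h[0])


class TestDesignFir:
    def test_magnitude_response(self):
        taps = design_fir(FilterSpec())
        assert len(taps) == 3001
        assert 0.9 <= _gain(taps, 0.03) <= 1.1          # passband centre
        assert _gain(taps, 0.0) < 0.01                  # DC, <= -40 dB
        assert _gain(taps, 0.5) < 0.01
        assert _gain(taps, 1.0) < 0.01

    def test_linear_phase_symmetry(self):
        taps = design_fir(FilterSpec())
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-15)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="even"):
            FilterSpec(order=3001)
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec(band=(0.01, 6.0))


class TestFilterBand:
    def test_passband_tone_zero_phase(self):
        t = np.arange(2400) / FS
        tone = np.cos(2 * np.pi * 0.03 * t)
        y = filter_band(tone)
        assert y.shape == tone.shape
        # cross-correlation peak at zero lag: no phase shift
        lags = np.arange(-50, 51)
        xc = [np.dot(y[200:-200], np.roll(tone, k)[200:-200]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_stopband_tone_suppressed(self):
        t = np.arange(2400) / FS
        tone = np.cos(2 * np.pi * 1.0 * t)
        assert np.std(filter_band(tone)) < 0.01 * np.std(tone)

    def test_dc_rejected(self):
        y = filter_band(np.full(2000, 3.7))
        assert np.max(np.abs(y)) < 0.05

    def test_linearity(self, rng):
        x1 = rng.standard_normal(1500)
        x2 = rng.standard_normal(1500)
        lhs = filter_band(2.0 * x1 - 0.5 * x2)
        rhs = 2.0 * filter_band(x1) - 0.5 * filter_band(x2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            filter_band(np.array([1.0]))


class TestDecimate:
    def test_identity_when_rates_match(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(decimate_to(x, 10, 10), x)

    def test_output_length_floor(self, rng):
        x = rng.standard_normal(1013)
        assert decimate_to(x, 250, 10).shape[-1] == 1013 // 25

    def test_slow_tone_survives_heavy_decimation(self):
        fs_in = 1000.0
        t = np.arange(int(200 * fs_in)) / fs_in
        tone = np.cos(2 * np.pi * 0.05 * t)
        y = decimate_to(tone, fs_in, 10.0)
        freqs = np.fft.rfftfreq(y.size, 1 / 10.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y)))]
        assert peak == pytest.approx(0.05, abs=freqs[1])

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            decimate_to(np.zeros(100), 25, 10)


class TestEpochs:
    def test_hand_enumerated_runs(self, rng):
        hyp = ["AWAKE"] * 4 + ["N2"] * 5 + ["AWAKE"] * 4
        sig = rng.standard_normal(int(len(hyp) * 30 * FS))
        eps = extract_state_epochs(hyp, sig, FS, epoch_len_s=120.0)
        assert [(e.state, e.onset_s) for e in eps] == [("AWAKE", 0.0), ("N2", 120.0)]
        n_ep = int(120 * FS)
        np.testing.assert_array_equal(eps[1].signals, sig[1200:1200 + n_ep])

    def test_short_runs_yield_nothing(self, rng):
        hyp = ["N1"] * 3  # 90 s < 120 s
        sig = rng.standard_normal(int(len(hyp) * 30 * FS))
        assert extract_state_epochs(hyp, sig, FS) == []

    def test_tie_broken_to_earliest_run(self, rng):
        hyp = ["AWAKE"] * 4 + ["N2"] * 4 + ["AWAKE"] * 4
        sig = rng.standard_normal(int(len(hyp) * 30 * FS))
        eps = extract_state_epochs(hyp, sig, FS)
        awake = [e for e in eps if e.state == "AWAKE"]
        assert len(awake) == 1 and awake[0].onset_s == 0.0

    def test_multiple_epochs_per_state(self, rng):
        hyp = ["N2"] * 10  # 300 s run
        sig = rng.standard_normal(int(len(hyp) * 30 * FS))
        eps = extract_state_epochs(hyp, sig, FS, n_per_state=3)
        assert [e.onset_s for e in eps] == [0.0, 120.0]  # only 2 fit in 300 s

    def test_epochs_exclude_everything_else(self, rng):
        hyp = ["AWAKE"] * 5
        sig = rng.standard_normal(int(len(hyp) * 30 * FS))
        eps = extract_state_epochs(hyp, {"a": sig, "b": 2 * sig}, FS)
        assert len(eps) == 1
        assert eps[0].signals["a"].shape[-1] == int(120 * FS)

    def test_misaligned_hypnogram_rejected(self, rng):
        sig = rng.standard_normal(5000)
        with pytest.raises(ValueError, match="misaligned"):
            extract_state_epochs(["AWAKE"] * 2, sig, FS)


class TestMbll:
    def test_zero_absorbance_zero_concentration(self):
        cal = OpticalCalibration()
        dC = mbll_concentrations(np.zeros((3, 50)), cal)
        np.testing.assert_array_equal(dC, np.zeros((3, 50)))

    def test_identity_calibration_is_identity(self):
        cal = OpticalCalibration(extinction=np.eye(3), pathlength=1.0)
        dA = np.array([[1.0], [0.0], [0.0]])
        np.testing.assert_allclose(mbll_concentrations(dA, cal), dA)

    def test_forward_inverse_round_trip(self, rng):
        E = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        cal = OpticalCalibration(extinction=E, pathlength=2.5, dpf=(1.1, 1.2, 1.3))
        dA = rng.standard_normal((3, 200))
        dC = mbll_concentrations(dA, cal)
        L = np.diag(cal.pathlength * np.asarray(cal.dpf))
        np.testing.assert_allclose(E @ L @ dC, dA, atol=1e-10)

    def test_singular_extinction_rejected(self):
        cal = OpticalCalibration.__new__(OpticalCalibration)
        cal.extinction = np.ones((3, 3))
        cal.pathlength = 3.0
        cal.dpf = (1.0, 1.0, 1.0)
        with pytest.raises(np.linalg.LinAlgError):
            mbll_concentrations(np.zeros((3, 5)), cal)
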