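"""Phase extraction, discrete TE, aggregation, and the lag-map control."""
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isocouple.coupling import (aggregate_te, analytic_phase, default_lag,
                                discretize_phase, pairwise_te_map, phase_te,
                                plugin_entropy, xcorr_lag_map)
from isocouple.synthgen import make_spatial

FS = 10.0


def brute_force_te(x, y, lag):
    """Independent oracle: explicit count tables over observed tuples."""
    def H(*cols):
        counts = Counter(zip(*cols))
        n = sum(counts.values())
        return -sum(c / n * math.log2(c / n) for c in counts.values())

    x, y = list(x), list(y)
    y_t = y[lag:]
    y_p = y[:-lag]
    x_p = x[:-lag]
    x_t = x[lag:]
    te_xy = H(y_t, y_p) + H(y_p, x_p) - H(y_p) - H(y_t, y_p, x_p)
    te_yx = H(x_t, x_p) + H(x_p, y_p) - H(x_p) - H(x_t, x_p, y_p)
    return max(te_xy, 0.0), max(te_yx, 0.0)


class TestAnalyticPhase:
    def test_cosine_phase_advances_linearly(self):
        t = np.arange(2400) / FS
        p = analytic_phase(np.cos(2 * np.pi * 0.03 * t), FS)
        unwrapped = np.unwrap(p.theta)
        mid = slice(240, 2160)  # middle 80 %
        slope = np.polyfit(np.arange(2400)[mid], unwrapped[mid], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.03 / FS, rel=0.01)

    def test_sine_lags_cosine_by_half_pi(self):
        t = np.arange(2400) / FS
        pc = analytic_phase(np.cos(2 * np.pi * 0.03 * t), FS).theta
        ps = analytic_phase(np.sin(2 * np.pi * 0.03 * t), FS).theta
        diff = np.angle(np.exp(1j * (pc - ps)))
        assert np.median(diff[200:-200]) == pytest.approx(np.pi / 2, abs=0.02)

    def test_amplitude_invariance(self, rng):
        from isocouple.preprocess import filter_band
        x = filter_band(rng.standard_normal(2000))
        np.testing.assert_allclose(analytic_phase(x, FS).theta,
                                   analytic_phase(5.0 * x, FS).theta, atol=1e-9)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            analytic_phase(np.zeros(100), FS)

    def test_phases_wrapped_to_half_open_interval(self, rng):
        from isocouple.preprocess import filter_band
        th = analytic_phase(filter_band(rng.standard_normal(3000)), FS).theta
        assert np.all(th >= -np.pi) and np.all(th < np.pi)


class TestDiscretize:
    def test_edge_conventions(self):
        from isocouple.coupling import PhaseSeries
        eps = 1e-9
        p = PhaseSeries(theta=np.array([-np.pi, np.pi - eps]), fs=FS)
        s = discretize_phase(p, 8)
        assert list(s.symbols) == [0, 7]

    def test_two_bins_encode_phase_sign(self):
        from isocouple.coupling import PhaseSeries
        p = PhaseSeries(theta=np.array([-1.0, 1.0, -3.0, 3.0]), fs=FS)
        assert list(discretize_phase(p, 2).symbols) == [0, 1, 0, 1]

    def test_uniform_phases_occupy_bins_evenly(self, rng):
        from isocouple.coupling import PhaseSeries
        theta = rng.uniform(-np.pi, np.pi, 8000)
        s = discretize_phase(PhaseSeries(theta=theta, fs=FS), 8)
        freqs = np.bincount(s.symbols, minlength=8) / 8000
        np.testing.assert_allclose(freqs, 0.125, atol=0.02)


class TestPluginEntropy:
    def test_uniform_eight_symbols_three_bits(self):
        assert plugin_entropy(np.tile(np.arange(8), 100)) == pytest.approx(3.0)

    def test_constant_series_zero_bits(self):
        assert plugin_entropy(np.zeros(500, dtype=int)) == 0.0

    def test_duplicated_series_adds_nothing(self, rng):
        x = rng.integers(0, 5, 400)
        assert plugin_entropy(x, x) == pytest.approx(plugin_entropy(x))


class TestPhaseTe:
    def test_constant_source_or_target_gives_exact_zero(self, rng):
        x = rng.integers(0, 8, 600)
        const = np.full(600, 3)
        assert phase_te(const, x, lag=10, n_bins=8).te_xy == 0.0
        assert phase_te(x, const, lag=10, n_bins=8).te_xy == 0.0

    def test_copy_process_transfers_one_bit(self):
        rng = np.random.default_rng(42)
        d = 7
        x = rng.integers(0, 2, 2048)
        y = np.empty_like(x)
        y[d:] = x[:-d]
        y[:d] = rng.integers(0, 2, d)
        te = phase_te(x, y, lag=d, n_bins=2)
        assert te.te_xy == pytest.approx(1.0, abs=0.05)
        assert te.te_yx == pytest.approx(0.0, abs=0.05)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            lag = int(rng.integers(1, n - 1))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            te = phase_te(x, y, lag=lag, n_bins=2)
            bf_xy, bf_yx = brute_force_te(x, y, lag)
            assert te.te_xy == pytest.approx(bf_xy, abs=1e-12)
            assert te.te_yx == pytest.approx(bf_yx, abs=1e-12)

    def test_invalid_lags_rejected(self, rng):
        x = rng.integers(0, 8, 50)
        with pytest.raises(ValueError):
            phase_te(x, x, lag=0)
        with pytest.raises(ValueError):
            phase_te(x, x, lag=50)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 7), min_size=6, max_size=40),
           st.lists(st.integers(0, 7), min_size=6, max_size=40),
           st.integers(1, 4))
    def test_antisymmetry_and_nonnegativity(self, xs, ys, lag):
        n = min(len(xs), len(ys))
        if lag >= n:
            lag = n - 1
        x = np.asarray(xs[:n])
        y = np.asarray(ys[:n])
        fwd = phase_te(x, y, lag=lag, n_bins=8)
        rev = phase_te(y, x, lag=lag, n_bins=8)
        assert fwd.te_xy >= 0 and fwd.te_yx >= 0
        assert fwd.delta_te == pytest.approx(-rev.delta_te, abs=1e-12)
        assert fwd.te_xy == pytest.approx(rev.te_yx, abs=1e-12)


class TestDefaultLag:
    @pytest.mark.parametrize("f_center,fs,expect",
                             [(0.03, 10.0, 333), (0.05, 10.0, 200), (0.1, 10.0, 100)])
    def test_one_cycle_in_samples(self, f_center, fs, expect):
        assert default_lag(f_center, fs) == expect

    def test_invalid_centre_frequency(self):
        with pytest.raises(ValueError):
            default_lag(6.0, 10.0)


class TestTeMapAggregation:
    def test_single_voxel_single_electrode_reduces_to_phase_te(self, rng):
        from isocouple.preprocess import filter_band
        T = 1200
        sig = filter_band(rng.standard_normal((3, 2 * T)))[:, 600:600 + T]
        bold = sig[0].reshape(1, 1, 1, T)
        mask = np.ones((1, 1, 1), dtype=bool)
        tm = pairwise_te_map(bold, mask, sig[1][None, :], sig[2], fs=FS, lag=333)
        sb = discretize_phase(analytic_phase(sig[0], FS), 8)
        se = discretize_phase(analytic_phase(sig[1], FS), 8)
        expected = phase_te(sb, se, lag=333)
        assert tm.delta["bold_eeg"][0, 0, 0] == pytest.approx(expected.delta_te, abs=1e-12)

    def test_aggregation_partition_identity(self, quiet_config, rng):
        sp = make_spatial(quiet_config)
        V = int(sp.mask.sum())
        tm_delta = rng.standard_normal(V)
        from isocouple.coupling import TEMap

        def vol(v):
            out = np.full(sp.mask.shape, np.nan)
            out[sp.mask] = v
            return out

        te_xy = rng.uniform(0, 1, V)
        te_yx = te_xy - tm_delta
        elec = rng.standard_normal(4)
        tm = TEMap(delta={"bold_eeg": vol(tm_delta), "bold_h2o": vol(tm_delta),
                          "eeg_h2o": elec},
                   te_xy={"bold_eeg": vol(te_xy), "bold_h2o": vol(te_xy),
                          "eeg_h2o": elec},
                   te_yx={"bold_eeg": vol(te_yx), "bold_h2o": vol(te_yx),
                          "eeg_h2o": np.zeros(4)},
                   mask=sp.mask, lag_samples=333, n_bins=8)
        df = aggregate_te(tm, sp.atlas)
        wb = df[(df.pair == "bold_eeg") & (df.region == "whole_brain")].iloc[0]
        rois = df[(df.pair == "bold_eeg") & (df.region != "whole_brain")
                  & (df.region != "electrodes")]
        # whole-brain mean equals the voxel-weighted mean of region means
        weighted = (rois.delta_te * rois.n_voxels).sum() / rois.n_voxels.sum()
        assert wb.delta_te == pytest.approx(weighted, rel=1e-12)
        # aggregation commutes with the Delta-TE subtraction
        assert wb.delta_te == pytest.approx(wb.te_xy - wb.te_yx, abs=1e-12)

    def test_constant_map_has_constant_roi_means(self, quiet_config):
        sp = make_spatial(quiet_config)
        from isocouple.coupling import TEMap
        c = 0.42
        vol = np.where(sp.mask, c, np.nan)
        tm = TEMap(delta={"bold_eeg": vol, "bold_h2o": vol, "eeg_h2o": np.full(4, c)},
                   te_xy={"bold_eeg": vol, "bold_h2o": vol, "eeg_h2o": np.full(4, c)},
                   te_yx={"bold_eeg": vol * 0, "bold_h2o": vol * 0, "eeg_h2o": np.zeros(4)},
                   mask=sp.mask, lag_samples=333, n_bins=8)
        df = aggregate_te(tm, sp.atlas)
        np.testing.assert_allclose(df[df.pair == "bold_eeg"].delta_te, c)


class TestLagMap:
    def _bold_with_shift(self, rng, shift):
        # broadband source: its sharp autocorrelation makes the single-sample
        # shift identifiable (a pure infraslow tone's xcorr peak is flat)
        T = 900
        src = rng.standard_normal(3 * T)
        seed_sig = src[600:600 + T]
        mask = np.ones((2, 1, 1), dtype=bool)
        seed_mask = np.zeros((2, 1, 1), dtype=bool)
        seed_mask[0] = True
        bold = np.empty((2, 1, 1, T))
        bold[0, 0, 0] = seed_sig
        bold[1, 0, 0] = src[600 - shift:600 - shift + T]   # follows seed by `shift`
        return bold, mask, seed_mask

    def test_constructed_shift_recovered(self, rng):
        bold, mask, seed_mask = self._bold_with_shift(rng, 5)
        res = xcorr_lag_map(bold, mask, seed_mask, fs=FS)
        assert res.lag_map[0, 0, 0] == pytest.approx(0.0)
        assert res.lag_map[1, 0, 0] == pytest.approx(0.5)

    def test_flat_seed_rejected(self):
        bold = np.zeros((2, 1, 1, 500))
        mask = np.ones((2, 1, 1), dtype=bool)
        with pytest.raises(ValueError, match="flat"):
            xcorr_lag_map(bold, mask, mask, fs=FS)

    def test_independent_noise_lag_uncorrelated_with_te(self):
        """On uncoupled data the lag map carries no information about ΔTE."""
        from isocouple.preprocess import filter_band
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            T = 600
            V = 30
            raw = rng.standard_normal((V, 2 * T))
            bold = filter_band(raw)[:, 600:600 + T].reshape(V, 1, 1, T)
            mask = np.ones((V, 1, 1), dtype=bool)
            seed_mask = np.zeros((V, 1, 1), dtype=bool)
            seed_mask[:3] = True
            te_map = rng.standard_normal((V, 1, 1))
            res = xcorr_lag_map(bold, mask, seed_mask, fs=FS, te_map=te_map,
                                n_perm=200, rng=rng)
            hits += res.p_perm > 0.05
        assert hits >= 9
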