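import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_sen
from eegsen import (
    DEFAULT_BANDS,
    BandDefinition,
    SpectralWindow,
    entropy_series,
    power_spectrum,
    spectral_entropy,
    split_bands,
    window_signal,
)
from eegsen.trend import fit_trend, moving_average

RATE = 256.0
FULL = BandDefinition("full", 0.0, 128.0)


def make_window(power, rate=RATE):
    """A SpectralWindow with a directly prescribed binned spectrum."""
    n = len(power)
    w = SpectralWindow(start_s_rel_onset=0.0, length_samples=2 * n, slice_start=0)
    w.power = np.asarray(power, dtype=float)
    w.bin_freqs_hz = (np.arange(n) + 0.5) * (rate / 2) / n
    return w


class TestWindowing:
    @pytest.mark.parametrize(
        "minutes,expected", [(28, 105), (32, 120)]
    )
    def test_non_overlapping_window_count(self, minutes, expected):
        n = minutes * 60 * 256
        wins = window_signal(np.zeros(n), RATE, 4096, start_s_rel_onset=-minutes * 60)
        assert len(wins) == expected

    def test_trailing_remainder_discarded(self):
        wins = window_signal(np.zeros(4096 * 2 + 1000), RATE, 4096)
        assert len(wins) == 2

    def test_short_signal_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            wins = window_signal(np.zeros(4000), RATE, 4096)
        assert wins == [] and "shorter than one" in caplog.text

    def test_timestamps_at_window_centers(self):
        wins = window_signal(np.zeros(4096 * 3), RATE, 4096, start_s_rel_onset=-1920.0)
        centers = [w.center_s_rel_onset for w in wins]
        np.testing.assert_allclose(centers, [-1912.0, -1896.0, -1880.0])


class TestPowerSpectrum:
    def test_pure_sine_concentrates(self):
        # sine at an exact bin-center frequency of the 1024-bin grid
        f0 = 32.0625  # center of a 0.125 Hz bin
        t = np.arange(4096) / RATE
        x = np.sin(2 * np.pi * f0 * t)
        w = window_signal(x, RATE, 4096)[0]
        power_spectrum(w, x, RATE)
        k = np.argmax(w.power)
        assert abs(w.bin_freqs_hz[k] - f0) < 0.125
        assert w.power[k] / w.power.sum() >= 0.99

    def test_zero_signal(self):
        x = np.zeros(4096)
        w = window_signal(x, RATE, 4096)[0]
        power_spectrum(w, x, RATE)
        assert w.power.sum() == 0.0

    def test_bin_count_and_span(self):
        x = np.ones(4096)
        w = power_spectrum(window_signal(x, RATE, 4096)[0], x, RATE)
        assert w.power.size == 1024
        assert w.bin_freqs_hz[0] == pytest.approx(0.0625)
        assert w.bin_freqs_hz[-1] == pytest.approx(127.9375)

    def test_parseval_ratio_constant(self, rng):
        """Sum of bin powers tracks sum of squared samples with a fixed
        constant across random inputs (DC excluded)."""
        ratios = []
        for _ in range(20):
            x = rng.standard_normal(4096)
            x -= x.mean()
            w = power_spectrum(window_signal(x, RATE, 4096)[0], x, RATE)
            ratios.append(w.power.sum() / np.sum(x**2))
        ratios = np.array(ratios)
        np.testing.assert_allclose(ratios, 4096 / 2, rtol=0.02)

    def test_length_mismatch(self):
        w = window_signal(np.zeros(4096), RATE, 4096)[0]
        with pytest.raises(ValueError, match="does not match"):
            power_spectrum(w, np.zeros(100), RATE)

    def test_indivisible_binning_rejected(self):
        x = np.zeros(4096)
        w = window_signal(x, RATE, 4096)[0]
        with pytest.raises(ValueError, match="aggregated"):
            power_spectrum(w, x, RATE, n_bins=1000)


class TestSpectralEntropy:
    def test_flat_spectrum_is_one(self):
        assert spectral_entropy(make_window(np.ones(1024)), FULL) == pytest.approx(1.0)

    def test_single_bin_is_zero(self):
        p = np.zeros(1024)
        p[100] = 5.0
        assert spectral_entropy(make_window(p), FULL) == 0.0

    def test_two_of_four_bins_is_half(self):
        band = BandDefinition("four", 0.0, 0.5)  # exactly 4 bins at this rate
        p = np.zeros(1024)
        p[0] = p[2] = 3.0
        assert spectral_entropy(make_window(p), band) == pytest.approx(
            math.log(2) / math.log(4)
        )

    def test_zero_power_is_nan_not_extreme(self):
        sen = spectral_entropy(make_window(np.zeros(1024)), FULL)
        assert math.isnan(sen)

    def test_band_restriction_ignores_out_of_band_power(self):
        p = np.ones(1024)
        p[900:] = 1e6  # power above the band must not matter
        band = BandDefinition("low", 0.1, 12.0)
        assert spectral_entropy(make_window(p), band) == pytest.approx(1.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            spectral_entropy(make_window(np.ones(1024)), BandDefinition("sliver", 0.0, 0.1))

    def test_white_noise_full_band_near_one(self, rng):
        vals = []
        for _ in range(50):
            x = rng.standard_normal(4096)
            w = power_spectrum(window_signal(x, RATE, 4096)[0], x, RATE)
            vals.append(spectral_entropy(w, FULL))
        assert np.mean(vals) >= 0.9

    @given(
        data=st.lists(st.floats(0.0, 1e3), min_size=4, max_size=64),
        base=st.sampled_from([math.e, 2.0, 10.0]),
        scale=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_brute_force_any_base_any_scale(self, data, base, scale):
        """SEN equals the brute-force oracle and is invariant to the log base
        and to power scaling."""
        if sum(data) <= 0:
            return
        w = make_window(np.asarray(data) * scale)
        band = BandDefinition("all", 0.0, RATE / 2)
        expected = brute_force_sen(data, log=lambda v: math.log(v, base))
        got = spectral_entropy(w, band)
        assert got == pytest.approx(expected, abs=1e-9)
        assert 0.0 <= got <= 1.0 + 1e-12

    @given(st.data())
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_concentration_monotonicity(self, data):
        """Moving power from a weaker bin to a stronger bin never raises SEN
        (checked against the brute-force oracle)."""
        n = data.draw(st.integers(4, 32))
        p = np.array(data.draw(
            st.lists(st.floats(0.01, 10.0), min_size=n, max_size=n)
        ))
        i, j = int(np.argmin(p)), int(np.argmax(p))
        if i == j:
            return
        frac = data.draw(st.floats(0.0, 1.0))
        q = p.copy()
        delta = frac * q[i]
        q[i] -= delta
        q[j] += delta
        assert brute_force_sen(q) <= brute_force_sen(p) + 1e-9
        band = BandDefinition("all", 0.0, RATE / 2)
        assert spectral_entropy(make_window(q), band) <= spectral_entropy(
            make_window(p), band
        ) + 1e-9


class TestEntropySeries:
    def test_counts_and_bounds_white_noise(self, rng):
        x = rng.standard_normal(28 * 60 * 256)
        series = entropy_series(x, DEFAULT_BANDS[0], RATE, start_s_rel_onset=-1920.0)
        assert len(series) == 105
        assert np.all((series.sen >= 0) & (series.sen <= 1))
        steps = np.diff(series.times_min_rel_onset)
        np.testing.assert_allclose(steps, 16 / 60)

    def test_amplitude_scaling_invariance_end_to_end(self, rng):
        x = rng.standard_normal(4096 * 8)
        for band_name in ("low", "high"):
            band = next(b for b in DEFAULT_BANDS if b.name == band_name)
            s1 = entropy_series(split_bands(x, rate_hz=RATE)[band_name], band, RATE)
            s2 = entropy_series(
                split_bands(137.0 * x, rate_hz=RATE)[band_name], band, RATE
            )
            np.testing.assert_allclose(s1.sen, s2.sen, atol=1e-9)

    def test_stationary_input_has_no_trend(self, rng):
        """Under stationarity the fitted slope is statistically zero."""
        hits = 0
        for _ in range(20):
            x = rng.standard_normal(28 * 60 * 256)
            series = entropy_series(x, DEFAULT_BANDS[2], RATE, start_s_rel_onset=-1920.0)
            tr = fit_trend(series)
            hits += abs(tr.slope_per_min) < 3 * tr.stderr
        assert hits >= 18

    def test_narrowing_spectrum_decreases_smoothed_sen(self, rng):
        """Noise whose bandwidth shrinks over time yields a decreasing 4-min
        moving average of SEN."""
        from scipy import signal as sps

        pieces = []
        n_win, wlen = 30, 4096
        for i in range(n_win):
            bw = 100.0 - i * 2.8  # linearly narrowing lowpass bandwidth
            taps = sps.firwin(257, bw, fs=RATE)
            noise = rng.standard_normal(wlen + 256)
            pieces.append(sps.lfilter(taps, 1.0, noise)[256:])
        x = np.concatenate(pieces)
        series = entropy_series(x, FULL, RATE, start_s_rel_onset=-n_win * 16.0)
        ma = moving_average(series, 4.0)
        interior = ma.value[7:-7]
        assert np.all(np.diff(interior) < 0)
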