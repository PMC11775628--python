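import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy.stats import spearmanr

from stnlfp import (
    TFConfig,
    band_power,
    band_power_series,
    bin_power,
    db_normalize,
    extract_epochs,
    morlet_power,
    qc_trial,
    zscore_epoch,
)
from stnlfp.datamodel import ConfigError, NumericalError, SchemaError
from stnlfp.spectral import TFMap

FS = 1000.0


def _tone(freq, dur=10.0, amp=1.0):
    t = np.arange(int(dur * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestMorlet:
    def test_theta_tone_selectivity(self):
        cfg = TFConfig()
        tf = morlet_power(_tone(5.0), FS, cfg)
        theta = band_power(tf, cfg.theta_band)
        beta = band_power(tf, cfg.beta_band)
        mid = slice(2000, 8000)
        assert theta[mid].mean() >= 10.0 * beta[mid].mean()
        peak_freq = cfg.freqs[np.argmax(tf.power[:, 5000])]
        assert abs(peak_freq - 5.0) <= 1.0

    def test_beta_tone_selectivity(self):
        cfg = TFConfig()
        tf = morlet_power(_tone(18.0), FS, cfg)
        mid = slice(2000, 8000)
        assert band_power(tf, cfg.beta_band)[mid].mean() >= 10.0 * band_power(
            tf, cfg.theta_band
        )[mid].mean()

    def test_zero_signal_zero_power(self):
        tf = morlet_power(np.zeros(6000), FS)
        assert np.allclose(tf.power, 0.0)

    def test_short_trace_rejected(self):
        with pytest.raises(SchemaError):
            morlet_power(np.zeros(500), FS)

    def test_streaming_band_series_matches_full_map(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4000)
        cfg = TFConfig()
        tf = morlet_power(x, FS, cfg)
        series, edge = band_power_series(x, FS, cfg)
        assert np.allclose(series["theta"], band_power(tf, cfg.theta_band))
        assert np.allclose(series["beta"], band_power(tf, cfg.beta_band))
        assert np.allclose(series["broadband"], tf.power.mean(axis=0))
        assert edge == tf.edge_samples.max()

    def test_amplitude_ladder_monotone_with_periodogram(self):
        """Wavelet and periodogram band power rank amplitudes identically."""
        cfg = TFConfig()
        amps = [0.5, 1.0, 2.0, 4.0, 8.0]
        wavelet, welch = [], []
        for a in amps:
            x = _tone(5.0, dur=6.0, amp=a)
            tf = morlet_power(x, FS, cfg)
            wavelet.append(band_power(tf, cfg.theta_band)[2000:4000].mean())
            f, p = sps.welch(x, fs=FS, nperseg=2048)
            sel = (f >= 4) & (f <= 7)
            welch.append(p[sel].mean())
        rho, _ = spearmanr(wavelet, welch)
        assert rho == pytest.approx(1.0)


class TestBandPower:
    def test_constant_map(self):
        tf = TFMap(np.arange(2.0, 31.0), np.full((29, 100), 3.25), np.zeros(29, int), FS)
        assert np.allclose(band_power(tf, (4, 7)), 3.25)

    def test_single_line_map(self):
        freqs = np.arange(2.0, 31.0)
        power = np.zeros((29, 50))
        power[freqs == 5.0] = 2.0
        tf = TFMap(freqs, power, np.zeros(29, int), FS)
        assert band_power(tf, (4, 7)).max() > 0
        assert np.allclose(band_power(tf, (12, 22)), 0.0)

    def test_matches_row_mean_oracle(self, rng):
        freqs = np.arange(2.0, 41.0)
        power = rng.random((len(freqs), 64))
        tf = TFMap(freqs, power, np.zeros(len(freqs), int), FS)
        sel = (freqs >= 12) & (freqs <= 22)
        assert np.allclose(band_power(tf, (12, 22)), power[sel].mean(axis=0))

    def test_band_outside_freqs_rejected(self):
        tf = TFMap(np.arange(4.0, 31.0), np.ones((27, 10)), np.zeros(27, int), FS)
        with pytest.raises(ConfigError):
            band_power(tf, (40, 60))


class TestNormalization:
    def test_db_closed_forms(self):
        base = np.full(380, 2.0)
        assert np.allclose(db_normalize(np.full(380, 2.0), base), 0.0)
        assert np.allclose(db_normalize(np.full(380, 20.0), base), 10.0)
        assert np.allclose(db_normalize(np.full(380, 1.0), base), -3.0103, atol=1e-3)

    def test_db_antisymmetry_for_constants(self):
        x = np.full(10, 5.0)
        y = np.full(10, 2.0)
        assert np.allclose(db_normalize(x, y) + db_normalize(y, x), 0.0)

    def test_db_rejects_nonpositive_baseline(self):
        with pytest.raises(NumericalError):
            db_normalize(np.ones(10), np.zeros(10))

    def test_zscore_closed_forms(self, rng):
        base = rng.standard_normal(100_000)
        z = zscore_epoch(np.full(380, 2.0), base)
        assert np.allclose(z, 2.0, atol=0.05)
        same = rng.random(380) + 1.0
        assert np.allclose(zscore_epoch(np.full(380, same.mean()), same), 0.0, atol=1e-12)

    def test_zscore_affine_invariance(self, rng):
        power = rng.random(380) + 1.0
        base = rng.random(380) + 1.0
        z1 = zscore_epoch(power, base)
        z2 = zscore_epoch(5.0 * power + 3.0, 5.0 * base + 3.0)
        assert np.allclose(z1, z2)

    def test_zscore_rejects_zero_sd(self):
        with pytest.raises(NumericalError):
            zscore_epoch(np.ones(10), np.ones(10))


class TestQC:
    def test_identical_windows_excluded(self):
        x = np.linspace(1, 2, 380)
        included, _ = qc_trial(x, x)
        assert not included

    def test_large_offset_included(self, rng):
        base = rng.random(380)
        included, p = qc_trial(base + 10.0, base)
        assert included and p < 1e-10

    def test_null_inclusion_rate_near_alpha(self, rng):
        hits = 0
        n = 2000
        for _ in range(n):
            a = rng.standard_normal(380)
            b = rng.standard_normal(380)
            inc, _ = qc_trial(a, b, 0.05)
            hits += inc
        assert abs(hits / n - 0.05) < 0.015

    def test_unequal_windows_rejected(self):
        with pytest.raises(SchemaError):
            qc_trial(np.ones(380), np.ones(379))


class TestBinning:
    def test_constant_series(self):
        assert np.allclose(bin_power(np.full(380, 2.5)), 2.5)

    def test_linear_ramp_midpoints(self):
        ramp = np.linspace(0.0, 1.0, 380, endpoint=False) + 0.5 / 380
        assert np.allclose(bin_power(ramp), [0.125, 0.375, 0.625, 0.875], atol=1e-3)

    def test_matches_brute_force_segments(self, rng):
        x = rng.random(380)
        expected = [x[i * 95 : (i + 1) * 95].mean() for i in range(4)]
        assert np.allclose(bin_power(x), expected)

    def test_indivisible_length_rejected(self):
        with pytest.raises(SchemaError):
            bin_power(np.ones(381))


class TestExtractEpochs:
    def _series(self, n=20_000):
        x = np.arange(n, dtype=float)
        return {"theta": x, "beta": 2 * x, "broadband": np.ones(n)}

    def _trials(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "trial_id", "block", "depth", "stim_onset_s", "stim_side",
                "correct_side", "response_side", "rt_ms", "correspondence",
                "accuracy", "iti_prev_ms",
            ],
        )

    def test_window_arithmetic(self):
        trials = self._trials(
            [[0, 0, "dorsal", 9.5, "left", "left", "left", 500.0, "Cs", "correct", 1000.0]]
        )
        eps, _ = extract_epochs(
            self._series(), FS, trials, TFConfig(), "left", "s", "dorsal"
        )
        theta = [e for e in eps if e.band == "theta"][0]
        # response at 10.000 s -> analysis window covers samples 9620..9999
        assert np.array_equal(theta.power_trace, np.arange(9620.0, 10000.0))
        # intertrial baseline: ends 100 ms before the 9.5 s stimulus onset
        assert np.array_equal(theta.baseline_power, np.arange(9020.0, 9400.0))
        assert theta.hemisphere_rel == "ipsilateral"

    def test_literal_preresponse_baseline(self):
        trials = self._trials(
            [[0, 0, "dorsal", 9.5, "left", "left", "right", 500.0, "Cs", "correct", 1000.0]]
        )
        cfg = TFConfig(baseline_policy="literal_preresponse")
        eps, _ = extract_epochs(self._series(), FS, trials, cfg, "left", "s", "dorsal")
        theta = [e for e in eps if e.band == "theta"][0]
        # baseline = [-480, -100) ms before the 10.0 s response
        assert np.array_equal(theta.baseline_power, np.arange(9520.0, 9900.0))
        assert theta.hemisphere_rel == "contralateral"

    def test_error_trial_emits_no_epoch(self):
        trials = self._trials(
            [[0, 0, "dorsal", 9.5, "left", "right", "left", 500.0, "NC", "error", 1000.0]]
        )
        eps, dropped = extract_epochs(
            self._series(), FS, trials, TFConfig(), "left", "s", "dorsal"
        )
        assert eps == []
        assert dropped[0]["reason"] == "not_correct:error"

    def test_out_of_bounds_dropped_with_reason(self):
        trials = self._trials(
            [[0, 0, "dorsal", 0.05, "left", "left", "left", 50.0, "Cs", "correct", 1000.0]]
        )
        eps, dropped = extract_epochs(
            self._series(), FS, trials, TFConfig(), "left", "s", "dorsal"
        )
        assert eps == []
        assert dropped[0]["reason"] == "out_of_bounds"
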