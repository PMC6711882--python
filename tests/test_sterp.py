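import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mweeg import sterp, synth
from mweeg.containers import CHANNELS, default_time_axis


@pytest.mark.parametrize("u, expected", [
    (0.0, 1.0),                      # unit peak
    (0.25, 0.0),                     # zero crossing of 1 - 16u^2
    (0.5, -3.0 * np.exp(-2.0)),      # closed-form evaluation
    (-0.5, -3.0 * np.exp(-2.0)),     # even symmetry
])
def test_mexican_hat_closed_form(u, expected):
    assert sterp.mexican_hat(u) == pytest.approx(expected, abs=1e-12)


class TestCrossCovariance:
    def test_zero_signal_gives_zero_map(self, time_axis):
        m = sterp.wavelet_cross_covariance(np.zeros(time_axis.size), time_axis,
                                           [100.0, 200.0])
        assert np.all(m.W == 0.0)

    def test_fast_route_matches_riemann_sum(self, time_axis):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(time_axis.size)
        s_grid = np.geomspace(50, 1400, 6)
        t_grid = time_axis[::17]
        fast = sterp.wavelet_cross_covariance(f, time_axis, s_grid, t_grid)
        slow = sterp.riemann_cross_covariance(f, time_axis, s_grid, t_grid)
        rel = np.max(np.abs(fast.W - slow.W)) / np.max(np.abs(slow.W))
        assert rel < 1e-6

    def test_embedded_template_is_grid_argmax(self, time_axis):
        t0, s0 = 450.0, 400.0
        f = sterp.mexican_hat((time_axis - t0) / s0)
        s_grid = np.geomspace(200, 1400, 32)
        m = sterp.wavelet_cross_covariance(f, time_axis, s_grid)
        si, tj = np.unravel_index(np.argmax(m.W), m.W.shape)
        dt = time_axis[1] - time_axis[0]
        assert abs(m.t_grid[tj] - t0) <= dt
        # nearest grid scale to s0
        assert abs(np.log(m.s_grid[si] / s0)) <= np.diff(np.log(s_grid))[0]

    def test_rejects_bad_inputs(self, time_axis):
        with pytest.raises(ValueError):
            sterp.wavelet_cross_covariance(np.array([]), np.array([]), [100.0])
        with pytest.raises(ValueError):
            sterp.wavelet_cross_covariance(np.zeros(time_axis.size), time_axis,
                                           [-5.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=-50, max_value=50,
                       allow_nan=False, allow_infinity=False))
    def test_scaling_equivariance(self, c):
        # W is linear in the signal: scaling f by c scales every W by c
        time_ms = default_time_axis()
        rng = np.random.default_rng(7)
        f = rng.standard_normal(time_ms.size)
        s_grid = np.array([100.0, 400.0])
        t_grid = time_ms[::50]
        base = sterp.wavelet_cross_covariance(f, time_ms, s_grid, t_grid)
        scaled = sterp.wavelet_cross_covariance(c * f, time_ms, s_grid, t_grid)
        np.testing.assert_allclose(scaled.W, c * base.W, rtol=1e-9, atol=1e-12)


class TestDetectComponent:
    def test_zero_map_is_degraded_with_zero_amplitude(self):
        m = sterp.WaveletMap(np.zeros((3, 11)), np.geomspace(100, 400, 3),
                             np.linspace(250, 600, 11))
        feat = sterp.detect_component(m, (250, 600), +1)
        assert feat.amplitude == 0.0 and feat.found == "degraded"

    def test_tie_breaks_to_earliest_lag_then_smallest_scale(self):
        W = np.zeros((3, 11))
        W[2, 6] = 5.0
        W[1, 3] = 5.0   # earlier lag wins
        W[2, 3] = 5.0   # smaller scale wins at that lag
        m = sterp.WaveletMap(W, np.geomspace(100, 400, 3), np.linspace(250, 600, 11))
        feat = sterp.detect_component(m, (250, 600), +1)
        assert feat.lag_ms == pytest.approx(np.linspace(250, 600, 11)[3])
        assert feat.scale_ms == pytest.approx(np.geomspace(100, 400, 3)[1])

    def test_boundary_extreme_flagged_degraded(self):
        W = np.zeros((3, 11))
        W[1, 0] = 2.0   # at the window's first lag
        m = sterp.WaveletMap(W, np.geomspace(100, 400, 3), np.linspace(250, 600, 11))
        assert sterp.detect_component(m, (250, 600), +1).found == "degraded"

    def test_negative_polarity_finds_minimum(self):
        W = np.zeros((3, 11))
        W[1, 5] = -4.0
        m = sterp.WaveletMap(W, np.geomspace(100, 400, 3), np.linspace(100, 200, 11))
        feat = sterp.detect_component(m, (100, 200), -1)
        assert feat.amplitude == -4.0 and feat.found == "ok"

    def test_window_outside_grid_raises(self):
        m = sterp.WaveletMap(np.zeros((2, 5)), [100.0, 200.0],
                             np.linspace(0, 100, 5))
        with pytest.raises(ValueError):
            sterp.detect_component(m, (500, 600), +1)


class TestExtractFeatures:
    def _epochs_with_p3(self, amps, extra=None, seed=0):
        time_ms = default_time_axis()
        rng = np.random.default_rng(seed)
        n = len(amps)
        data = np.zeros((n, len(CHANNELS), time_ms.size), dtype=np.float32)
        a19 = CHANNELS.index("A19")
        for k, a in enumerate(amps):
            data[k, a19] += a * sterp.mexican_hat((time_ms - 450.0) / 400.0)
            if extra is not None:
                data[k] += extra(rng, time_ms)
        import mweeg.containers as mc
        return mc.EpochSet(data, list(CHANNELS), 256.0, time_ms)

    def test_five_features_per_trial(self, make_epochs):
        eps = make_epochs(n_trials=3, fill=0.1)
        out = sterp.extract_erp_features(eps)
        assert len(out) == 5 * 3
        assert set(zip(out.component, out.channel)) == {
            ("P1", "A10"), ("P1", "B7"), ("N1", "A10"), ("N1", "B7"),
            ("P3", "A19")}

    def test_designed_p3_attenuation_recovered_noise_free(self):
        eps = self._epochs_with_p3([5.0] * 20 + [3.5] * 20)
        out = sterp.extract_erp_features(eps)
        p3 = out[out.component == "P3"].set_index("trial_id").W
        assert p3.iloc[20:].mean() < p3.iloc[:20].mean()

    def test_wider_n1_window_allows_late_lags(self, make_epochs):
        time_ms = default_time_axis()
        n1 = -3.0 * sterp.mexican_hat((time_ms - 220.0) / 120.0)
        eps = make_epochs(n_trials=1)
        eps.data[0, CHANNELS.index("A10")] = n1
        default = sterp.extract_erp_features(eps)
        widened = sterp.extract_erp_features(eps, sterp.with_n1_window())
        lag_def = default.query("component=='N1' and channel=='A10'").t_ms.iloc[0]
        lag_wide = widened.query("component=='N1' and channel=='A10'").t_ms.iloc[0]
        assert lag_def <= 200.0
        assert lag_wide > 200.0

    def test_missing_channel_raises(self, time_axis):
        import mweeg.containers as mc
        eps = mc.EpochSet(np.zeros((2, 2, time_axis.size)), ["A10", "B7"],
                          256.0, time_axis)
        with pytest.raises(KeyError):
            sterp.extract_erp_features(eps)

    def test_amplitude_recovery_under_noise(self):
        # matched-filter property at half-amplitude spectrally flat noise
        rng_amp = np.random.default_rng(11)
        amps = rng_amp.uniform(1.0, 5.0, 60)

        def extra(rng, time_ms):
            sd = 0.5 * 3.0
            return synth.pink_noise((len(CHANNELS), time_ms.size), 0.0, sd, rng)

        eps = self._epochs_with_p3(amps, extra=extra, seed=3)
        out = sterp.extract_erp_features(eps)
        p3 = out[out.component == "P3"].sort_values("trial_id")
        r = np.corrcoef(amps, p3.W)[0, 1]
        assert r > 0.9
        assert np.median(np.abs(p3.t_ms - 450.0)) <= 20.0


class TestTraditionalErp:
    def test_identical_epochs_average_to_one_epoch(self, make_epochs):
        eps = make_epochs(n_trials=4, fill=0.5)
        labels = np.array(["on_task"] * 4)
        waveforms, _ = sterp.traditional_erp(eps, labels)
        assert np.allclose(waveforms["mean_uv"], 0.5)

    def test_window_mean_of_constant_epoch_is_constant(self, make_epochs):
        eps = make_epochs(n_trials=2, fill=1.0)
        _, amps = sterp.traditional_erp(eps, np.array(["on_task", "mind_wandering"]))
        assert np.allclose(amps["amplitude"], 1.0)

    def test_empty_state_class_raises(self, make_epochs):
        eps = make_epochs(n_trials=2)
        with pytest.raises(ValueError):
            sterp.traditional_erp(eps, np.array(["on_task"]))

    def test_p3_window_mean_separates_designed_states(self):
        time_ms = default_time_axis()
        n = 40
        rng = np.random.default_rng(5)
        data = rng.standard_normal((n, len(CHANNELS), time_ms.size)).astype(np.float32)
        a19 = CHANNELS.index("A19")
        amps = np.array([5.0] * (n // 2) + [3.5] * (n // 2))
        for k in range(n):
            data[k, a19] += amps[k] * sterp.mexican_hat((time_ms - 450.0) / 400.0)
        import mweeg.containers as mc
        eps = mc.EpochSet(data, list(CHANNELS), 256.0, time_ms)
        labels = np.array(["on_task"] * (n // 2) + ["mind_wandering"] * (n // 2))
        _, amps_df = sterp.traditional_erp(eps, labels)
        p3 = amps_df[amps_df.component == "P3"]
        ot = p3[p3.state == "on_task"].amplitude
        mw = p3[p3.state == "mind_wandering"].amplitude
        assert ot.mean() > mw.mean()
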