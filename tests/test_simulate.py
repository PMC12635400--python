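import numpy as np
import pytest
from scipy.stats import poisson

from gutephys.conditioning import FilterSpec, butterworth_filter
from gutephys.simulate import (BurstSpec, EventSpec, LineNoiseSpec,
                               OscillationSpec, SyntheticConfig, UnitSpec,
                               generate_spike_train, inject_evoked_response,
                               make_spike_template, simulate_behavior_session,
                               simulate_session)
from gutephys.spectral import welch_psd


class TestNullAndDeterminism:
    def test_all_zero_config_gives_zero_matrix(self, single_tetrode):
        cfg = SyntheticConfig(layout=single_tetrode, fs=10_000.0,
                              duration_s=2.0, noise_sd_uv=0.0, seed=1)
        sess, _ = simulate_session(cfg)
        assert np.all(sess.voltages == 0.0)

    def test_same_seed_bit_identical(self, single_tetrode):
        cfg = SyntheticConfig(
            layout=single_tetrode, fs=10_000.0, duration_s=3.0,
            units=[UnitSpec(peak_site=0, mean_rate=4.0)],
            background=[OscillationSpec(0.1, 20.0)],
            line_noise=LineNoiseSpec(amplitude_uv=5.0),
            noise_sd_uv=5.0, seed=99)
        a, ta = simulate_session(cfg)
        b, tb = simulate_session(cfg)
        assert np.array_equal(a.voltages, b.voltages)
        np.testing.assert_array_equal(ta.spike_times[0], tb.spike_times[0])

    def test_different_seed_differs(self, quiet_config):
        import dataclasses

        a, _ = simulate_session(quiet_config)
        b, _ = simulate_session(dataclasses.replace(quiet_config, seed=8))
        assert not np.array_equal(a.voltages, b.voltages)


class TestSpikeGeneration:
    def test_poisson_count_in_99pct_interval(self, single_tetrode):
        cfg = SyntheticConfig(
            layout=single_tetrode, fs=10_000.0, duration_s=300.0,
            units=[UnitSpec(peak_site=0, mean_rate=5.0, amplitude_uv=0.0,
                            refractory_ms=0.1)],
            noise_sd_uv=0.0, seed=2)
        _, truth = simulate_session(cfg)
        n = len(truth.spike_times[0])
        assert poisson.ppf(0.005, 1500) <= n <= poisson.ppf(0.995, 1500)

    def test_refractory_never_violated(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = generate_spike_train(rng, 80.0, 30.0, 0.003)
            assert len(t) > 0
            assert np.diff(t).min() >= 0.003

    def test_template_is_negative_biphasic(self):
        tpl = make_spike_template(30_000.0)
        assert len(tpl) == 105  # 3.5 ms at 30 kHz
        assert tpl.min() == -1.0
        assert tpl[np.argmin(tpl):].max() > 0.05  # rebound after trough

    def test_spatial_amplitude_ordering(self, single_tetrode):
        cfg = SyntheticConfig(
            layout=single_tetrode, fs=30_000.0, duration_s=5.0,
            units=[UnitSpec(peak_site=0, amplitude_uv=100.0, mean_rate=10.0)],
            noise_sd_uv=0.0, seed=3)
        sess, truth = simulate_session(cfg)
        troughs = -sess.voltages.min(axis=1)
        dists = [single_tetrode.distance(0, c) for c in sess.channel_ids]
        order = np.argsort(dists)
        assert np.all(np.diff(troughs[order]) <= 1e-9)
        assert np.argmax(troughs) == sess.channel_ids.index(0)

    def test_rate_schedule_thinning(self):
        rng = np.random.default_rng(0)
        t = generate_spike_train(rng, 10.0, 200.0, 0.001,
                                 schedule=[(100.0, 200.0, 2.0)])
        pre = np.sum(t < 100.0)
        post = np.sum(t >= 100.0)
        assert post / pre == pytest.approx(2.0, rel=0.15)


class TestOscillationsAndNoise:
    def test_spectral_placement_of_single_oscillation(self, single_tetrode):
        for f in (0.1, 0.5, 2.0, 50.0, 500.0):
            cfg = SyntheticConfig(
                layout=single_tetrode, fs=10_000.0, duration_s=60.0,
                background=[OscillationSpec(f, 10.0)],
                noise_sd_uv=0.01, seed=4)
            sess, _ = simulate_session(cfg)
            psd = welch_psd(sess.voltages[0], 10_000.0, segment_length=200_000)
            peak = psd.freqs[np.argmax(psd.density)]
            lo, hi = OscillationSpec(f, 1.0).band
            assert lo <= peak < hi

    def test_oscillation_above_nyquist_rejected(self, single_tetrode):
        cfg = SyntheticConfig(layout=single_tetrode, fs=100.0, duration_s=1.0,
                              background=[OscillationSpec(80.0, 1.0)], seed=0)
        with pytest.raises(ValueError):
            simulate_session(cfg)

    def test_line_noise_contains_only_odd_harmonics(self, single_tetrode):
        from gutephys.simulate import LineNoiseSpec

        cfg = SyntheticConfig(layout=single_tetrode, fs=10_000.0,
                              duration_s=20.0,
                              line_noise=LineNoiseSpec(amplitude_uv=10.0),
                              noise_sd_uv=0.0, seed=5)
        sess, _ = simulate_session(cfg)
        psd = welch_psd(sess.voltages[0], 10_000.0, segment_length=20_000)

        def level(f):
            return psd.density[np.argmin(np.abs(psd.freqs - f))]

        for f in (50.0, 150.0, 250.0, 350.0):
            assert level(f) > 1e3 * level(100.0)
        assert level(100.0) == pytest.approx(level(97.0), abs=1e-6)


class TestEvokedInjection:
    def _base(self, single_tetrode, **kw):
        cfg = SyntheticConfig(layout=single_tetrode, fs=10_000.0,
                              duration_s=60.0, noise_sd_uv=0.0, seed=6, **kw)
        return simulate_session(cfg)

    def test_saline_leaves_session_unchanged(self, single_tetrode):
        sess, _ = self._base(single_tetrode)
        out = inject_evoked_response(sess, EventSpec("saline", 10.0))
        assert np.max(np.abs(out.voltages - sess.voltages)) == 0.0
        assert list(out.events.entries["kind"]) == ["saline"]

    def test_hf_burst_energy_confined_to_window(self, single_tetrode):
        sess, _ = self._base(single_tetrode)
        ev = EventSpec("distension", 10.0, amplitude_uv=30.0,
                       lf_amplitude_uv=0.0, delay_s=2.0, hf_duration_s=5.0)
        out = inject_evoked_response(sess, ev)
        hp = butterworth_filter(out.voltages[0], 10_000.0,
                                FilterSpec("bandpass", (300.0, 2000.0)))
        e = hp ** 2
        t = np.arange(len(e)) / 10_000.0
        inside = e[(t >= 11.9) & (t <= 17.1)].sum()
        assert inside / e.sum() > 0.99

    def test_desensitization_halves_second_response(self, single_tetrode):
        sess, _ = self._base(single_tetrode)
        common = dict(amplitude_uv=0.0, lf_amplitude_uv=40.0, delay_s=1.0,
                      lf_duration_s=4.0, desensitization=0.5)
        out = inject_evoked_response(sess, EventSpec("drug", 5.0,
                                                     repeat_index=0, **common))
        out = inject_evoked_response(out, EventSpec("drug", 25.0,
                                                    repeat_index=1, **common))
        low = butterworth_filter(out.voltages[0], 10_000.0,
                                 FilterSpec("lowpass", (300.0,)))
        first = low[(np.arange(len(low)) / 10_000.0 > 5) &
                    (np.arange(len(low)) / 10_000.0 < 11)].max()
        second = low[(np.arange(len(low)) / 10_000.0 > 25) &
                     (np.arange(len(low)) / 10_000.0 < 31)].max()
        assert second == pytest.approx(0.5 * first, rel=0.02)

    def test_response_past_session_end_rejected(self, single_tetrode):
        sess, _ = self._base(single_tetrode)
        with pytest.raises(ValueError):
            inject_evoked_response(
                sess, EventSpec("drug", 58.0, delay_s=1.0, hf_duration_s=5.0))


class TestBehaviorSession:
    def test_no_modulation_keeps_rates_equal(self, single_tetrode):
        cfg = SyntheticConfig(
            layout=single_tetrode, fs=1000.0, duration_s=600.0,
            units=[UnitSpec(peak_site=0, mean_rate=6.0, amplitude_uv=0.0,
                            feeding_gain=1.0)],
            noise_sd_uv=0.0, seed=7)
        _, truth = simulate_behavior_session(cfg, feeding_time=300.0,
                                             stress_density_uv2hz=0.0)
        t = truth.spike_times[0]
        pre, post = np.sum(t < 300.0), np.sum(t >= 300.0)
        assert post / pre == pytest.approx(1.0, rel=0.15)

    def test_feeding_step_doubles_rate(self, single_tetrode):
        cfg = SyntheticConfig(
            layout=single_tetrode, fs=1000.0, duration_s=600.0,
            units=[UnitSpec(peak_site=0, mean_rate=6.0, amplitude_uv=0.0,
                            feeding_gain=2.0)],
            noise_sd_uv=0.0, seed=8)
        _, truth = simulate_behavior_session(cfg, feeding_time=300.0,
                                             stress_density_uv2hz=0.0)
        t = truth.spike_times[0]
        assert np.sum(t >= 300.0) / np.sum(t < 300.0) == pytest.approx(
            2.0, rel=0.15)

    def test_day_attenuation_zero_flattens_background(self, single_tetrode):
        cfg = SyntheticConfig(layout=single_tetrode, fs=1000.0,
                              duration_s=300.0, noise_sd_uv=1.0, seed=9)
        _, truth = simulate_behavior_session(
            cfg, feeding_time=150.0, day_attenuation=0.0, day=2,
            stress_density_uv2hz=5.0)
        assert np.all(truth.band_power["power"] == 0.0)

    def test_ground_truth_band_power_decays_exponentially(self, single_tetrode):
        cfg = SyntheticConfig(layout=single_tetrode, fs=1000.0,
                              duration_s=300.0, noise_sd_uv=0.5, seed=10)
        _, truth = simulate_behavior_session(
            cfg, feeding_time=150.0, stress_decay_tau=300.0,
            stress_density_uv2hz=4.0)
        bp = truth.band_power
        one = bp[bp["band"] == bp["band"].iloc[0]].sort_values("minute")
        ratios = one["power"].to_numpy()[1:] / one["power"].to_numpy()[:-1]
        np.testing.assert_allclose(ratios, np.exp(-60.0 / 300.0), rtol=1e-9)


def test_emg_burst_outside_session_rejected(single_tetrode):
    cfg = SyntheticConfig(layout=single_tetrode, fs=1000.0, duration_s=10.0,
                          emg=BurstSpec(times_s=[9.5], duration_s=2.0,
                                        amplitude_uv=10.0), seed=0)
    with pytest.raises(ValueError):
        simulate_session(cfg)
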