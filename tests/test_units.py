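import numpy as np
import pandas as pd
import pytest

from gutephys import SyntheticConfig, UnitSpec, simulate_session
from gutephys.conditioning import ArtifactEpochs, FilterSpec, butterworth_filter
from gutephys.simulate import make_spike_template
from gutephys.units import (GAUSSIAN_QUARTILE, UnitCluster, correlogram,
                            detect_spikes, extract_waveforms, merge_events,
                            noise_floor, qc_unit, reject_coincident,
                            sort_session, SpikeTrain)


class TestNoiseFloor:
    def test_zero_signal_zero_floor(self):
        assert noise_floor(np.zeros(1000), 1000.0).floor == 0.0

    def test_gaussian_calibration_mean_variant(self, rng):
        # E|X| = sigma*sqrt(2/pi), so mean(|x|)/0.6745 -> 1.183*sigma
        sigma = 4.0
        x = rng.standard_normal(100_000) * sigma
        fl = noise_floor(x, 1000.0)
        expected = sigma * np.sqrt(2 / np.pi) / GAUSSIAN_QUARTILE
        assert fl.floor == pytest.approx(expected, rel=0.02)
        assert fl.floor == pytest.approx(1.183 * sigma, rel=0.02)

    def test_gaussian_calibration_median_variant(self, rng):
        sigma = 4.0
        x = rng.standard_normal(100_000) * sigma
        fl = noise_floor(x, 1000.0, variant="median")
        assert fl.floor == pytest.approx(sigma, rel=0.02)

    def test_five_longest_epochs_selected(self):
        # artifacts carve the 21 s trace into epochs of 1..6 s
        fs = 1000.0
        x = np.ones(int(21 * fs))
        cuts = [1.0, 3.0, 6.0, 10.0, 15.0]  # epochs: 1,2,3,4,5,6 s
        ep = ArtifactEpochs(pd.DataFrame(
            [{"start_s": c, "end_s": c, "reason": "manual"} for c in cuts]))
        fl = noise_floor(x, fs, ep)
        lengths = sorted(round(e - s) for s, e in fl.epochs_used)
        assert lengths == [2, 3, 4, 5, 6]

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(50_000)
        f1 = noise_floor(x, 1000.0).floor
        f3 = noise_floor(3.0 * x, 1000.0).floor
        assert f3 == pytest.approx(3.0 * f1, rel=1e-12)

    def test_no_artifact_free_samples_rejected(self):
        ep = ArtifactEpochs(pd.DataFrame(
            [{"start_s": 0.0, "end_s": 10.0, "reason": "manual"}]))
        with pytest.raises(ValueError):
            noise_floor(np.zeros(1000), 100.0, ep)


class TestDetectSpikes:
    def test_false_positive_rate_on_pure_noise(self, rng):
        # threshold 5*floor = 5.9 sigma: Gaussian tail gives ~0 crossings
        fs = 30_000.0
        x = butterworth_filter(rng.standard_normal(int(10 * fs)), fs,
                               FilterSpec("highpass", (300.0,)))
        fl = noise_floor(x, fs)
        train = detect_spikes(x, fs, fl, 5.0)
        assert len(train) / 10.0 < 0.1  # events per second

    def test_recall_and_precision_on_inserted_templates(self, rng):
        fs = 30_000.0
        sigma = 5.0
        x = rng.standard_normal(int(30 * fs)) * sigma
        tpl = make_spike_template(fs)
        true_times = np.arange(0.5, 29.5, 0.1)  # 290 spikes
        amp = 10 * 1.183 * sigma  # -10x the (mean-variant) floor
        for t in true_times:
            i = int(t * fs)
            x[i:i + len(tpl)] += amp * tpl
        hp = butterworth_filter(x, fs, FilterSpec("highpass", (300.0,)))
        fl = noise_floor(hp, fs)
        train = detect_spikes(hp, fs, fl, 5.0)
        trough_offset = np.argmin(tpl) / fs
        matched = sum(np.min(np.abs(train.times - (t + trough_offset))) < 5e-4
                      for t in true_times)
        assert matched / len(true_times) >= 0.99          # recall
        assert matched / max(1, len(train)) >= 0.95       # precision

    def test_single_excursion_single_spike(self):
        fs = 30_000.0
        x = np.zeros(int(fs))
        x[1000:1009] = -50.0  # 0.3 ms excursion
        train = detect_spikes(x, fs, 5.0, 5.0)
        assert len(train) == 1

    def test_monotone_in_multiplier(self, rng):
        fs = 30_000.0
        x = butterworth_filter(rng.standard_normal(int(20 * fs)) * 5, fs,
                               FilterSpec("highpass", (300.0,)))
        fl = noise_floor(x, fs)
        counts = [len(detect_spikes(x, fs, fl, m))
                  for m in (4.0, 4.5, 5.0, 5.5, 6.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nonstandard_multiplier_warns(self):
        with pytest.warns(UserWarning):
            detect_spikes(np.zeros(100), 1000.0, 1.0, 7.0)


class TestCoincidenceRejection:
    def _train(self, times, ch):
        t = np.asarray(times, dtype=float)
        return SpikeTrain(ch, t, np.full_like(t, -50.0), 5.0)

    def test_spike_on_all_channels_removed(self):
        trains = [self._train([1.0, 2.0], c) for c in range(28)]
        out = reject_coincident(trains)
        assert all(len(tr) == 0 for tr in out)

    def test_localized_spike_survives(self):
        trains = [self._train([1.0], c) for c in range(4)]
        trains += [self._train([], c) for c in range(4, 28)]
        out = reject_coincident(trains)
        assert sum(len(tr) for tr in out) == 4

    def test_empty_trains_pass_through(self):
        trains = [self._train([], c) for c in range(3)]
        out = reject_coincident(trains)
        assert all(len(tr) == 0 for tr in out)


class TestWaveforms:
    def test_snippet_length_at_30khz(self, rng):
        from gutephys.io import RecordingSession

        sess = RecordingSession(
            rng.standard_normal((2, 30_000)).astype(np.float32), 30_000.0,
            [0, 1])
        wf, kept, dropped = extract_waveforms(sess, np.array([0.5]))
        assert wf.shape == (1, 2, 105)

    def test_edge_spike_dropped_and_reported(self, rng):
        from gutephys.io import RecordingSession

        sess = RecordingSession(
            rng.standard_normal((1, 30_000)).astype(np.float32), 30_000.0, [0])
        wf, kept, dropped = extract_waveforms(sess, np.array([0.0001, 0.5]))
        assert dropped == 1 and len(kept) == 1

    def test_recovered_template_correlates(self, single_tetrode):
        cfg = SyntheticConfig(
            layout=single_tetrode, fs=30_000.0, duration_s=20.0,
            units=[UnitSpec(peak_site=0, amplitude_uv=100.0, mean_rate=5.0)],
            noise_sd_uv=2.0, seed=11)
        sess, truth = simulate_session(cfg)
        hp = sess.copy_with(voltages=butterworth_filter(
            sess.voltages, sess.fs, FilterSpec("highpass", (300.0,))))
        wf, kept, _ = extract_waveforms(hp, truth.spike_times[0])
        # oracle: the inserted template passed through the same high-pass
        pad = np.zeros(3000)
        tpl = np.concatenate([pad, make_spike_template(sess.fs), pad])
        tpl_hp = butterworth_filter(tpl, sess.fs,
                                    FilterSpec("highpass", (300.0,)))
        tpl_hp = tpl_hp[len(pad):len(pad) + 105]
        mean_peak = wf.mean(axis=0)[0]
        r = np.corrcoef(mean_peak, tpl_hp)[0, 1]
        assert r > 0.99


class TestSortingAndQC:
    def test_two_units_recovered_with_high_accuracy(self, single_tetrode):
        floor = 1.183 * 5.0
        tpl = make_spike_template(30_000.0)
        n = len(tpl)
        t_ms = np.arange(n) / 30_000.0 * 1e3
        wide = -np.exp(-0.5 * ((t_ms - 3.5 / 3) / 0.25) ** 2) \
            + 0.5 * np.exp(-0.5 * ((t_ms - 3.5 / 3 - 0.9) / 0.5) ** 2)
        wide /= np.abs(wide.min())
        cfg = SyntheticConfig(
            layout=single_tetrode, fs=30_000.0, duration_s=120.0,
            units=[UnitSpec(peak_site=0, amplitude_uv=10 * floor, mean_rate=5),
                   UnitSpec(peak_site=3, amplitude_uv=8 * floor, mean_rate=5,
                            template=wide)],
            noise_sd_uv=5.0, seed=7)
        sess, truth = simulate_session(cfg)
        clusters = sort_session(sess)
        accepted = [c for c in clusters if c.accepted]
        assert len(accepted) == 2
        correct = total = 0
        for c in accepted:
            hits = [np.sum(np.abs(gt[:, None] - c.spike_times[None, :]
                                  ).min(axis=0) < 5e-4)
                    for gt in truth.spike_times.values()]
            correct += max(hits)
            total += len(c.spike_times)
        assert correct / total >= 0.95

    def test_single_unit_single_cluster(self, single_tetrode):
        floor = 1.183 * 5.0
        cfg = SyntheticConfig(
            layout=single_tetrode, fs=30_000.0, duration_s=60.0,
            units=[UnitSpec(peak_site=0, amplitude_uv=10 * floor,
                            mean_rate=5)],
            noise_sd_uv=5.0, seed=13)
        sess, _ = simulate_session(cfg)
        accepted = [c for c in sort_session(sess) if c.accepted]
        assert len(accepted) == 1

    def test_refractory_violations_fail_qc(self, rng):
        # Poisson train with no dead time at 50 Hz: ~10% of ISIs < 2 ms
        tpl = make_spike_template(30_000.0)
        wf = np.tile(tpl * 80.0, (200, 1, 1))
        wf[:, 0, :] += rng.standard_normal(wf[:, 0, :].shape)
        times = np.sort(rng.uniform(0, 4.0, 200))
        c = UnitCluster(0, times, wf.mean(axis=0), 0, [0],
                        np.zeros((200, 2)), waveforms=wf, fs=30_000.0)
        qc_unit(c)
        assert not c.qc["refractory"]

    def test_common_mode_waveform_fails_spatial(self, default_layout, rng):
        tpl = make_spike_template(30_000.0) * 80.0
        wf = np.tile(tpl, (50, 28, 1))
        wf += 0.1 * rng.standard_normal(wf.shape)
        times = np.sort(rng.uniform(0, 50.0, 50))
        c = UnitCluster(0, times, wf.mean(axis=0),
                        default_layout.recording_ids[0],
                        default_layout.recording_ids, np.zeros((50, 2)),
                        waveforms=wf, fs=30_000.0)
        qc_unit(c, default_layout)
        assert not c.qc["spatial"]

    def test_merge_events_collapses_multichannel_detections(self):
        t = SpikeTrain(0, np.array([1.0]), np.array([-60.0]), 5.0)
        u = SpikeTrain(1, np.array([1.0001]), np.array([-80.0]), 5.0)
        times, chans = merge_events([t, u])
        assert len(times) == 1 and chans[0] == 1  # deepest trough wins


class TestCorrelogram:
    def test_cross_symmetry(self, rng):
        a = np.sort(rng.uniform(0, 100.0, 400))
        b = np.sort(rng.uniform(0, 100.0, 300))
        ab = correlogram(a, b, n_shuffles=10, seed=0, duration_s=100.0)
        ba = correlogram(b, a, n_shuffles=10, seed=0, duration_s=100.0)
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])

    def test_total_count_conservation(self, rng):
        a = np.sort(rng.uniform(0, 50.0, 200))
        b = np.sort(rng.uniform(0, 50.0, 150))
        cg = correlogram(a, b, bin_ms=1.0, span_ms=20.0, n_shuffles=5,
                         seed=0, duration_s=50.0)
        half = (20.0 + 0.5) * 1e-3
        pairs = sum(np.sum(np.abs(b - t) < half) for t in a)
        assert cg.counts.sum() == pairs

    def test_autocorrelogram_refractory_dip(self):
        from gutephys.simulate import generate_spike_train

        rng = np.random.default_rng(21)
        t = generate_spike_train(rng, 20.0, 300.0, 0.005)
        cg = correlogram(t, bin_ms=1.0, span_ms=50.0, n_shuffles=200,
                         seed=1, duration_s=300.0)
        inner = np.abs(cg.lags_ms) < 4.0
        assert np.all(cg.counts[inner] < cg.ci_low[inner])

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            correlogram(np.array([]), np.array([1.0]))
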