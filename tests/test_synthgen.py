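"""Generator contracts: determinism, conservation, event-rate consistency."""
import numpy as np
import pytest

from ictaloop import calcium, synthgen
from ictaloop.synthgen import CalciumConfig, GenConfig, RegionOnsetRule


class TestGenerateLfp:
    def test_no_events_requested_gives_pure_noise(self):
        cfg = GenConfig(duration=30, interictal_rate=0.0, seizure_rate=0.0, seed=1)
        rec, truth = synthgen.generate_lfp(cfg)
        assert truth.interictal_spike_times.size == 0
        assert truth.n_seizures == 0
        # pure Gaussian noise: robust SD close to configured sigma
        from ictaloop.core import robust_sd
        assert robust_sd(rec.samples[0]) == pytest.approx(cfg.gaussian_sigma, rel=0.1)

    def test_determinism_bit_identical(self):
        cfg = GenConfig(duration=60, seed=42, seizure_rate=0.05, seizure_min_gap=10)
        rec1, truth1 = synthgen.generate_lfp(cfg)
        rec2, truth2 = synthgen.generate_lfp(cfg)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert np.array_equal(truth1.interictal_spike_times, truth2.interictal_spike_times)
        assert truth1.seizure_intervals == truth2.seizure_intervals

    def test_interictal_count_matches_poisson_expectation(self):
        # mean inserted count over replicate seeds ~ rate x duration
        rate, duration, n_seeds = 0.2, 600.0, 50
        counts = []
        for seed in range(n_seeds):
            cfg = GenConfig(duration=duration, interictal_rate=rate,
                            seizure_rate=0.0, seed=seed)
            _, truth = synthgen.generate_lfp(cfg)
            counts.append(truth.interictal_spike_times.size)
        expected = rate * duration
        tol = 3.0 * np.sqrt(expected)  # 3 x Poisson sd
        assert abs(np.mean(counts) - expected) < tol

    def test_conservation_removing_events_recovers_noise(self):
        cfg = GenConfig(duration=60, seed=5, seizure_rate=0.05, seizure_min_gap=10)
        rec, truth = synthgen.generate_lfp(cfg)
        noise_cfg = GenConfig(duration=60, seed=5, interictal_rate=0.0,
                              seizure_rate=0.0)
        noise, _ = synthgen.generate_lfp(noise_cfg)
        wave, peak = synthgen.spike_waveform(cfg.spike_width, cfg.spike_amplitude,
                                             cfg.sampling_rate)
        rebuilt = rec.samples[0].copy()
        for t in truth.all_spike_times():
            synthgen._add_waveform(rebuilt, cfg.sampling_rate, t, wave, peak,
                                   sign=-1.0)
        np.testing.assert_allclose(rebuilt, noise.samples[0], atol=1e-12)

    def test_per_seizure_spikes_inside_intervals_and_clusterable(self):
        cfg = GenConfig(duration=300, seed=3, seizure_rate=0.03,
                        seizure_min_gap=15)
        _, truth = synthgen.generate_lfp(cfg)
        assert truth.n_seizures > 0
        for (a, b), spikes in zip(truth.seizure_intervals,
                                  truth.per_seizure_spike_times):
            # spike train spans the interval: first discharge at onset,
            # terminal discharge at offset
            assert spikes[0] == pytest.approx(a)
            assert spikes[-1] == pytest.approx(b)
            assert np.all((spikes >= a) & (spikes <= b))
            assert np.all(np.diff(spikes) < 1.0)  # inclusion criterion holds
            assert np.all(np.diff(spikes) > 0)

    def test_interictal_spikes_are_isolated(self):
        cfg = GenConfig(duration=600, seed=9, interictal_rate=0.3,
                        seizure_rate=0.0)
        _, truth = synthgen.generate_lfp(cfg)
        assert np.all(np.diff(truth.interictal_spike_times)
                      >= cfg.interictal_min_gap)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GenConfig(truncation_factor=1.5)
        with pytest.raises(ValueError):
            GenConfig(interictal_rate=-1)
        with pytest.raises(ValueError):
            GenConfig(within_isi_mean=1.5)


class TestApplyIntervention:
    def _session(self):
        cfg = GenConfig(duration=120, seed=11, seizure_rate=0.05,
                        seizure_min_gap=15)
        rec, truth = synthgen.generate_lfp(cfg)
        assert truth.n_seizures >= 1
        return cfg, rec, truth

    def test_factor_one_is_identity(self):
        cfg, rec, truth = self._session()
        a, b = truth.seizure_intervals[0]
        out, t2 = synthgen.apply_intervention(rec, truth, [(a + b) / 2], cfg, 1.0)
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert t2.seizure_intervals == truth.seizure_intervals
        assert len(t2.light_intervals) == 1

    def test_post_trigger_duration_scaled(self):
        # one seizure [10, 20), trigger 12, factor 0.5 -> new offset 16
        cfg = GenConfig(duration=40, seed=0, interictal_rate=0,
                        seizure_rate=0)
        rec, _ = synthgen.generate_lfp(cfg)
        spikes = np.arange(10.0, 20.0, 0.4)
        truth = synthgen.GroundTruth(np.array([]), [(10.0, 20.0)], [spikes],
                                     duration=40.0)
        for t in spikes:
            wave, peak = synthgen.spike_waveform(cfg.spike_width,
                                                 cfg.spike_amplitude, 500.0)
            synthgen._add_waveform(rec.samples[0], 500.0, t, wave, peak)
        _, t2 = synthgen.apply_intervention(rec, truth, [12.0], cfg, 0.5)
        assert t2.seizure_intervals[0] == (10.0, pytest.approx(16.0))
        assert np.all(t2.per_seizure_spike_times[0] <= 16.0)
        assert t2.per_seizure_spike_times[0][-1] == pytest.approx(16.0)
        assert t2.light_intervals == [(12.0, pytest.approx(16.0))]

    def test_trigger_outside_any_seizure_is_noop(self, caplog):
        cfg, rec, truth = self._session()
        gap_t = truth.seizure_intervals[0][1] + 1e9  # far outside
        out, t2 = synthgen.apply_intervention(rec, truth, [gap_t], cfg, 0.5)
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert t2.seizure_intervals == truth.seizure_intervals
        assert not t2.light_intervals

    def test_signal_stays_consistent_with_truth_after_intervention(self):
        # conservation: stripping every truth spike from the intervened
        # signal and from the original signal leaves the same background
        cfg, rec, truth = self._session()
        a, b = truth.seizure_intervals[0]
        out, t2 = synthgen.apply_intervention(rec, truth, [a + 0.5], cfg, 0.3)
        wave, peak = synthgen.spike_waveform(cfg.spike_width,
                                             cfg.spike_amplitude, 500.0)
        assert t2.per_seizure_spike_times[0].size < \
            truth.per_seizure_spike_times[0].size
        res_out = out.samples[0].copy()
        for t in t2.all_spike_times():
            synthgen._add_waveform(res_out, 500.0, t, wave, peak, sign=-1.0)
        res_in = rec.samples[0].copy()
        for t in truth.all_spike_times():
            synthgen._add_waveform(res_in, 500.0, t, wave, peak, sign=-1.0)
        np.testing.assert_allclose(res_out, res_in, atol=1e-12)

    def test_lengthening_rejected(self):
        cfg, rec, truth = self._session()
        with pytest.raises(ValueError):
            synthgen.apply_intervention(rec, truth, [], cfg, 1.2)


class TestGenerateCalcium:
    def test_no_events_no_noise_gives_flat_baseline(self):
        truth = synthgen.GroundTruth(np.array([]), [], [], duration=30.0)
        cfg = GenConfig(duration=30, calcium=CalciumConfig(noise_sigma=0.0))
        traces, ft = synthgen.generate_calcium(truth, 3, cfg)
        np.testing.assert_allclose(traces, 1.0)
        assert ft.size == int(round(30 * 15.49))

    def test_single_spike_peak_after_event_then_monotone_decay(self):
        truth = synthgen.GroundTruth(np.array([10.0]), [], [], duration=30.0)
        cfg = GenConfig(duration=30, calcium=CalciumConfig(noise_sigma=0.0))
        traces, ft = synthgen.generate_calcium(truth, 1, cfg)
        tr = traces[0]
        peak = int(np.argmax(tr))
        assert ft[peak] > 10.0
        tail = tr[peak:]
        assert np.all(np.diff(tail) <= 1e-12)

    def test_movie_roundtrip_recovers_traces(self):
        truth = synthgen.GroundTruth(np.array([3.0, 8.0]), [(12.0, 17.0)],
                                     [np.arange(12.0, 17.0, 0.3)], duration=25.0)
        cfg = GenConfig(duration=25, calcium=CalciumConfig(noise_sigma=0.0))
        traces, _ = synthgen.generate_calcium(truth, 4, cfg)
        movie, labels = synthgen.render_movie(traces, pixel_noise=0.0)
        masks = calcium.masks_from_label_image(labels)
        recovered = calcium.extract_traces(movie, masks)
        np.testing.assert_allclose(recovered, traces, rtol=1e-6)

    def test_bad_kinetics_rejected(self):
        with pytest.raises(ValueError):
            CalciumConfig(rise_tau=1.0, decay_tau=0.5)


class TestGenerateSeeg:
    PLAN = [("fc1", "FC"), ("ah1", "AH")]

    def test_full_involvement_zero_spread_simultaneous(self):
        rules = {"FC": RegionOnsetRule(1.0, 0.0, 0.0),
                 "AH": RegionOnsetRule(1.0, 0.0, 0.0)}
        cfg = GenConfig(sampling_rate=1000.0, duration=120, seed=2)
        rec, table = synthgen.generate_seeg_case(8, self.PLAN, rules, cfg)
        assert rec.n_channels == 2
        wide = table.pivot(index="seizure", columns="region",
                           values="onset_time")
        np.testing.assert_allclose(wide["FC"], wide["AH"])

    def test_fixed_lead_latency(self):
        rules = {"FC": RegionOnsetRule(1.0, 0.1, 0.0),
                 "AH": RegionOnsetRule(1.0, 0.0, 0.0)}
        cfg = GenConfig(sampling_rate=1000.0, duration=120, seed=3)
        _, table = synthgen.generate_seeg_case(6, self.PLAN, rules, cfg)
        wide = table.pivot(index="seizure", columns="region", values="onset_time")
        np.testing.assert_allclose(wide["FC"] - wide["AH"], 0.1)

    def test_involvement_probability_recovered_over_seeds(self):
        # 15/18 involvement probability -> mean fraction ~ 83% across seeds
        rules = {"FC": RegionOnsetRule(15.0 / 18.0, 0.1, 0.02),
                 "AH": RegionOnsetRule(1.0, 0.0, 0.0)}
        fracs = []
        for seed in range(30):
            cfg = GenConfig(sampling_rate=1000.0, duration=200, seed=seed)
            _, table = synthgen.generate_seeg_case(18, self.PLAN, rules, cfg)
            fc = table[table.region == "FC"]
            fracs.append(fc["onset_time"].notna().mean())
        assert np.mean(fracs) == pytest.approx(15.0 / 18.0, abs=0.05)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_seeg_case(
                1, [("fc1", "FC")], {"FC": RegionOnsetRule()}, GenConfig()
            )
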