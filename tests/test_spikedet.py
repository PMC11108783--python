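"""Spike-detector operators: filter response, thresholding, measurement,
template matching, artifact veto and Boolean combination."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictaloop import spikedet, synthgen
from ictaloop.core import Recording, robust_sd
from ictaloop.spikedet import (
    ArtifactCriteria,
    BooleanRule,
    SpikeEvent,
    combine_criteria,
)

from .reference import eval_rule_by_eval

FS = 500.0


def make_rec(x, fs=FS):
    return Recording(np.asarray(x, float)[None, :], fs)


class TestBandpassFilter:
    def test_constant_signal_zeroed(self):
        out = spikedet.bandpass_filter(make_rec(np.full(5000, 3.7)))
        assert np.max(np.abs(out.samples)) < 1e-6

    def test_band_center_preserved_low_freq_attenuated(self):
        t = np.arange(50000) / FS
        center = np.sqrt(5.0 * 40.0)  # geometric band center
        sig = np.sin(2 * np.pi * center * t)
        out = spikedet.bandpass_filter(make_rec(sig))
        mid = slice(5000, -5000)
        assert np.max(np.abs(out.samples[0][mid])) == pytest.approx(1.0, rel=0.05)

        low = np.sin(2 * np.pi * 0.5 * t)  # 0.1 x low edge
        out_low = spikedet.bandpass_filter(make_rec(low))
        assert np.max(np.abs(out_low.samples[0][mid])) < 0.1

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            spikedet.bandpass_filter(make_rec(np.zeros(100)), band=(5, 300))


class TestThresholdCrossings:
    def test_pure_noise_high_threshold_empty(self, rng):
        x = rng.normal(0, 1, 60000)
        events = spikedet.detect_threshold_crossings(make_rec(x), threshold=10)
        assert len(events) <= 1

    def test_single_inserted_waveform_detected_at_truth_time(self, rng):
        x = rng.normal(0, 1, 30000)
        wave, peak = synthgen.spike_waveform(0.04, 8.0, FS)
        t_true = 30.0
        synthgen._add_waveform(x, FS, t_true, wave, peak)
        events = spikedet.detect_threshold_crossings(make_rec(x), threshold=5)
        hits = [e for e in events if abs(e.time - t_true) <= 0.010]
        assert len(hits) == 1

    def test_refractory_suppresses_close_candidates(self):
        x = np.zeros(5000)
        wave, peak = synthgen.spike_waveform(0.02, 8.0, FS)
        x += 0.01 * np.sin(np.arange(5000))  # nonzero variance
        synthgen._add_waveform(x, FS, 5.0, wave, peak)
        synthgen._add_waveform(x, FS, 5.005, wave, peak)
        events = spikedet.detect_threshold_crossings(
            make_rec(x), threshold=5, refractory=0.2
        )
        assert len(events) == 1

    def test_zero_variance_gives_empty(self):
        assert spikedet.detect_threshold_crossings(make_rec(np.zeros(100))) == []

    def test_scale_invariance(self, rng):
        x = rng.normal(0, 1, 30000)
        wave, peak = synthgen.spike_waveform(0.04, 8.0, FS)
        for t in (10.0, 25.0, 40.0):
            synthgen._add_waveform(x, FS, t, wave, peak)
        e1 = spikedet.detect_threshold_crossings(make_rec(x))
        e2 = spikedet.detect_threshold_crossings(make_rec(1000.0 * x))
        assert [e.time for e in e1] == [e.time for e in e2]


class TestMeasureSpike:
    def test_triangle_fwhm_is_half_base(self):
        # symmetric triangular pulse, base 40 ms -> FWHM 20 ms
        base = int(0.040 * FS)
        tri = np.r_[np.linspace(0, 1, base // 2), np.linspace(1, 0, base // 2)]
        x = np.zeros(2000)
        x[1000 : 1000 + tri.size] = -tri
        amp, width = spikedet.measure_spike(
            x, FS, (1000 + base // 2) / FS, window=0.1, polarity="neg"
        )
        assert amp == pytest.approx(1.0, rel=0.05)
        assert width == pytest.approx(0.020, abs=0.004)

    def test_inserted_amplitude_recovered(self, rng):
        x = rng.normal(0, 1, 30000)
        wave, peak = synthgen.spike_waveform(0.04, 8.0, FS)
        synthgen._add_waveform(x, FS, 30.0, wave, peak)
        filt = spikedet.bandpass_filter(make_rec(x))
        sd = robust_sd(filt.samples[0])
        amp, _ = spikedet.measure_spike(filt.samples[0], FS, 30.0, polarity="neg")
        # 8-SD raw spike loses some energy in the band but stays prominent
        assert amp / sd > 8.0 * 0.5

    def test_flat_window_reports_zero(self):
        amp, width = spikedet.measure_spike(np.zeros(1000), FS, 1.0)
        assert amp == 0.0 and width == 0.0


class TestTemplateMatch:
    def test_identity_scores_one(self):
        wave, peak = synthgen.spike_waveform(0.04, 1.0, FS)
        x = np.zeros(2000)
        start = 900
        x[start : start + wave.size] = wave
        score = spikedet.template_match(x, FS, (start + peak) / FS, wave)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_negation_scores_minus_one(self):
        wave, peak = synthgen.spike_waveform(0.04, 1.0, FS)
        x = np.zeros(2000)
        start = 900
        x[start : start + wave.size] = -wave
        # symmetry of the correlation itself, so no jitter maximization
        score = spikedet.template_match(x, FS, (start + peak) / FS, wave,
                                        jitter=0.0)
        assert score == pytest.approx(-1.0, abs=1e-9)

    def test_noisy_spike_scores_high(self, rng):
        x = rng.normal(0, 1, 30000)
        wave, peak = synthgen.spike_waveform(0.04, 8.0, FS)
        synthgen._add_waveform(x, FS, 30.0, wave, peak)
        filt = spikedet.bandpass_filter(make_rec(x))
        tmpl = spikedet.filter_template(wave, FS, (5, 40), 4)
        score = spikedet.template_match(filt.samples[0], FS, 30.0, tmpl)
        assert score > 0.8

    def test_zero_variance_window_scores_zero(self):
        wave, _ = synthgen.spike_waveform(0.04, 1.0, FS)
        assert spikedet.template_match(np.zeros(2000), FS, 2.0, wave) == 0.0


class TestRejectArtifacts:
    def _events(self, times):
        return [SpikeEvent(time=t) for t in times]

    def test_no_artifacts_no_flags(self, rng):
        rec = make_rec(rng.normal(0, 1, 10000))
        events = spikedet.reject_artifacts(
            rec, self._events([5.0, 10.0]), ArtifactCriteria()
        )
        assert not any(e.flags["artifact"] for e in events)

    def test_clipping_segment_flags_nearby_events(self, rng):
        x = rng.normal(0, 1, 10000)
        x[5000:5100] = 50.0  # saturation plateau at t = 10.0-10.2 s
        rec = make_rec(x)
        crit = ArtifactCriteria(saturation_level=49.0, veto_pad=0.25)
        events = spikedet.reject_artifacts(
            rec, self._events([10.1, 10.4, 15.0]), crit
        )
        assert events[0].flags["artifact"]
        assert events[1].flags["artifact"]  # within pad of plateau end
        assert not events[2].flags["artifact"]

    def test_event_exactly_at_pad_boundary_flagged(self):
        x = np.zeros(10000)
        x[5000] = 100.0
        rec = make_rec(x)
        crit = ArtifactCriteria(saturation_level=99.0, veto_pad=0.25)
        events = spikedet.reject_artifacts(rec, self._events([10.25]), crit)
        assert events[0].flags["artifact"]  # closed boundary


class TestBooleanCombination:
    def test_single_flag_rule(self):
        events = [
            SpikeEvent(0.1, flags={"amplitude": True}),
            SpikeEvent(0.2, flags={"amplitude": False}),
        ]
        assert combine_criteria(events, "amplitude") == [events[0]]

    def test_four_event_truth_table_matches_hand_evaluation(self):
        rule = "amplitude AND NOT artifact"
        events = [
            SpikeEvent(0.1, flags={"amplitude": a, "artifact": b})
            for a in (True, False) for b in (True, False)
        ]
        accepted = combine_criteria(events, rule)
        assert [e.flags for e in accepted] == [{"amplitude": True, "artifact": False}]

    def test_undefined_flag_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            combine_criteria([SpikeEvent(0.1, flags={"a": True})], "a AND b")

    def test_malformed_expression_rejected(self):
        with pytest.raises(ValueError):
            BooleanRule("amplitude +")
        with pytest.raises(ValueError):
            BooleanRule("__import__('os')")

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.booleans(), b=st.booleans(), c=st.booleans(),
        expr=st.sampled_from([
            "a AND b", "a OR b", "NOT a", "NOT (a OR b)",
            "(NOT a) AND (NOT b)", "(a AND b) OR c",
            "a AND NOT (b OR c)", "NOT NOT a",
        ]),
    )
    def test_rule_matches_eval_oracle(self, a, b, c, expr):
        flags = {"a": a, "b": b, "c": c}
        assert BooleanRule(expr).evaluate(flags) == eval_rule_by_eval(expr, flags)

    def test_de_morgan_identity(self, rng):
        r1, r2 = BooleanRule("NOT (a OR b)"), BooleanRule("(NOT a) AND (NOT b)")
        for _ in range(32):
            flags = {"a": bool(rng.integers(2)), "b": bool(rng.integers(2))}
            assert r1.evaluate(flags) == r2.evaluate(flags)


class TestDetectSpikesPipeline:
    def test_sensitivity_and_false_rate_on_synthetic_session(self):
        cfg = synthgen.GenConfig(duration=300, seed=21, seizure_rate=0.03,
                                 seizure_min_gap=15, spike_amplitude=6.0)
        rec, truth = synthgen.generate_lfp(cfg)
        times = spikedet.event_times(spikedet.detect_spikes(rec))
        tt = truth.all_spike_times()
        matched = sum(np.min(np.abs(times - t)) <= 0.025 for t in tt)
        fp = sum(np.min(np.abs(tt - t)) > 0.025 for t in times)
        assert matched / tt.size >= 0.95
        assert fp / (cfg.duration / 60.0) <= 2.0

    def test_accepted_times_strictly_increasing_and_refractory_spaced(self):
        cfg = synthgen.GenConfig(duration=120, seed=4, seizure_rate=0.05,
                                 seizure_min_gap=15)
        rec, _ = synthgen.generate_lfp(cfg)
        crit = spikedet.default_criteria()
        times = spikedet.event_times(spikedet.detect_spikes(rec, crit))
        assert np.all(np.diff(times) > 0)
        assert np.all(np.diff(times) >= crit.refractory - 1e-9)

    def test_detection_invariant_to_signal_scaling(self):
        cfg = synthgen.GenConfig(duration=120, seed=6, seizure_rate=0.05,
                                 seizure_min_gap=15)
        rec, _ = synthgen.generate_lfp(cfg)
        t1 = spikedet.event_times(spikedet.detect_spikes(rec))
        rec.samples *= 250.0
        t2 = spikedet.event_times(spikedet.detect_spikes(rec))
        np.testing.assert_array_equal(t1, t2)
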