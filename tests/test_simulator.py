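import numpy as np
import pytest
from scipy import stats

from rtpeth.simulator import (
    ArtifactSpec,
    BehavioralResponseSpec,
    EvokedSpec,
    SimulationConfig,
    StimulusSpec,
    UnitSpec,
    artifact_template,
    generate_behavioral_session,
    generate_stimulus_train,
    iter_packets,
    simulate_recording,
    spike_template,
    stream_packets,
)
from rtpeth.spike_detect import ThresholdConfig, detect_spikes_continuous
from rtpeth.stream_protocol import SamplePacket, replay_stream
from rtpeth.units import ms_to_samples

FS = 30_000.0


class TestStimulusTrain:
    def test_two_full_cycles(self):
        # 20 Hz, 2 s ON / 3 s OFF, 10 s -> 2 ON epochs x 40 pulses
        onsets = generate_stimulus_train(StimulusSpec(), 10.0)
        assert onsets.size == 80

    def test_single_on_epoch(self):
        assert generate_stimulus_train(StimulusSpec(), 2.0).size == 40

    def test_zero_on_time(self):
        assert generate_stimulus_train(StimulusSpec(on_s=0.0), 10.0).size == 0

    def test_no_pulses_during_off_epochs(self):
        onsets = generate_stimulus_train(StimulusSpec(), 10.0)
        phase = onsets % 5.0  # cycle length 5 s
        assert np.all(phase < 2.0)

    def test_pulse_rate_within_epoch(self):
        onsets = generate_stimulus_train(StimulusSpec(), 2.0)
        assert np.allclose(np.diff(onsets), 0.05)

    def test_non_integral_pulse_count_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(pulse_rate_hz=7.0, on_s=0.5)


class TestSimulateRecording:
    def test_silent_config_all_zero(self):
        config = SimulationConfig(n_channels=2, duration_s=0.1, seed=0, noise_sd_uv=0.0)
        rec = simulate_recording(config)
        assert not rec.data.any()

    def test_seed_reproducibility(self, tagged_config):
        a = simulate_recording(tagged_config(seed=5))
        b = simulate_recording(tagged_config(seed=5))
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(
            a.ground_truth.units[0].evoked, b.ground_truth.units[0].evoked
        )

    def test_different_seeds_differ(self, tagged_config):
        a = simulate_recording(tagged_config(seed=5))
        b = simulate_recording(tagged_config(seed=6))
        assert not np.array_equal(a.data, b.data)

    def test_evoked_count_within_binomial_bounds(self, tagged_config):
        # probability 0.8 per pulse; 10 s of 20 Hz 2s/3s trains -> 80 pulses
        rec = simulate_recording(tagged_config(seed=2))
        n_pulses = rec.ground_truth.pulse_onsets.size
        assert n_pulses == 80
        n_evoked = rec.ground_truth.units[0].evoked.size
        lo, hi = stats.binom.ppf([0.005, 0.995], n_pulses, 0.8)
        assert lo <= n_evoked <= hi

    def test_evoked_latency_within_jitter_bounds(self, tagged_config):
        rec = simulate_recording(tagged_config(seed=3))
        pulses = rec.ground_truth.pulse_onsets
        for ts in rec.ground_truth.units[0].evoked:
            latency_ms = np.min(np.abs(ts - pulses)) * 1000.0 / FS - 3.0
            assert abs(latency_ms) <= 4 * 0.5 + 0.1  # +- 4 x jitter (+ rounding)

    def test_peth_peak_bin(self, tagged_config):
        rec = simulate_recording(tagged_config(seed=4, noise_sd_uv=0.0))
        rel_ms = []
        pulses = rec.ground_truth.pulse_onsets
        for ts in rec.ground_truth.units[0].evoked:
            d = (ts - pulses) * 1000.0 / FS
            rel_ms.append(d[(d >= 0)].min())
        counts, _ = np.histogram(rel_ms, bins=np.arange(0, 11))
        assert 2 <= int(np.argmax(counts)) < 4

    def test_artifact_linear_in_intensity(self):
        def rec_at(intensity):
            return simulate_recording(
                SimulationConfig(
                    n_channels=1,
                    duration_s=5.0,
                    seed=0,
                    noise_sd_uv=0.0,
                    artifact=ArtifactSpec(intensity=intensity),
                    stimulus=StimulusSpec(),
                )
            )

        full = rec_at(1.0).data.min()
        half = rec_at(0.5).data.min()
        assert full < 0
        assert np.isclose(half / full, 0.5, rtol=1e-5)

    def test_zero_intensity_no_artifact(self):
        rec = simulate_recording(
            SimulationConfig(
                n_channels=1,
                duration_s=5.0,
                seed=0,
                noise_sd_uv=0.0,
                artifact=ArtifactSpec(intensity=0.0),
                stimulus=StimulusSpec(),
            )
        )
        assert not rec.data.any()

    def test_artifact_spike_dissociation_across_intensities(self):
        """Artifact amplitude tracks intensity; evoked-spike amplitude is
        all-or-none and stays constant."""
        def build(intensity):
            return simulate_recording(
                SimulationConfig(
                    n_channels=2,
                    duration_s=5.0,
                    seed=1,
                    noise_sd_uv=0.0,
                    units=[
                        UnitSpec(
                            channels={0: 1.0},
                            background_rate_hz=0.0,
                            evoked=EvokedSpec(probability=1.0, latency_ms=3.0, jitter_ms=0.0),
                        )
                    ],
                    artifact=ArtifactSpec(intensity=intensity, channels=(1,)),
                    stimulus=StimulusSpec(),
                )
            )

        amplitudes = {}
        for intensity in (0.25, 0.5, 1.0):
            rec = build(intensity)
            amplitudes[intensity] = (rec.data[1].min(), rec.data[0].min())
        art = {k: v[0] for k, v in amplitudes.items()}
        spk = {k: v[1] for k, v in amplitudes.items()}
        assert np.isclose(art[0.25] / art[1.0], 0.25, rtol=1e-5)
        assert np.isclose(art[0.5] / art[1.0], 0.5, rtol=1e-5)
        assert spk[0.25] == spk[0.5] == spk[1.0] == pytest.approx(-100.0, abs=1e-3)

    def test_overlapping_insertions_sum(self):
        template = spike_template(FS, -100.0)
        config = SimulationConfig(
            n_channels=1,
            duration_s=0.1,
            seed=0,
            noise_sd_uv=0.0,
            units=[
                UnitSpec(channels={0: 1.0}, background_rate_hz=0.0,
                         evoked=EvokedSpec(probability=1.0, latency_ms=3.0, jitter_ms=0.0)),
                UnitSpec(channels={0: 1.0}, background_rate_hz=0.0,
                         evoked=EvokedSpec(probability=1.0, latency_ms=3.0, jitter_ms=0.0)),
            ],
            stimulus=StimulusSpec(on_s=0.1, off_s=0.0, pulse_rate_hz=10.0),
        )
        rec = simulate_recording(config)
        assert np.isclose(rec.data.min(), 2 * template.min(), atol=1e-3)

    def test_background_suppressed_near_evoked(self, tagged_config):
        rec = simulate_recording(tagged_config(seed=8))
        gt = rec.ground_truth.units[0]
        for ev in gt.evoked:
            assert np.all(np.abs(gt.spontaneous - ev) > ms_to_samples(1.0, FS) - 1)

    def test_seed_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            SimulationConfig(n_channels=1, duration_s=1.0, seed=None)


class TestThresholdSweep:
    def test_sensitivity_monotone_in_threshold_magnitude(self):
        config = SimulationConfig(
            n_channels=1,
            duration_s=5.0,
            seed=13,
            noise_sd_uv=15.0,
            units=[UnitSpec(channels={0: 1.0}, background_rate_hz=20.0,
                            peak_uv=-100.0, refractory_ms=3.0)],
        )
        rec = simulate_recording(config)
        truth = rec.ground_truth.units[0].all_spikes
        tol = ms_to_samples(1.0, FS)
        sensitivities = []
        for threshold in (-40.0, -60.0, -80.0, -100.0, -120.0):
            det = detect_spikes_continuous(
                rec.data[0], FS, ThresholdConfig(default_threshold=threshold)
            )
            ts = np.array([s.timestamp for s in det])
            hits = sum(np.any(np.abs(ts - t) <= tol) for t in truth) if ts.size else 0
            sensitivities.append(hits / truth.size)
        assert all(a >= b for a, b in zip(sensitivities, sensitivities[1:]))
        assert sensitivities[0] > 0.9
        assert sensitivities[-1] < 0.5


class TestStreamPackets:
    def test_tiling_arithmetic(self, tmp_path):
        config = SimulationConfig(n_channels=1, duration_s=2.0, seed=0, noise_sd_uv=5.0)
        rec = simulate_recording(config)
        path = stream_packets(rec, tmp_path / "s.jsonl", packet_samples=640)
        packets = [p for p in replay_stream(path) if isinstance(p, SamplePacket)]
        assert len(packets) == -(-60_000 // 640)  # ceil
        assert packets[-1].n_samples == 60_000 - 640 * (len(packets) - 1)

    def test_round_trip_exact(self, tmp_path, tagged_config):
        rec = simulate_recording(tagged_config(seed=1, duration_s=1.0))
        path = stream_packets(rec, tmp_path / "s.jsonl", packet_samples=977)
        chunks = [p.samples for p in replay_stream(path) if isinstance(p, SamplePacket)]
        assert np.array_equal(np.concatenate(chunks, axis=1), rec.data)

    def test_events_interleaved_at_correct_timestamps(self, tagged_config):
        rec = simulate_recording(tagged_config(seed=1, duration_s=5.0))
        packets = list(iter_packets(rec, packet_samples=640))
        events = [p for p in packets if not isinstance(p, SamplePacket)]
        expected = rec.ground_truth.ttl_events
        assert [e.timestamp for e in events] == [e.timestamp for e in expected]

    def test_exclude_events(self, tagged_config):
        rec = simulate_recording(tagged_config(seed=1, duration_s=5.0))
        packets = list(iter_packets(rec, include_events=False))
        assert all(isinstance(p, SamplePacket) for p in packets)


class TestBehavioralSession:
    def test_punishment_selective_response(self):
        from rtpeth.peth import PethAccumulator
        from rtpeth.offline_validation import light_response_criterion
        from rtpeth.spike_detect import DetectedSpike

        session = generate_behavioral_session(
            n_trials=100,
            response=BehavioralResponseSpec(label="punishment", probability=0.9,
                                            latency_ms=5.0, jitter_ms=1.0, n_spikes=3),
            seed=21,
            noise_sd_uv=0.0,
            background_rate_hz=0.5,
        )
        gt = session.recording.ground_truth.units[0]
        spikes = [
            DetectedSpike(0, 0, -100.0, 0, 0, timestamp=int(t)) for t in gt.all_spikes
        ]
        results = {}
        for label, events in session.events_by_label.items():
            acc = PethAccumulator(1, pre_ms=50, post_ms=50, sampling_rate=FS)
            for event in events:
                acc.update(spikes, event)
            results[label] = light_response_criterion(
                acc.counts[0], acc.edges, acc.n_events, latency_window_ms=(0, 30)
            )
        assert results["punishment"].outcome == "positive"
        assert results["reward"].outcome == "negative"

    def test_unresponsive_unit_flat_everywhere(self):
        from rtpeth.peth import PethAccumulator
        from rtpeth.offline_validation import light_response_criterion
        from rtpeth.spike_detect import DetectedSpike

        # background rate 0: histogram is exactly flat (all zero); a sparse
        # Poisson train can legitimately exceed a 3-SD max-bin criterion
        session = generate_behavioral_session(
            n_trials=60,
            response=BehavioralResponseSpec(probability=0.0),
            seed=22,
            noise_sd_uv=0.0,
            background_rate_hz=0.0,
        )
        gt = session.recording.ground_truth.units[0]
        spikes = [
            DetectedSpike(0, 0, -100.0, 0, 0, timestamp=int(t)) for t in gt.all_spikes
        ]
        for events in session.events_by_label.values():
            acc = PethAccumulator(1, pre_ms=50, post_ms=50, sampling_rate=FS)
            for event in events:
                acc.update(spikes, event)
            res = light_response_criterion(
                acc.counts[0], acc.edges, acc.n_events, latency_window_ms=(0, 30)
            )
            assert res.outcome == "negative"

    def test_trial_throughput(self):
        # a full-size session (254 trials) generates quickly at desk scale
        import time

        start = time.time()
        session = generate_behavioral_session(n_trials=254, seed=1, noise_sd_uv=5.0)
        assert time.time() - start < 60
        n_events = sum(len(v) for v in session.events_by_label.values())
        assert n_events == 254

    def test_bad_trial_count(self):
        with pytest.raises(ValueError):
            generate_behavioral_session(n_trials=0)


class TestTemplates:
    def test_spike_template_shape(self):
        t = spike_template(FS, -100.0)
        assert t.size == ms_to_samples(1.3, FS)
        assert t.min() == pytest.approx(-100.0, abs=1e-3)
        assert t.max() > 0  # biphasic: positive rebound present

    def test_artifact_template_w_shape(self):
        t = artifact_template(FS, -300.0)
        assert t.size == ms_to_samples(2.0, FS)
        assert t.min() == pytest.approx(-300.0, abs=1e-3)
        # two negative lobes: the trough between them is shallower than both
        mid = t.size // 2
        assert t[:mid].min() < t[mid] < 0 or t[mid:].min() < t[mid] < 0
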