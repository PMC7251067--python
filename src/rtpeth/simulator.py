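"""Synthetic multichannel extracellular recordings with ground truth.

Generates Gaussian background noise, spontaneous and light-evoked unit
spikes (biphasic template, all-or-none amplitude), photostimulation
artifacts (W-shaped template whose amplitude scales linearly with
stimulation intensity, unlike real spikes), TTL stimulus trains with an
ON/OFF duty cycle, and behavioral event sessions.  Every generator is a
pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .stream_protocol import Packet, SamplePacket, TriggerEvent, write_stream
from .units import ms_to_samples

DEFAULT_SAMPLING_RATE = 30_000.0

SPIKE_TEMPLATE_MS = 1.3
ARTIFACT_TEMPLATE_MS = 2.0


def spike_template(sampling_rate: float, peak_uv: float = -100.0) -> np.ndarray:
    """Biphasic extracellular spike: sharp negative main phase followed
    by a smaller, slower positive rebound; 1.3 ms support."""
    n = ms_to_samples(SPIKE_TEMPLATE_MS, sampling_rate)
    t = np.arange(n) / sampling_rate * 1000.0  # ms
    main = -np.exp(-(((t - 0.3) / 0.12) ** 2))
    rebound = 0.35 * np.exp(-(((t - 0.75) / 0.25) ** 2))
    w = main + rebound
    # negative peak_uv keeps the negative-going main phase; positive flips it
    return (w / np.abs(w).max() * abs(peak_uv) * (1.0 if peak_uv < 0 else -1.0)).astype(
        np.float32
    )


def artifact_template(sampling_rate: float, peak_uv: float = -300.0) -> np.ndarray:
    """W-shaped photostimulation artifact: two negative lobes, 2 ms
    support, locked to the pulse onset."""
    n = ms_to_samples(ARTIFACT_TEMPLATE_MS, sampling_rate)
    t = np.arange(n) / sampling_rate * 1000.0  # ms
    w = -(np.exp(-(((t - 0.4) / 0.18) ** 2)) + np.exp(-(((t - 1.3) / 0.22) ** 2)))
    return (w / np.abs(w).max() * abs(peak_uv)).astype(np.float32)


@dataclass(frozen=True)
class EvokedSpec:
    """Per-pulse spiking response of a light-sensitive unit."""

    probability: float = 0.8
    latency_ms: float = 3.0
    jitter_ms: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0, 1], got {self.probability}")
        if self.jitter_ms < 0:
            raise ValueError(f"jitter_ms must be >= 0, got {self.jitter_ms}")


@dataclass(frozen=True)
class UnitSpec:
    """One simulated unit: fixed-amplitude template on a channel subset.

    ``channels`` maps 0-based channel indices to per-channel gains (a
    tetrode sees the same spike at different amplitudes).  The template
    amplitude never depends on stimulation intensity -- spikes are
    all-or-none.
    """

    channels: dict[int, float]
    background_rate_hz: float = 2.0
    evoked: EvokedSpec | None = None
    peak_uv: float = -100.0
    refractory_ms: float = 2.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("unit must project to at least one channel")
        if self.background_rate_hz < 0:
            raise ValueError("background_rate_hz must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Pulse-locked artifact whose amplitude scales linearly with
    intensity; intensity 0 produces no artifact at all."""

    intensity: float = 1.0
    peak_uv: float = -300.0
    channels: tuple[int, ...] | None = None  # None = all channels

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity must be in [0, 1], got {self.intensity}")


@dataclass(frozen=True)
class StimulusSpec:
    """Pulse train with a duty cycle: 1 ms pulses at 20 Hz, 2 s ON then
    3 s OFF, repeating from t=0 (the defaults)."""

    pulse_rate_hz: float = 20.0
    pulse_width_ms: float = 1.0
    on_s: float = 2.0
    off_s: float = 3.0

    def __post_init__(self) -> None:
        if self.pulse_rate_hz <= 0:
            raise ValueError("pulse_rate_hz must be positive")
        if self.on_s < 0 or self.off_s < 0:
            raise ValueError("on_s and off_s must be >= 0")
        n_pulses = self.pulse_rate_hz * self.on_s
        if abs(n_pulses - round(n_pulses)) > 1e-9:
            raise ValueError(
                f"pulse_rate_hz x on_s must be integral, got {n_pulses}"
            )


@dataclass
class SimulationConfig:
    n_channels: int
    duration_s: float
    seed: int
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    noise_sd_uv: float = 10.0
    units: list[UnitSpec] = field(default_factory=list)
    artifact: ArtifactSpec | None = None
    stimulus: StimulusSpec | None = None
    trigger_channel: int = 1

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class UnitGroundTruth:
    spontaneous: np.ndarray  # sample timestamps
    evoked: np.ndarray

    @property
    def all_spikes(self) -> np.ndarray:
        return np.sort(np.concatenate((self.spontaneous, self.evoked)))


@dataclass
class GroundTruth:
    units: list[UnitGroundTruth]
    artifact_onsets: np.ndarray
    ttl_events: list[TriggerEvent]

    @property
    def pulse_onsets(self) -> np.ndarray:
        return np.array(
            [e.timestamp for e in self.ttl_events if e.edge == "rising"], dtype=np.int64
        )


@dataclass
class SimulatedRecording:
    data: np.ndarray  # [channel][sample], microvolts
    ground_truth: GroundTruth
    config: SimulationConfig

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def generate_stimulus_train(spec: StimulusSpec, duration_s: float) -> np.ndarray:
    """Pulse-onset times (seconds) for alternating ON/OFF epochs.

    Epochs alternate ON then OFF starting at t=0; during each ON epoch
    pulses fire at ``pulse_rate_hz``.  Only onsets strictly inside
    ``[0, duration_s)`` are returned.
    """
    if spec.on_s == 0:
        return np.empty(0)
    cycle = spec.on_s + spec.off_s
    period = 1.0 / spec.pulse_rate_hz
    n_per_epoch = int(round(spec.pulse_rate_hz * spec.on_s))
    onsets = []
    epoch_start = 0.0
    while epoch_start < duration_s:
        for k in range(n_per_epoch):
            t = epoch_start + k * period
            if t < duration_s and t < epoch_start + spec.on_s:
                onsets.append(t)
        epoch_start += cycle
    return np.array(onsets)


def _poisson_train(
    rng: np.random.Generator, rate_hz: float, duration_s: float, refractory_s: float
) -> np.ndarray:
    """Homogeneous Poisson spike times (seconds) with a dead time."""
    if rate_hz <= 0:
        return np.empty(0)
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if times:
            t = max(t, times[-1] + refractory_s)
        if t >= duration_s:
            break
        times.append(t)
    return np.array(times)


def _insert(data: np.ndarray, channel: int, start: int, waveform: np.ndarray) -> None:
    """Add a waveform at ``start``; overlaps sum, edges are clipped."""
    n = data.shape[1]
    lo = max(start, 0)
    hi = min(start + waveform.size, n)
    if hi <= lo:
        return
    data[channel, lo:hi] += waveform[lo - start : hi - start]


def simulate_recording(config: SimulationConfig) -> SimulatedRecording:
    """Render the configured scene into a continuous voltage matrix.

    signal = Gaussian noise + sum of unit templates at ground-truth
    times (with per-channel gains) + artifact template at every pulse,
    scaled by intensity.  The same (config, seed) always yields a
    bit-identical matrix; the ground truth used for rendering is
    returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = int(round(config.duration_s * fs))
    if config.noise_sd_uv > 0:
        data = rng.normal(0.0, config.noise_sd_uv, (config.n_channels, n_samples))
        data = data.astype(np.float32)
    else:
        data = np.zeros((config.n_channels, n_samples), dtype=np.float32)

    # stimulus train and its TTL edges
    ttl_events: list[TriggerEvent] = []
    pulse_onset_samples = np.empty(0, dtype=np.int64)
    if config.stimulus is not None:
        onsets_s = generate_stimulus_train(config.stimulus, config.duration_s)
        pulse_onset_samples = np.round(onsets_s * fs).astype(np.int64)
        width = ms_to_samples(config.stimulus.pulse_width_ms, fs)
        for onset in pulse_onset_samples:
            ttl_events.append(
                TriggerEvent(config.trigger_channel, int(onset), "rising")
            )
            off = int(onset) + width
            if off < n_samples:
                ttl_events.append(
                    TriggerEvent(config.trigger_channel, off, "falling")
                )

    # artifact: amplitude strictly linear in intensity, zero at zero
    artifact_onsets = np.empty(0, dtype=np.int64)
    if config.artifact is not None and config.artifact.intensity > 0:
        template = artifact_template(fs, config.artifact.peak_uv) * config.artifact.intensity
        channels = (
            range(config.n_channels)
            if config.artifact.channels is None
            else config.artifact.channels
        )
        artifact_onsets = pulse_onset_samples.copy()
        for onset in artifact_onsets:
            for ch in channels:
                _insert(data, ch, int(onset), template)

    # units
    unit_truths: list[UnitGroundTruth] = []
    for unit in config.units:
        template = spike_template(fs, unit.peak_uv)
        refractory_s = unit.refractory_ms / 1000.0

        evoked_s = np.empty(0)
        if unit.evoked is not None and pulse_onset_samples.size:
            fired = rng.random(pulse_onset_samples.size) < unit.evoked.probability
            jitter = rng.normal(0.0, unit.evoked.jitter_ms, int(fired.sum()))
            if unit.evoked.jitter_ms > 0:
                jitter = np.clip(jitter, -4 * unit.evoked.jitter_ms, 4 * unit.evoked.jitter_ms)
            latencies_ms = unit.evoked.latency_ms + jitter
            evoked_s = pulse_onset_samples[fired] / fs + latencies_ms / 1000.0
            evoked_s = evoked_s[(evoked_s >= 0) & (evoked_s < config.duration_s)]

        spont_s = _poisson_train(rng, unit.background_rate_hz, config.duration_s, refractory_s)
        if evoked_s.size:
            # suppress background within +-1 ms of an evoked spike so
            # ground-truth counting stays unambiguous
            keep = np.ones(spont_s.size, dtype=bool)
            for t in evoked_s:
                keep &= np.abs(spont_s - t) > 1e-3
            spont_s = spont_s[keep]

        spont_ts = np.round(spont_s * fs).astype(np.int64)
        evoked_ts = np.round(np.sort(evoked_s) * fs).astype(np.int64)
        for ts in np.concatenate((spont_ts, evoked_ts)):
            for ch, gain in unit.channels.items():
                _insert(data, ch, int(ts), template * gain)
        unit_truths.append(UnitGroundTruth(spontaneous=spont_ts, evoked=evoked_ts))

    ttl_events.sort(key=lambda e: e.timestamp)
    return SimulatedRecording(
        data=data,
        ground_truth=GroundTruth(
            units=unit_truths,
            artifact_onsets=artifact_onsets,
            ttl_events=ttl_events,
        ),
        config=config,
    )


def iter_packets(
    recording: SimulatedRecording,
    packet_samples: int = 640,
    include_events: bool = True,
) -> Iterator[Packet]:
    """Tile the recording into sample packets, interleaving TTL events.

    Each event is emitted immediately after the packet that covers its
    timestamp, mimicking a live stream where event notifications follow
    the data they refer to.
    """
    if packet_samples < 1:
        raise ValueError("packet_samples must be >= 1")
    events = sorted(recording.ground_truth.ttl_events, key=lambda e: e.timestamp) \
        if include_events else []
    ev_idx = 0
    n = recording.n_samples
    fs = recording.config.sampling_rate
    for start in range(0, n, packet_samples):
        stop = min(start + packet_samples, n)
        yield SamplePacket(
            start_timestamp=start,
            samples=recording.data[:, start:stop],
            sampling_rate=fs,
        )
        while ev_idx < len(events) and events[ev_idx].timestamp < stop:
            yield events[ev_idx]
            ev_idx += 1
    while ev_idx < len(events):
        yield events[ev_idx]
        ev_idx += 1


def stream_packets(
    recording: SimulatedRecording,
    path: str | Path,
    packet_samples: int = 640,
    include_events: bool = True,
) -> Path:
    """Write the recording as a JSON-lines stream file (round-trips
    bit-exactly through replay)."""
    path = Path(path)
    write_stream(path, iter_packets(recording, packet_samples, include_events))
    return path


# ---------------------------------------------------------------------------
# behavioral sessions


@dataclass(frozen=True)
class BehavioralResponseSpec:
    """A unit that fires a short-latency burst after one event label."""

    label: str = "punishment"
    probability: float = 0.9
    latency_ms: float = 15.0
    jitter_ms: float = 5.0
    n_spikes: int = 3


@dataclass
class BehavioralSession:
    recording: SimulatedRecording
    events_by_label: dict[str, list[TriggerEvent]]
    responsive_trials: np.ndarray  # timestamps of trials that actually responded


def generate_behavioral_session(
    n_trials: int,
    response: BehavioralResponseSpec | None = None,
    seed: int = 0,
    n_channels: int = 4,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    noise_sd_uv: float = 10.0,
    inter_trial_s: float = 1.0,
    labels: Sequence[str] = ("reward", "punishment"),
    label_channels: dict[str, int] | None = None,
    background_rate_hz: float = 2.0,
) -> BehavioralSession:
    """Simulate a session with two behavioral TTL channels.

    Trials alternate between the two labels; the configured unit fires
    a burst after events of ``response.label`` only, so a PETH aligned
    to that label is positive while the other label's PETH stays flat.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if response is None:
        response = BehavioralResponseSpec()
    if label_channels is None:
        label_channels = {label: i + 1 for i, label in enumerate(labels)}
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    duration_s = (n_trials + 1) * inter_trial_s

    trial_labels = [labels[i % len(labels)] for i in range(n_trials)]
    trial_times_s = (np.arange(n_trials) + 0.5) * inter_trial_s

    base_config = SimulationConfig(
        n_channels=n_channels,
        duration_s=duration_s,
        seed=seed,
        sampling_rate=fs,
        noise_sd_uv=noise_sd_uv,
        units=[
            UnitSpec(
                channels={c: 1.0 - 0.1 * c for c in range(n_channels)},
                background_rate_hz=background_rate_hz,
            )
        ],
    )
    recording = simulate_recording(base_config)

    # overlay the event-locked bursts on top of the spontaneous unit
    template = spike_template(fs, base_config.units[0].peak_uv)
    evoked_ts: list[int] = []
    responsive_trials: list[int] = []
    events_by_label: dict[str, list[TriggerEvent]] = {label: [] for label in labels}
    for label, t_s in zip(trial_labels, trial_times_s):
        ts = int(round(t_s * fs))
        events_by_label[label].append(TriggerEvent(label_channels[label], ts, "rising"))
        if label == response.label and rng.random() < response.probability:
            responsive_trials.append(ts)
            for k in range(response.n_spikes):
                lat_ms = response.latency_ms + k * 4.0 + rng.normal(0, response.jitter_ms)
                lat_ms = max(lat_ms, 0.5)
                spike_ts = ts + ms_to_samples(lat_ms, fs)
                evoked_ts.append(spike_ts)
                for ch, gain in base_config.units[0].channels.items():
                    _insert(recording.data, ch, spike_ts, template * gain)

    recording.ground_truth.units[0].evoked = np.array(sorted(evoked_ts), dtype=np.int64)
    all_events = [e for evs in events_by_label.values() for e in evs]
    all_events.sort(key=lambda e: e.timestamp)
    recording.ground_truth.ttl_events.extend(all_events)
    recording.ground_truth.ttl_events.sort(key=lambda e: e.timestamp)
    return BehavioralSession(
        recording=recording,
        events_by_label=events_by_label,
        responsive_trials=np.array(responsive_trials, dtype=np.int64),
    )
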