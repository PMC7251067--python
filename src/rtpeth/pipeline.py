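"""End-to-end chains wiring the modules together.

``run_online`` emulates the live path: packets -> ring buffer ->
event-aligned windows -> threshold detection -> PETH accumulation.
``run_offline`` is the post-hoc path: zero-phase band-pass filtering of
the full recording, whole-trace detection per wire, tetrode-wide merge
with largest-spike censoring, then a cross-correlation PETH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .collector import Collector, RoiWindow
from .offline_validation import (
    FilterSpec,
    LightResponseResult,
    bandpass_filter,
    light_response_criterion,
    merge_and_censor,
)
from .peth import PethAccumulator, peth_by_crosscorrelation
from .spike_detect import (
    DetectedSpike,
    ThresholdConfig,
    detect_spikes,
    detect_spikes_continuous,
)
from .stream_protocol import Packet, TriggerEvent


@dataclass
class OnlineResult:
    accumulator: PethAccumulator
    spikes: list[DetectedSpike] = field(default_factory=list)
    events: list[TriggerEvent] = field(default_factory=list)
    stale_events: int = 0

    def criterion(self, channel: int = None, **kwargs) -> LightResponseResult:
        """Light-response judgment on the summed (or one channel's) PETH."""
        acc = self.accumulator
        counts = acc.counts.sum(axis=0) if channel is None else acc.counts[channel]
        return light_response_criterion(counts, acc.edges, acc.n_events, **kwargs)


def run_online(
    packets: Iterable[Packet],
    n_channels: int,
    sampling_rate: float = 30_000.0,
    trigger_channel: int = 1,
    roi: RoiWindow | None = None,
    threshold: ThresholdConfig | None = None,
    bin_width_ms: float = 1.0,
) -> OnlineResult:
    """Stream packets through the live detection + PETH chain."""
    roi = roi or RoiWindow()
    threshold = threshold or ThresholdConfig()
    collector = Collector(
        n_channels=n_channels,
        sampling_rate=sampling_rate,
        trigger_channel=trigger_channel,
        roi=roi,
    )
    acc = PethAccumulator(
        n_channels=n_channels,
        pre_ms=roi.pre_ms,
        post_ms=roi.post_ms,
        bin_width_ms=bin_width_ms,
        sampling_rate=sampling_rate,
    )
    result = OnlineResult(accumulator=acc)

    def handle(windows) -> None:
        for window in windows:
            spikes = detect_spikes(window, threshold)
            acc.update(spikes, window.event)
            result.spikes.extend(spikes)
            result.events.append(window.event)

    for packet in packets:
        collector.process_packet(packet)
        handle(collector.ready_windows())
    handle(collector.flush())
    result.stale_events = collector.stale_events
    return result


@dataclass
class OfflineResult:
    spikes: list[DetectedSpike]
    lags_ms: np.ndarray
    counts: np.ndarray
    n_events: int

    def criterion(self, **kwargs) -> LightResponseResult:
        edges = np.append(self.lags_ms, self.lags_ms[-1] + (self.lags_ms[1] - self.lags_ms[0]))
        return light_response_criterion(self.counts, edges, self.n_events, **kwargs)


def run_offline(
    data: np.ndarray,
    sampling_rate: float,
    event_timestamps: np.ndarray,
    tetrode_channels: Iterable[int] | None = None,
    threshold: ThresholdConfig | None = None,
    filter_spec: FilterSpec | None = None,
    censor_ms: float = 0.75,
    max_lag_ms: int = 50,
) -> OfflineResult:
    """Post-hoc chain over one tetrode of a full-length recording."""
    threshold = threshold or ThresholdConfig()
    filter_spec = filter_spec or FilterSpec()
    data = np.atleast_2d(np.asarray(data))
    channels = list(tetrode_channels) if tetrode_channels is not None else list(
        range(data.shape[0])
    )
    filtered = bandpass_filter(data[channels], filter_spec, sampling_rate)

    per_wire: list[list[DetectedSpike]] = []
    for i, ch in enumerate(channels):
        spikes = detect_spikes_continuous(filtered[i], sampling_rate, threshold)
        # re-tag with the recording channel index
        per_wire.append(
            [
                DetectedSpike(
                    channel=ch,
                    peak_index=s.peak_index,
                    peak_amplitude=s.peak_amplitude,
                    excursion_start=s.excursion_start,
                    excursion_end=s.excursion_end,
                    timestamp=s.timestamp,
                )
                for s in spikes
            ]
        )
    merged = merge_and_censor(per_wire, censor_ms, sampling_rate)

    event_timestamps = np.asarray(event_timestamps)
    spike_ms = np.array([s.timestamp for s in merged]) * 1000.0 / sampling_rate
    event_ms = event_timestamps * 1000.0 / sampling_rate
    lags, counts = peth_by_crosscorrelation(spike_ms, event_ms, 1.0, max_lag_ms)
    return OfflineResult(
        spikes=merged, lags_ms=lags, counts=counts, n_events=len(event_timestamps)
    )
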