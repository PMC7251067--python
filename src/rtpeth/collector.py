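"""Bounded sample history, event registry and event-aligned extraction.

The :class:`RingBuffer` keeps the most recent ``capacity_samples`` of
each channel.  The :class:`Collector` feeds it from a packet stream,
queues rising-edge trigger events and releases an
:class:`AlignedWindow` per event once the buffer covers the full
region of interest (ROI) after the event.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .stream_protocol import Packet, SamplePacket, TriggerEvent
from .units import ms_to_samples

logger = logging.getLogger(__name__)

DEFAULT_CAPACITY_SECONDS = 10.0


class ChannelCountMismatchError(ValueError):
    """Packet channel count differs from the buffer's configuration."""


class StaleEventError(LookupError):
    """The requested window precedes the retained history."""


@dataclass(frozen=True)
class RoiWindow:
    """Time window around a trigger event, in milliseconds."""

    pre_ms: float = 20.0
    post_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.pre_ms < 0:
            raise ValueError(f"pre_ms must be >= 0, got {self.pre_ms}")
        if self.post_ms <= 0:
            raise ValueError(f"post_ms must be > 0, got {self.post_ms}")

    def pre_samples(self, sampling_rate: float) -> int:
        return ms_to_samples(self.pre_ms, sampling_rate)

    def post_samples(self, sampling_rate: float) -> int:
        return ms_to_samples(self.post_ms, sampling_rate)

    def n_samples(self, sampling_rate: float) -> int:
        # per-boundary rounding, summed -- see ms_to_samples
        return self.pre_samples(sampling_rate) + self.post_samples(sampling_rate)


@dataclass
class AlignedWindow:
    """Samples covering ``[event - pre, event + post)`` for one event.

    ``t0_offset`` is the index of the sample at the event time;
    ``start_timestamp`` the absolute sample index of column 0.
    """

    event: TriggerEvent
    samples: np.ndarray  # [channel][sample]
    t0_offset: int
    start_timestamp: int
    sampling_rate: float

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


class RingBuffer:
    """Per-channel circular history of the most recent samples.

    The retrievable span is exactly the most recent
    ``min(written, capacity)`` samples; appending past capacity evicts
    the oldest data.  Timestamp gaps between packets are zero-filled
    and logged so analysis can continue over a lossy stream.
    """

    def __init__(
        self,
        n_channels: int,
        capacity_samples: int,
        sampling_rate: float = 30_000.0,
    ):
        if n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if capacity_samples < 1:
            raise ValueError("capacity_samples must be >= 1")
        self.n_channels = int(n_channels)
        self.capacity_samples = int(capacity_samples)
        self.sampling_rate = float(sampling_rate)
        self._data = np.zeros((self.n_channels, self.capacity_samples), dtype=np.float32)
        self._write_pos = 0
        self._written = 0  # total samples ever written (incl. zero-fill)
        self.newest_timestamp: int | None = None  # last sample index stored
        self.n_gaps = 0

    @property
    def span(self) -> int:
        """Number of samples currently retrievable."""
        return min(self._written, self.capacity_samples)

    @property
    def oldest_timestamp(self) -> int | None:
        if self.newest_timestamp is None:
            return None
        return self.newest_timestamp - self.span + 1

    def _write(self, block: np.ndarray) -> None:
        n = block.shape[1]
        if n >= self.capacity_samples:
            self._data[:, :] = block[:, -self.capacity_samples :]
            self._write_pos = 0
            self._written += n
            return
        end = self._write_pos + n
        if end <= self.capacity_samples:
            self._data[:, self._write_pos : end] = block
        else:
            first = self.capacity_samples - self._write_pos
            self._data[:, self._write_pos :] = block[:, :first]
            self._data[:, : end - self.capacity_samples] = block[:, first:]
        self._write_pos = end % self.capacity_samples
        self._written += n

    def append(self, packet: SamplePacket) -> None:
        """Append a packet, zero-filling any timestamp gap."""
        if packet.n_channels != self.n_channels:
            raise ChannelCountMismatchError(
                f"packet has {packet.n_channels} channels, buffer configured "
                f"for {self.n_channels}"
            )
        if self.newest_timestamp is not None:
            expected = self.newest_timestamp + 1
            gap = packet.start_timestamp - expected
            if gap > 0:
                logger.warning(
                    "gap of %d samples before timestamp %d; zero-filling",
                    gap,
                    packet.start_timestamp,
                )
                self.n_gaps += 1
                self._write(np.zeros((self.n_channels, gap), dtype=np.float32))
            elif gap < 0:
                logger.warning(
                    "packet at %d overlaps buffered data ending at %d; appending as-is",
                    packet.start_timestamp,
                    self.newest_timestamp,
                )
        self._write(np.asarray(packet.samples, dtype=np.float32))
        self.newest_timestamp = packet.end_timestamp - 1

    def get(self, start_timestamp: int, n_samples: int) -> np.ndarray:
        """Return a contiguous copy of samples ``[start, start + n)``.

        Raises :class:`StaleEventError` when the range precedes the
        retained history and :class:`LookupError` when it extends past
        the newest sample.
        """
        if self.newest_timestamp is None:
            raise StaleEventError("buffer is empty")
        oldest = self.oldest_timestamp
        end_timestamp = start_timestamp + n_samples
        if start_timestamp < oldest:
            raise StaleEventError(
                f"window starts at {start_timestamp}, history begins at {oldest}"
            )
        if end_timestamp > self.newest_timestamp + 1:
            raise LookupError(
                f"window ends at {end_timestamp}, newest sample is "
                f"{self.newest_timestamp}"
            )
        # position of start within the logical (unrolled) history
        offset_from_end = (self.newest_timestamp + 1) - start_timestamp
        logical_start = self.span - offset_from_end
        unrolled = self._unrolled()
        return unrolled[:, logical_start : logical_start + n_samples].copy()

    def _unrolled(self) -> np.ndarray:
        """View of the history in chronological order (copy-free when possible)."""
        if self._written <= self.capacity_samples:
            return self._data[:, : self._written]
        return np.concatenate(
            (self._data[:, self._write_pos :], self._data[:, : self._write_pos]), axis=1
        )

    def recent(self, n_samples: int) -> np.ndarray:
        """The most recent ``n_samples`` (fewer if less is buffered)."""
        n = min(n_samples, self.span)
        return self._unrolled()[:, self.span - n : self.span].copy()


def extract_roi(buffer: RingBuffer, event: TriggerEvent, roi: RoiWindow) -> AlignedWindow:
    """Slice the event-aligned window ``[event - pre, event + post)``.

    The result equals the corresponding slice of the underlying
    continuous signal exactly.  An event whose window precedes the
    retained history raises :class:`StaleEventError` (callers count
    and skip, they do not abort).
    """
    pre = roi.pre_samples(buffer.sampling_rate)
    post = roi.post_samples(buffer.sampling_rate)
    start = event.timestamp - pre
    if start < 0:
        raise StaleEventError(
            f"event at {event.timestamp} with pre={pre} samples precedes t=0"
        )
    samples = buffer.get(start, pre + post)
    return AlignedWindow(
        event=event,
        samples=samples,
        t0_offset=pre,
        start_timestamp=start,
        sampling_rate=buffer.sampling_rate,
    )


def downsample_for_display(
    buffer: RingBuffer, target_points: int, span_seconds: float = 1.0
) -> np.ndarray:
    """Decimate the most recent ``span_seconds`` for display.

    Each output bucket keeps its extreme value (largest absolute
    excursion) so brief spikes survive decimation.  Returns an array of
    shape ``(n_channels, target_points)`` (fewer points if less data is
    buffered than requested).
    """
    if target_points < 2:
        raise ValueError("target_points must be >= 2")
    data = buffer.recent(int(round(span_seconds * buffer.sampling_rate)))
    n = data.shape[1]
    if n == 0:
        return np.zeros((buffer.n_channels, 0), dtype=np.float32)
    if n <= target_points:
        return data
    edges = np.linspace(0, n, target_points + 1).astype(int)
    out = np.empty((buffer.n_channels, target_points), dtype=np.float32)
    for j in range(target_points):
        bucket = data[:, edges[j] : max(edges[j + 1], edges[j] + 1)]
        idx = np.argmax(np.abs(bucket), axis=1)
        out[:, j] = bucket[np.arange(buffer.n_channels), idx]
    return out


@dataclass
class Collector:
    """Routes a packet stream into the ring buffer and an event queue.

    Rising-edge events on ``trigger_channel`` are held until the
    buffer covers the full post-event window, then released as aligned
    windows by :meth:`ready_windows`.  Events on other channels and
    falling edges are logged but never trigger extraction.
    """

    n_channels: int
    sampling_rate: float = 30_000.0
    trigger_channel: int = 1
    roi: RoiWindow = field(default_factory=RoiWindow)
    capacity_seconds: float = DEFAULT_CAPACITY_SECONDS

    def __post_init__(self) -> None:
        self.buffer = RingBuffer(
            self.n_channels,
            int(round(self.capacity_seconds * self.sampling_rate)),
            self.sampling_rate,
        )
        self.pending: deque[TriggerEvent] = deque()
        self.other_events: list[TriggerEvent] = []
        self.stale_events = 0

    def process_packet(self, packet: Packet) -> None:
        if isinstance(packet, SamplePacket):
            self.buffer.append(packet)
        elif isinstance(packet, TriggerEvent):
            self.register_event(packet)
        # heartbeats are transport bookkeeping; nothing to do here

    def register_event(self, event: TriggerEvent) -> None:
        """Queue a rising-edge event on the trigger channel; log others."""
        if event.edge != "rising" or event.event_channel != self.trigger_channel:
            logger.debug("non-trigger event logged: %s", event)
            self.other_events.append(event)
            return
        self.pending.append(event)

    def ready_windows(self) -> list[AlignedWindow]:
        """Pop and extract every pending event whose window is buffered.

        An event becomes ready once the buffer has reached
        ``event + post`` samples; at ``event + post - 1`` it is still
        held pending.
        """
        post = self.roi.post_samples(self.sampling_rate)
        out: list[AlignedWindow] = []
        while self.pending:
            event = self.pending[0]
            newest = self.buffer.newest_timestamp
            if newest is None or newest < event.timestamp + post:
                break  # data not yet available; keep waiting
            self.pending.popleft()
            try:
                out.append(extract_roi(self.buffer, event, self.roi))
            except StaleEventError as exc:
                self.stale_events += 1
                logger.warning("skipping stale event at %d: %s", event.timestamp, exc)
        return out

    def flush(self) -> list[AlignedWindow]:
        """Extract any remaining pending events whose full window
        ``[event - pre, event + post)`` is already covered (used at end
        of stream, where no further sample can arrive)."""
        post = self.roi.post_samples(self.sampling_rate)
        out: list[AlignedWindow] = []
        while self.pending:
            event = self.pending.popleft()
            newest = self.buffer.newest_timestamp
            if newest is None or newest < event.timestamp + post - 1:
                logger.warning("event at %d never covered by data; dropped", event.timestamp)
                continue
            try:
                out.append(extract_roi(self.buffer, event, self.roi))
            except StaleEventError as exc:
                self.stale_events += 1
                logger.warning("skipping stale event at %d: %s", event.timestamp, exc)
        return out
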