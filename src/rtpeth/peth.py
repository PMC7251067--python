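"""Peri-event time histogram accumulation and the cross-correlation PETH.

A PETH is a histogram of spike times relative to an external event; it
is mathematically the cross-correlation of the spike and event point
processes.  :class:`PethAccumulator` implements the streaming
event-loop form used online; :func:`peth_by_crosscorrelation`
implements the offline binary-time-series form used for validation.
Bins are half-open ``[lo, hi)`` with the event time falling in the
``[0, 1)`` ms bin; counts are raw (rate normalisation is a separate
presentation helper).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spike_detect import DetectedSpike
from .stream_protocol import TriggerEvent


@dataclass(frozen=True)
class GroupingConfig:
    """How channels are pooled for display: 1..8 per plot (default 4,
    matching classical tetrode recordings), or one histogram per channel."""

    channels_per_plot: int = 4
    view: str = "aggregate"

    def __post_init__(self) -> None:
        if not 1 <= self.channels_per_plot <= 8:
            raise ValueError(
                f"channels_per_plot must be in 1..8, got {self.channels_per_plot}"
            )
        if self.view not in ("aggregate", "per_channel"):
            raise ValueError(f"view must be 'aggregate' or 'per_channel', got {self.view!r}")


class PethAccumulator:
    """Binned counts of relative spike times, one row per channel.

    Parameters
    ----------
    n_channels :
        Number of histogram rows.
    pre_ms, post_ms :
        Span of relative time covered, ``[-pre_ms, +post_ms)``.
    bin_width_ms :
        Bin width; 1 ms by default.
    sampling_rate :
        Clock used to convert sample timestamps to milliseconds.
    """

    def __init__(
        self,
        n_channels: int,
        pre_ms: float = 20.0,
        post_ms: float = 50.0,
        bin_width_ms: float = 1.0,
        sampling_rate: float = 30_000.0,
    ):
        if bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be positive")
        self.n_channels = int(n_channels)
        self.pre_ms = float(pre_ms)
        self.post_ms = float(post_ms)
        self.bin_width_ms = float(bin_width_ms)
        self.sampling_rate = float(sampling_rate)
        n_bins = int(round((pre_ms + post_ms) / bin_width_ms))
        self.edges = -pre_ms + np.arange(n_bins + 1) * bin_width_ms
        self.counts = np.zeros((self.n_channels, n_bins), dtype=np.int64)
        self.n_events = 0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def update(self, spikes: list[DetectedSpike], event: TriggerEvent) -> "PethAccumulator":
        """Fold one event and its detected spikes into the histogram.

        Each spike contributes to bin ``floor((r + pre) / width)`` where
        ``r = (spike_ts - event_ts) / fs`` in ms, if ``r`` lies in
        ``[-pre, post)``; ``n_events`` advances once per event, spikes
        or not.
        """
        self.n_events += 1
        for spike in spikes:
            r_ms = (spike.timestamp - event.timestamp) * 1000.0 / self.sampling_rate
            b = math.floor((r_ms + self.pre_ms) / self.bin_width_ms)
            if 0 <= b < self.n_bins:
                self.counts[spike.channel, b] += 1
        return self

    def reset(self) -> "PethAccumulator":
        """Zero all counts and the event counter; edges/config persist."""
        self.counts[:] = 0
        self.n_events = 0
        return self

    def group_counts(self, grouping: GroupingConfig) -> np.ndarray:
        """Pool counts into display groups.

        Aggregate view sums consecutive channel blocks of
        ``channels_per_plot``; a trailing smaller block forms its own
        group.  Per-channel view returns the counts unchanged.
        """
        if grouping.view == "per_channel" or grouping.channels_per_plot == 1:
            return self.counts.copy()
        k = grouping.channels_per_plot
        n_groups = -(-self.n_channels // k)  # ceil
        out = np.zeros((n_groups, self.n_bins), dtype=np.int64)
        for g in range(n_groups):
            out[g] = self.counts[g * k : (g + 1) * k].sum(axis=0)
        return out

    def rate_per_event(self) -> np.ndarray:
        """Counts converted to spikes/s per event (presentation helper)."""
        if self.n_events == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / (self.n_events * self.bin_width_ms / 1000.0)


def peth_by_crosscorrelation(
    spike_times_ms,
    event_times_ms,
    resolution_ms: float = 1.0,
    max_lag_ms: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Offline PETH via cross-correlation of binarized point processes.

    Both point processes are binarized at ``resolution_ms`` (a bin is 1
    if at least one point falls in it).  Returns ``(lags_ms, counts)``
    where ``counts[i]`` is the number of (spike bin, event bin) pairs
    separated by ``lags_ms[i]``, for lags in ``[-max_lag, +max_lag]``.

    For point processes with at most one point per bin this equals the
    event-loop accumulation over the same bins.
    """
    event_times_ms = np.asarray(event_times_ms, dtype=float)
    if event_times_ms.size == 0:
        raise ValueError("event list is empty: no alignment possible")
    if resolution_ms <= 0:
        raise ValueError("resolution_ms must be positive")
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)

    spike_bins = np.unique(np.floor(spike_times_ms / resolution_ms).astype(np.int64))
    event_bins = np.unique(np.floor(event_times_ms / resolution_ms).astype(np.int64))

    n_lags = int(round(max_lag_ms / resolution_ms))
    lags = np.arange(-n_lags, n_lags + 1) * resolution_ms
    counts = np.zeros(lags.size, dtype=np.int64)
    event_set = set(event_bins.tolist())
    for i, lag_bins in enumerate(range(-n_lags, n_lags + 1)):
        counts[i] = sum(1 for s in spike_bins if (s - lag_bins) in event_set)
    return lags, counts
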