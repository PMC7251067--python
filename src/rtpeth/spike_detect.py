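"""Threshold-crossing spike discrimination with censoring.

Detection runs independently per channel inside an event-aligned
window.  A detection starts when the signal strictly crosses the
threshold (below it for negative polarity); the extremum of the
supra-threshold run is the spike peak.  After a detection no new spike
is accepted until the holdoff (censoring) time has elapsed and the
signal has returned across the threshold, so one spike is never
counted twice.  Channel ids are 1-based in user-facing text and
configuration, 0-based internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .collector import AlignedWindow
from .units import ms_to_samples

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_UV = -50.0
DEFAULT_HOLDOFF_MS = 0.75

WAVEFORM_PRE_MS = 0.3
WAVEFORM_POST_MS = 1.0


@dataclass
class ThresholdConfig:
    """Per-channel thresholds, polarity, holdoff and disabled channels.

    ``thresholds`` maps 1-based channel ids to microvolt levels; ids
    not present use ``default_threshold``.  Negative polarity (the
    default, suiting non-inverted extracellular data) requires negative
    thresholds.
    """

    default_threshold: float = DEFAULT_THRESHOLD_UV
    thresholds: dict[int, float] = field(default_factory=dict)
    polarity: str = "negative"
    holdoff_ms: float = DEFAULT_HOLDOFF_MS
    disabled_channels: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"polarity must be 'negative' or 'positive', got {self.polarity!r}")
        if self.holdoff_ms < 0:
            raise ValueError(f"holdoff_ms must be >= 0, got {self.holdoff_ms}")
        for value in [self.default_threshold, *self.thresholds.values()]:
            self._check_sign(value)

    def _check_sign(self, value: float) -> None:
        if self.polarity == "negative" and value >= 0:
            raise ValueError(
                f"negative polarity requires threshold < 0, got {value}"
            )
        if self.polarity == "positive" and value <= 0:
            raise ValueError(
                f"positive polarity requires threshold > 0, got {value}"
            )

    def threshold_for(self, channel_1b: int) -> float:
        return self.thresholds.get(channel_1b, self.default_threshold)

    def is_enabled(self, channel_1b: int) -> bool:
        return channel_1b not in self.disabled_channels


def set_threshold(config: ThresholdConfig, channel: int | str, value: float) -> ThresholdConfig:
    """Set the threshold for one 1-based channel or for ``'all'``.

    Returns the updated config (mutated in place for convenience).
    A value whose sign contradicts the polarity is a validation error.
    """
    config._check_sign(value)
    if channel == "all":
        config.default_threshold = value
        config.thresholds.clear()
    else:
        config.thresholds[int(channel)] = value
    return config


@dataclass(frozen=True)
class DetectedSpike:
    """One threshold-crossing detection.

    Indices are sample positions within the source window;
    ``timestamp`` is absolute (window start + peak index).
    """

    channel: int  # 0-based channel index within the window
    peak_index: int
    peak_amplitude: float
    excursion_start: int
    excursion_end: int
    timestamp: int = -1

    def __post_init__(self) -> None:
        if not self.excursion_start <= self.peak_index <= self.excursion_end:
            raise ValueError("peak_index must lie within the excursion bounds")


@dataclass(frozen=True)
class SpikeWaveform:
    channel: int
    samples: np.ndarray
    peak_offset: int


def _runs_across_threshold(trace: np.ndarray, threshold: float, polarity: str):
    """Yield (start, end_inclusive, peak_idx, peak_amp) for each
    supra-threshold run.  Strict comparison; a run still open at the
    window end is closed at the last sample.  Peak ties break to the
    earliest extremal sample."""
    if polarity == "negative":
        below = trace < threshold
    else:
        below = trace > threshold
    if not below.any():
        return
    padded = np.diff(np.concatenate(([0], below.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1  # inclusive
    for s, e in zip(starts, ends):
        segment = trace[s : e + 1]
        rel = int(np.argmin(segment) if polarity == "negative" else np.argmax(segment))
        yield int(s), int(e), s + rel, float(segment[rel])


def detect_spikes(window: AlignedWindow, config: ThresholdConfig) -> list[DetectedSpike]:
    """Detect spikes on every enabled channel of an aligned window.

    Censoring: a supra-threshold run is ignored when it begins before
    ``holdoff_ms`` has elapsed since the previous accepted peak (runs
    are separated by threshold re-crossings by construction, so both
    censoring conditions are enforced).  Disabled channels yield no
    detections.  Overlapping windows from consecutive triggers may
    report the same spike twice -- online detection does not dedupe.
    """
    holdoff = ms_to_samples(config.holdoff_ms, window.sampling_rate)
    spikes: list[DetectedSpike] = []
    for ch in range(window.n_channels):
        if not config.is_enabled(ch + 1):
            continue
        threshold = config.threshold_for(ch + 1)
        last_peak: int | None = None
        for start, end, peak, amp in _runs_across_threshold(
            window.samples[ch], threshold, config.polarity
        ):
            if last_peak is not None and start < last_peak + holdoff:
                continue  # censored
            spikes.append(
                DetectedSpike(
                    channel=ch,
                    peak_index=peak,
                    peak_amplitude=amp,
                    excursion_start=start,
                    excursion_end=end,
                    timestamp=window.start_timestamp + peak,
                )
            )
            last_peak = peak
    return spikes


def detect_spikes_continuous(
    data: np.ndarray, sampling_rate: float, config: ThresholdConfig
) -> list[DetectedSpike]:
    """Run the same detector over a full-length continuous matrix.

    Convenience for the offline chain; timestamps are absolute sample
    indices from the start of ``data``.
    """
    window = AlignedWindow(
        event=None,  # type: ignore[arg-type]
        samples=np.atleast_2d(np.asarray(data)),
        t0_offset=0,
        start_timestamp=0,
        sampling_rate=sampling_rate,
    )
    return detect_spikes(window, config)


def extract_waveform(
    spike: DetectedSpike,
    window: AlignedWindow,
    pre_ms: float = WAVEFORM_PRE_MS,
    post_ms: float = WAVEFORM_POST_MS,
) -> SpikeWaveform | None:
    """Cut the waveform around a detected peak (default -0.3 ms to +1 ms).

    Returns ``None`` (spike retained, extraction logged) when the span
    would exceed the window bounds.
    """
    pre = ms_to_samples(pre_ms, window.sampling_rate)
    post = ms_to_samples(post_ms, window.sampling_rate)
    lo = spike.peak_index - pre
    hi = spike.peak_index + post  # inclusive end
    if lo < 0 or hi >= window.n_samples:
        logger.debug(
            "waveform span [%d, %d] exceeds window of %d samples; skipped",
            lo,
            hi,
            window.n_samples,
        )
        return None
    return SpikeWaveform(
        channel=spike.channel,
        samples=window.samples[spike.channel, lo : hi + 1].copy(),
        peak_offset=pre,
    )


_RANGE_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")


def parse_channel_ranges(text: str) -> set[int]:
    """Parse a channel list: comma-separated ids and/or dash ranges.

    ``"1, 2, 3"`` and ``"1-3"`` both give ``{1, 2, 3}``; en-dash is
    accepted.  Malformed tokens raise ``ValueError`` naming the token.
    """
    channels: set[int] = set()
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        if token.isdigit():
            channels.add(int(token))
            continue
        m = _RANGE_RE.match(token)
        if not m:
            raise ValueError(f"malformed channel token: {token!r}")
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo > hi:
            raise ValueError(f"malformed channel range (start > end): {token!r}")
        channels.update(range(lo, hi + 1))
    return channels


def format_channel_ranges(channels: set[int]) -> str:
    """Inverse of :func:`parse_channel_ranges` (canonical dash form)."""
    if not channels:
        return ""
    ids = sorted(channels)
    parts: list[str] = []
    start = prev = ids[0]
    for c in ids[1:] + [None]:  # type: ignore[list-item]
        if c is not None and c == prev + 1:
            prev = c
            continue
        parts.append(str(start) if start == prev else f"{start}-{prev}")
        if c is not None:
            start = prev = c
    return ",".join(parts)
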