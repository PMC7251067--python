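"""Post-hoc analysis chain: zero-phase filtering, tetrode-wide spike
merging with largest-spike censoring, automated light-response
classification, online/offline concordance statistics and
experiment-time accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sp_signal

from .spike_detect import DetectedSpike
from .units import ms_to_samples

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# band-pass filtering


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass for the spike band.

    Defaults: 600-6000 Hz, order 4, applied forward-backward (effective
    order 8, zero phase shift).
    """

    low_cut: float = 600.0
    high_cut: float = 6000.0
    order: int = 4

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError(
                f"need 0 < low_cut < high_cut, got ({self.low_cut}, {self.high_cut})"
            )
        if self.high_cut >= sampling_rate / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz must be below Nyquist "
                f"({sampling_rate / 2} Hz)"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


def bandpass_filter(
    data: np.ndarray, spec: FilterSpec, sampling_rate: float
) -> np.ndarray:
    """Filter a trace (or ``[channel][sample]`` matrix) with zero phase.

    Forward-backward application (``sosfiltfilt``) keeps spike peaks at
    their original sample positions, unlike the causal filters used
    online.
    """
    spec.validate(sampling_rate)
    sos = sp_signal.butter(
        spec.order,
        [spec.low_cut, spec.high_cut],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )
    return sp_signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# tetrode-wide merge + censor


def merge_and_censor(
    per_channel_spikes: Sequence[Iterable[DetectedSpike]],
    censor_ms: float,
    sampling_rate: float,
) -> list[DetectedSpike]:
    """Merge spike lists from the wires of one tetrode and censor.

    Within any censoring window only the detection with the largest
    absolute amplitude survives (largest first, greedily), so the same
    physical spike seen on several wires is counted once -- by its
    biggest appearance.  Output is time-sorted with all inter-spike
    gaps >= ``censor_ms``.
    """
    censor = ms_to_samples(censor_ms, sampling_rate)
    merged = [s for lst in per_channel_spikes for s in lst]
    # largest |amplitude| first; ties broken by earlier time for determinism
    merged.sort(key=lambda s: (-abs(s.peak_amplitude), s.timestamp, s.channel))
    kept_ts: list[int] = []
    kept: list[DetectedSpike] = []
    for spike in merged:
        if all(abs(spike.timestamp - t) >= censor for t in kept_ts):
            kept.append(spike)
            kept_ts.append(spike.timestamp)
    kept.sort(key=lambda s: s.timestamp)
    return kept


# ---------------------------------------------------------------------------
# light-response classification


@dataclass(frozen=True)
class LightResponseResult:
    outcome: str  # "positive" | "negative" | "insufficient_events"
    score: float
    peak_bin_ms: float | None = None

    def __bool__(self) -> bool:
        return self.outcome == "positive"


def light_response_criterion(
    counts: np.ndarray,
    edges_ms: np.ndarray,
    n_events: int,
    latency_window_ms: tuple[float, float] = (0.0, 10.0),
    baseline_window_ms: tuple[float, float] | None = None,
    z_threshold: float = 3.0,
    min_events: int = 10,
) -> LightResponseResult:
    """Automated surrogate for the experimenter's online judgment.

    Positive iff the maximum bin count inside the latency window
    exceeds the baseline mean by more than ``z_threshold`` baseline
    standard deviations.  The baseline defaults to all pre-event bins.
    Fewer than ``min_events`` events gives the ``insufficient_events``
    outcome (neither positive nor negative).
    """
    counts = np.asarray(counts)
    edges_ms = np.asarray(edges_ms, dtype=float)
    if counts.ndim != 1 or counts.size != edges_ms.size - 1:
        raise ValueError("counts must be 1-D with len(edges) - 1 bins")
    if n_events < min_events:
        return LightResponseResult("insufficient_events", float("nan"))
    if baseline_window_ms is None:
        baseline_window_ms = (float(edges_ms[0]), 0.0)

    lo_bins = edges_ms[:-1]
    base_mask = (lo_bins >= baseline_window_ms[0]) & (lo_bins < baseline_window_ms[1])
    lat_mask = (lo_bins >= latency_window_ms[0]) & (lo_bins < latency_window_ms[1])
    if not base_mask.any() or not lat_mask.any():
        raise ValueError("both the baseline and latency windows must contain bins")

    base = counts[base_mask].astype(float)
    mean, sd = base.mean(), base.std(ddof=0)
    peak_idx = int(np.flatnonzero(lat_mask)[np.argmax(counts[lat_mask])])
    peak = float(counts[peak_idx])
    if sd == 0.0:
        score = float("inf") if peak > mean else 0.0
    else:
        score = (peak - mean) / sd
    positive = score > z_threshold
    return LightResponseResult(
        "positive" if positive else "negative",
        score,
        peak_bin_ms=float(lo_bins[peak_idx]),
    )


# ---------------------------------------------------------------------------
# concordance


@dataclass(frozen=True)
class TetrodeDetectionRecord:
    """Online vs offline light-response labels for one (session, tetrode)."""

    session_id: str
    tetrode_id: int
    online_positive: bool
    offline_positive: bool


@dataclass(frozen=True)
class ConcordanceTable:
    """Confusion counts of online detection against the offline standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def online_positive(self) -> int:
        return self.tp + self.fp

    @property
    def sensitivity(self) -> float | None:
        """True-positive rate in percent, full precision; ``None`` when
        undefined (no offline positives)."""
        if self.tp + self.fn == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        if self.tn + self.fp == 0:
            return None
        return 100.0 * self.tn / (self.tn + self.fp)

    def sensitivity_pct(self) -> float | str:
        """Sensitivity rounded to two decimals, or ``'undefined'``."""
        s = self.sensitivity
        return "undefined" if s is None else round(s, 2)

    def specificity_pct(self) -> float | str:
        s = self.specificity
        return "undefined" if s is None else round(s, 2)

    def __add__(self, other: "ConcordanceTable") -> "ConcordanceTable":
        return ConcordanceTable(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def concordance(records: Sequence[TetrodeDetectionRecord]) -> ConcordanceTable:
    """Tally online vs offline labels into a confusion table."""
    if not records:
        raise ValueError("record list is empty")
    tp = sum(1 for r in records if r.online_positive and r.offline_positive)
    fp = sum(1 for r in records if r.online_positive and not r.offline_positive)
    fn = sum(1 for r in records if not r.online_positive and r.offline_positive)
    tn = sum(1 for r in records if not r.online_positive and not r.offline_positive)
    return ConcordanceTable(tp, fp, fn, tn)


def concordance_from_counts(
    session_counts: Iterable[tuple[int, int, int, int]]
) -> ConcordanceTable:
    """Sum per-session (tp, fp, fn, tn) rows into one table."""
    table = ConcordanceTable(0, 0, 0, 0)
    for tp, fp, fn, tn in session_counts:
        table = table + ConcordanceTable(tp, fp, fn, tn)
    return table


# ---------------------------------------------------------------------------
# experiment-time accounting


@dataclass
class TimeBudget:
    """Inputs of the experiment-time accounting.

    ``actual_hours`` are the measured per-animal waiting-plus-recording
    durations of sessions guided by online feedback; the baseline is
    what exhaustive recording of every position would have cost.
    """

    n_animals: int
    actual_hours: list[float] = field(default_factory=list)
    settle_min: float = 30.0
    record_min: float = 15.0
    positions_per_animal: int = 10
    analysis_min_per_session: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "n_animals",
            "settle_min",
            "record_min",
            "positions_per_animal",
            "analysis_min_per_session",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(h < 0 for h in self.actual_hours):
            raise ValueError("actual_hours must be non-negative")


@dataclass(frozen=True)
class TimeSavingsReport:
    baseline_hours: float
    actual_hours_total: float
    recording_saved_h: float
    sessions_avoided: int
    analysis_saved_h: float
    total_saved_h: float


def time_savings(budget: TimeBudget) -> TimeSavingsReport:
    """Compute hours of recording and analysis work saved.

    Baseline assumes every planned position is settled and recorded;
    sessions actually recorded are inferred from the measured total at
    one settle+record block per session (rounded to the nearest whole
    session); each avoided session also avoids its analysis time.
    """
    session_h = (budget.settle_min + budget.record_min) / 60.0
    baseline = budget.n_animals * budget.positions_per_animal * session_h
    actual_total = float(sum(budget.actual_hours))
    recording_saved = baseline - actual_total
    if recording_saved < 0:
        logger.warning(
            "actual time (%.2f h) exceeds baseline (%.2f h); negative savings",
            actual_total,
            baseline,
        )
    sessions_recorded = int(round(actual_total / session_h)) if session_h > 0 else 0
    sessions_avoided = budget.n_animals * budget.positions_per_animal - sessions_recorded
    analysis_saved = sessions_avoided * budget.analysis_min_per_session / 60.0
    return TimeSavingsReport(
        baseline_hours=baseline,
        actual_hours_total=actual_total,
        recording_saved_h=recording_saved,
        sessions_avoided=sessions_avoided,
        analysis_saved_h=analysis_saved,
        total_saved_h=recording_saved + analysis_saved,
    )
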