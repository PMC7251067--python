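"""Time-unit conversion helpers shared across modules."""

from __future__ import annotations

import math


def ms_to_samples(ms: float, sampling_rate: float) -> int:
    """Convert milliseconds to a sample count.

    Rounds half away from zero, applied once per boundary (never
    cumulatively) so repeated conversions cannot drift.
    """
    x = ms * sampling_rate / 1000.0
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def samples_to_ms(samples: float, sampling_rate: float) -> float:
    return samples * 1000.0 / sampling_rate
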