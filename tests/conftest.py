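import numpy as np
import pytest

from rtpeth.collector import AlignedWindow
from rtpeth.stream_protocol import TriggerEvent


@pytest.fixture
def make_window():
    """Build an AlignedWindow directly from a sample matrix."""

    def _make(samples, sampling_rate=30_000.0, start_timestamp=0, t0_offset=0):
        samples = np.atleast_2d(np.asarray(samples, dtype=np.float32))
        return AlignedWindow(
            event=TriggerEvent(1, start_timestamp + t0_offset, "rising"),
            samples=samples,
            t0_offset=t0_offset,
            start_timestamp=start_timestamp,
            sampling_rate=sampling_rate,
        )

    return _make


@pytest.fixture
def tagged_config():
    """Standard tagged-unit simulation: 20 Hz trains, 2 s ON / 3 s OFF,
    evoked latency 3 +- 0.5 ms."""
    from rtpeth.simulator import (
        EvokedSpec,
        SimulationConfig,
        StimulusSpec,
        UnitSpec,
    )

    def _make(seed=1, duration_s=10.0, n_channels=4, noise_sd_uv=10.0, **kwargs):
        return SimulationConfig(
            n_channels=n_channels,
            duration_s=duration_s,
            seed=seed,
            noise_sd_uv=noise_sd_uv,
            units=[
                UnitSpec(
                    channels={c: 1.0 - 0.15 * c for c in range(min(4, n_channels))},
                    background_rate_hz=2.0,
                    evoked=EvokedSpec(probability=0.8, latency_ms=3.0, jitter_ms=0.5),
                )
            ],
            stimulus=StimulusSpec(),
            **kwargs,
        )

    return _make
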