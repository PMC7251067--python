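"""Raw int16 binary recordings with a JSON metadata sidecar.

Layout: little-endian int16, sample-major (interleaved channels, the
common layout of acquisition-system raw dumps).  The sidecar
``<file>.json`` records ``n_channels``, ``sampling_rate`` and
``scale_uv_per_bit``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

DEFAULT_SCALE_UV_PER_BIT = 0.195  # typical headstage LSB size


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_raw_binary(
    path: str | Path,
    data_uv: np.ndarray,
    sampling_rate: float,
    scale_uv_per_bit: float = DEFAULT_SCALE_UV_PER_BIT,
) -> Path:
    """Write a ``[channel][sample]`` microvolt matrix as int16 + sidecar."""
    path = Path(path)
    data_uv = np.asarray(data_uv)
    if data_uv.ndim != 2:
        raise ValueError("data must be a 2-D [channel][sample] matrix")
    counts = np.round(data_uv / scale_uv_per_bit)
    if np.abs(counts).max(initial=0) > 32767:
        raise ValueError("data exceeds int16 range at this scale")
    counts.astype("<i2").T.tofile(path)  # sample-major
    sidecar_path(path).write_text(
        json.dumps(
            {
                "n_channels": int(data_uv.shape[0]),
                "sampling_rate": float(sampling_rate),
                "scale_uv_per_bit": float(scale_uv_per_bit),
                "dtype": "int16",
                "byte_order": "little",
                "layout": "sample_major",
            },
            indent=2,
        )
    )
    return path


def read_raw_binary(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an int16 recording back to microvolts using its sidecar.

    Returns ``(data_uv [channel][sample], sampling_rate)``.
    """
    path = Path(path)
    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_file}")
    meta = json.loads(meta_file.read_text())
    n_channels = int(meta["n_channels"])
    raw = np.fromfile(path, dtype="<i2")
    if raw.size % n_channels:
        raise ValueError(
            f"file holds {raw.size} values, not divisible by {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(np.float32)
    return data * float(meta["scale_uv_per_bit"]), float(meta["sampling_rate"])
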