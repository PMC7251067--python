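"""Wire format for streamed continuous data and digital events.

A stream is a sequence of JSON messages, one per line (the
``opeth-jsonl/1`` dialect).  Every message is a self-describing JSON
object with a ``type`` tag:

``samples``
    A block of multichannel continuous voltage data.  Metadata fields
    ``timestamp`` (first sample index), ``n_channels``, ``n_samples``
    and ``sampling_rate``; the voltage matrix is carried in ``content``
    as base64-encoded little-endian float32 microvolts, row-major
    ``[channel][sample]``.

``event``
    A digital (TTL) edge: ``event_channel``, ``timestamp`` (sample
    index) and ``edge`` (``rising`` or ``falling``).

``heartbeat``
    Liveness message from a client: ``client_id`` and ``sent_at``
    (wall-clock seconds).

``header``
    Optional first line of a stream file carrying ``version``.

Timestamps are 0-based integer sample counts since acquisition start;
events are stamped at the edge sample so a single clock aligns data and
events.
"""

from __future__ import annotations

import base64
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

import numpy as np

logger = logging.getLogger(__name__)

STREAM_VERSION = "opeth-jsonl/1"

DEFAULT_SAMPLING_RATE = 30_000.0


class StreamError(Exception):
    """Base class for wire-format errors."""


class PacketValidationError(StreamError, ValueError):
    """A packet violates its own invariants; names the offending field."""


class ParseError(StreamError, ValueError):
    """The byte sequence is not a well-formed JSON message."""


class SchemaError(StreamError, ValueError):
    """A well-formed JSON message is missing a mandatory field."""


class UnknownPacketTypeError(StreamError, ValueError):
    """The message carries an unrecognised ``type`` tag."""

    def __init__(self, tag: object):
        self.tag = tag
        super().__init__(f"unknown packet type: {tag!r}")


@dataclass
class SamplePacket:
    """A timestamped block of multichannel continuous voltage samples.

    ``samples`` is a float array of shape ``(n_channels, n_samples)``
    in microvolts.  ``start_timestamp`` is the index of the first
    sample on the acquisition clock.
    """

    start_timestamp: int
    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise PacketValidationError(
                f"samples: expected a 2-D [channel][sample] matrix, "
                f"got ndim={self.samples.ndim}"
            )
        if self.start_timestamp < 0:
            raise PacketValidationError(
                f"start_timestamp: must be non-negative, got {self.start_timestamp}"
            )
        if self.sampling_rate <= 0:
            raise PacketValidationError(
                f"sampling_rate: must be positive, got {self.sampling_rate}"
            )
        if 0 in self.samples.shape:
            raise PacketValidationError(
                f"samples: matrix must be non-empty, got shape {self.samples.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def end_timestamp(self) -> int:
        """One past the last sample index covered by this packet."""
        return self.start_timestamp + self.n_samples

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SamplePacket):
            return NotImplemented
        return (
            self.start_timestamp == other.start_timestamp
            and self.sampling_rate == other.sampling_rate
            and self.samples.shape == other.samples.shape
            and np.array_equal(self.samples, other.samples)
        )


@dataclass(frozen=True)
class TriggerEvent:
    """A digital event: channel id plus timestamp in samples."""

    event_channel: int
    timestamp: int
    edge: str = "rising"

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise PacketValidationError(
                f"timestamp: must be non-negative, got {self.timestamp}"
            )
        if self.edge not in ("rising", "falling"):
            raise PacketValidationError(
                f"edge: must be 'rising' or 'falling', got {self.edge!r}"
            )


@dataclass(frozen=True)
class HeartbeatMessage:
    """Client liveness message."""

    client_id: str
    sent_at: float = field(default_factory=time.time)

    def __post_init__(self) -> None:
        if not self.client_id:
            raise PacketValidationError("client_id: must be non-empty")


Packet = Union[SamplePacket, TriggerEvent, HeartbeatMessage]


def encode_packet(packet: Packet) -> bytes:
    """Serialize a packet to one JSON line (no trailing newline).

    ``decode_packet(encode_packet(p))`` reproduces ``p`` field for
    field; sample payloads are bitwise-stable at float32 precision.
    """
    if isinstance(packet, SamplePacket):
        payload = base64.b64encode(
            np.ascontiguousarray(packet.samples, dtype="<f4").tobytes()
        ).decode("ascii")
        obj = {
            "type": "samples",
            "timestamp": int(packet.start_timestamp),
            "n_channels": packet.n_channels,
            "n_samples": packet.n_samples,
            "sampling_rate": float(packet.sampling_rate),
            "content": payload,
        }
    elif isinstance(packet, TriggerEvent):
        obj = {
            "type": "event",
            "event_channel": int(packet.event_channel),
            "timestamp": int(packet.timestamp),
            "edge": packet.edge,
        }
    elif isinstance(packet, HeartbeatMessage):
        obj = {
            "type": "heartbeat",
            "client_id": packet.client_id,
            "sent_at": float(packet.sent_at),
        }
    else:
        raise TypeError(f"cannot encode object of type {type(packet).__name__}")
    return json.dumps(obj, separators=(",", ":")).encode("utf-8")


def _require(obj: dict, key: str, msg_type: str):
    try:
        return obj[key]
    except KeyError:
        raise SchemaError(f"{msg_type} message missing mandatory field {key!r}") from None


def decode_packet(message: bytes | str) -> Packet:
    """Parse one JSON-line message into its typed packet.

    Raises :class:`ParseError` for malformed JSON, :class:`SchemaError`
    for a missing mandatory field and :class:`UnknownPacketTypeError`
    for an unrecognised type tag (never silently dropped).
    """
    if isinstance(message, bytes):
        message = message.decode("utf-8", errors="replace")
    try:
        obj = json.loads(message)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON envelope: {exc}") from exc
    if not isinstance(obj, dict):
        raise ParseError(f"expected a JSON object, got {type(obj).__name__}")

    tag = _require(obj, "type", "stream")
    if tag == "samples":
        n_channels = int(_require(obj, "n_channels", tag))
        n_samples = int(_require(obj, "n_samples", tag))
        raw = base64.b64decode(_require(obj, "content", tag))
        flat = np.frombuffer(raw, dtype="<f4")
        if flat.size != n_channels * n_samples:
            raise SchemaError(
                f"samples payload holds {flat.size} values, metadata says "
                f"{n_channels}x{n_samples}"
            )
        return SamplePacket(
            start_timestamp=int(_require(obj, "timestamp", tag)),
            samples=flat.reshape(n_channels, n_samples),
            sampling_rate=float(obj.get("sampling_rate", DEFAULT_SAMPLING_RATE)),
        )
    if tag == "event":
        return TriggerEvent(
            event_channel=int(_require(obj, "event_channel", tag)),
            timestamp=int(_require(obj, "timestamp", tag)),
            edge=obj.get("edge", "rising"),
        )
    if tag == "heartbeat":
        return HeartbeatMessage(
            client_id=str(_require(obj, "client_id", tag)),
            sent_at=float(obj.get("sent_at", 0.0)),
        )
    if tag == "header":
        raise UnknownPacketTypeError(tag)  # header lines are handled by replay_stream
    raise UnknownPacketTypeError(tag)


def write_stream(path: str | Path, packets) -> int:
    """Write packets to a JSON-lines stream file with a version header.

    Returns the number of packets written.
    """
    n = 0
    with open(path, "wb") as fh:
        fh.write(
            json.dumps({"type": "header", "version": STREAM_VERSION}).encode() + b"\n"
        )
        for packet in packets:
            fh.write(encode_packet(packet) + b"\n")
            n += 1
    return n


def replay_stream(
    path: str | Path,
    speed: str = "max",
    skip_heartbeats: bool = False,
) -> Iterator[Packet]:
    """Replay a JSON-lines stream file as an ordered packet iterator.

    ``speed='realtime'`` sleeps between sample packets to approximate
    the pace of live acquisition; ``'max'`` replays as fast as
    possible.  Out-of-order sample timestamps are logged as warnings
    and passed through, matching the behaviour of a lossy live stream.
    """
    if speed not in ("max", "realtime"):
        raise ValueError(f"speed must be 'max' or 'realtime', got {speed!r}")
    path = Path(path)
    last_sample_ts: int | None = None
    with open(path, "rb") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            if isinstance(obj, dict) and obj.get("type") == "header":
                version = obj.get("version")
                if version != STREAM_VERSION:
                    logger.warning(
                        "%s: stream version %r, expected %r", path, version, STREAM_VERSION
                    )
                continue
            packet = decode_packet(line)
            if isinstance(packet, HeartbeatMessage) and skip_heartbeats:
                continue
            if isinstance(packet, SamplePacket):
                if last_sample_ts is not None and packet.start_timestamp < last_sample_ts:
                    logger.warning(
                        "%s:%d: out-of-order sample packet (ts %d < %d)",
                        path,
                        lineno,
                        packet.start_timestamp,
                        last_sample_ts,
                    )
                last_sample_ts = max(last_sample_ts or 0, packet.start_timestamp)
                if speed == "realtime":
                    time.sleep(packet.n_samples / packet.sampling_rate)
            yield packet
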