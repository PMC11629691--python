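"""Wire format: one JSON object per line.

EEG samples travel as base-64 little-endian float32 with a declared
shape, so a streamed epoch decodes to exactly the floats the offline
pipeline would see.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ..errors import ProtocolError


class MessageType(str, Enum):
    JOIN = "JOIN"
    ACK = "ACK"
    START_PARADIGM = "START_PARADIGM"
    STIM_SYNC = "STIM_SYNC"
    EEG_DATA = "EEG_DATA"
    ANALYSIS_RESULT = "ANALYSIS_RESULT"
    FEEDBACK = "FEEDBACK"
    STOP_PARADIGM = "STOP_PARADIGM"
    ERROR = "ERROR"


@dataclass
class SessionMessage:
    message_type: MessageType
    session_id: str
    participant_id: str
    sequence_number: int
    timestamp_ms: int
    route: str = ""
    payload: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "message_type": self.message_type.value,
            "session_id": self.session_id,
            "participant_id": self.participant_id,
            "sequence_number": self.sequence_number,
            "timestamp_ms": self.timestamp_ms,
            "route": self.route,
            "payload": self.payload,
        }

    def to_line(self) -> bytes:
        return (json.dumps(self.to_dict(), separators=(",", ":"))
                + "\n").encode("utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "SessionMessage":
        try:
            return cls(
                message_type=MessageType(d["message_type"]),
                session_id=d["session_id"],
                participant_id=d["participant_id"],
                sequence_number=int(d["sequence_number"]),
                timestamp_ms=int(d["timestamp_ms"]),
                route=d.get("route", ""),
                payload=d.get("payload", {}),
            )
        except (KeyError, ValueError) as exc:
            raise ProtocolError(f"malformed message: {exc}") from exc

    @classmethod
    def from_line(cls, line: bytes) -> "SessionMessage":
        try:
            d = json.loads(line.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ProtocolError(f"message is not valid JSON: {exc}") from exc
        if not isinstance(d, dict):
            raise ProtocolError("message must be a JSON object")
        return cls.from_dict(d)


@dataclass
class StimulusState:
    """Visual properties of the flickering targets."""

    targets: dict = field(default_factory=dict)  # freq -> descriptor
    active: bool = False

    @staticmethod
    def default(frequencies) -> "StimulusState":
        freqs = [float(f) for f in frequencies]
        if len(set(freqs)) != len(freqs):
            raise ProtocolError("stimulus frequencies must be unique")
        return StimulusState(targets={
            f: {"frequency": f, "color": [255, 255, 255], "size": 1.0,
                "form": "checkerboard", "highlighted": False}
            for f in freqs})

    def to_dict(self) -> dict:
        import copy
        return {"targets": {str(f): copy.deepcopy(d)
                            for f, d in self.targets.items()},
                "active": self.active}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusState":
        return cls(targets={float(f): v for f, v in d["targets"].items()},
                   active=d["active"])


def encode_samples(samples: np.ndarray) -> dict:
    arr = np.ascontiguousarray(samples, dtype="<f4")
    return {
        "dtype": "float32",
        "shape": list(arr.shape),
        "data": base64.b64encode(arr.tobytes()).decode("ascii"),
    }


def decode_samples(payload: dict) -> np.ndarray:
    try:
        if payload["dtype"] != "float32":
            raise ProtocolError(f"unsupported dtype {payload['dtype']!r}")
        shape = tuple(int(s) for s in payload["shape"])
        raw = base64.b64decode(payload["data"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ProtocolError(f"malformed sample payload: {exc}") from exc
    arr = np.frombuffer(raw, dtype="<f4")
    if arr.size != int(np.prod(shape)):
        raise ProtocolError("sample payload size does not match its shape")
    return arr.reshape(shape).astype(np.float32)
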