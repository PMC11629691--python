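"""File I/O: EDF+ recordings and line-delimited JSON result records.

The EDF writer emits EDF+C files with one data record per second, an
"EDF Annotations" signal carrying the trial markers as standard TALs,
and 16-bit quantization against a documented physical range (default
±200 µV, widened per channel when the data exceed it).  The true sample
count is stashed after the "EDF+C" tag in the reserved header field so
that recordings whose length is not a whole number of records survive a
roundtrip exactly; standard readers ignore that suffix.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .coupling import CouplingResult
from .decoding import DecodingResult
from .errors import ParseError, SchemaError
from .synth import Recording

__all__ = ["write_edf", "read_edf", "write_results", "read_results"]

_DIG_MIN, _DIG_MAX = -32768, 32767
_DEFAULT_PHYS_RANGE = 200.0
_ANNOTATION_LABEL = "EDF Annotations"

RESULTS_SCHEMA = "cobci.results/1"
_RESULT_KINDS = {"decoding": DecodingResult, "coupling": CouplingResult}


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ParseError(f"header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int = 8) -> bytes:
    for fmt in ("%g", "%.6g", "%.4g", "%.2g"):
        s = fmt % value
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ParseError(f"cannot format {value} in {width} bytes")


def _tal(onset: float, duration: float | None, label: str) -> bytes:
    parts = [("+%.12g" % onset).encode("ascii")]
    if duration is not None:
        parts.append(b"\x15" + ("%.12g" % duration).encode("ascii"))
    parts.append(b"\x14" + label.encode("utf-8") + b"\x14")
    return b"".join(parts) + b"\x00"


def write_edf(recording: Recording, path) -> Path:
    """Write a Recording as EDF+C with trial annotations."""
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9 or spr < 1:
        raise ParseError(
            f"EDF writer requires an integer sampling rate, got {fs}")
    n_samples = recording.n_samples
    n_records = max(1, math.ceil(n_samples / spr))
    nch = recording.n_channels

    # Per-channel physical range: default ±200, widened if exceeded.
    data = np.asarray(recording.samples, dtype=np.float64)
    phys = np.full(nch, _DEFAULT_PHYS_RANGE)
    if n_samples:
        peaks = np.abs(data).max(axis=1)
        over = peaks > _DEFAULT_PHYS_RANGE
        phys[over] = np.ceil(peaks[over] * 1.05)

    # Annotation TALs: record r opens with its timestamp TAL; all trial
    # markers ride in record 0.
    record_tals = []
    for r in range(n_records):
        tal = _tal(float(r), None, "")
        if r == 0:
            for onset, duration, label in recording.annotations:
                tal += _tal(onset, duration, label)
        record_tals.append(tal)
    ann_bytes = max(len(t) for t in record_tals)
    ann_spr = (ann_bytes + 1) // 2 + 1  # int16 samples, headroom

    ns = nch + 1
    header = bytearray()
    header += _field("0", 8)
    header += _field(recording.participant_id or "X", 80)
    header += _field("cobci session", 80)
    header += _field("01.01.85", 8)
    header += _field("00.00.00", 8)
    header += _field(256 * (ns + 1), 8)
    header += _field(f"EDF+C NS={n_samples}", 44)
    header += _field(n_records, 8)
    header += _field("1", 8)
    header += _field(ns, 4)

    labels = list(recording.channel_labels) + [_ANNOTATION_LABEL]
    for lab in labels:
        header += _field(lab, 16)
    header += b" " * 80 * ns  # transducer
    for i in range(ns):
        header += _field("uV" if i < nch else "", 8)
    for i in range(ns):
        header += _num(-phys[i], 8) if i < nch else _num(-1.0, 8)
    for i in range(ns):
        header += _num(phys[i], 8) if i < nch else _num(1.0, 8)
    for _ in range(ns):
        header += _num(_DIG_MIN, 8)
    for _ in range(ns):
        header += _num(_DIG_MAX, 8)
    header += b" " * 80 * ns  # prefiltering
    for i in range(ns):
        header += _field(spr if i < nch else ann_spr, 8)
    header += b" " * 32 * ns  # signal reserved

    # Quantize channels once, pad to whole records.
    scale = (phys * 2) / (_DIG_MAX - _DIG_MIN)
    padded = np.zeros((nch, n_records * spr))
    padded[:, :n_samples] = data
    dig = np.rint((padded + phys[:, None]) / scale[:, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())
            fh.write(record_tals[r].ljust(2 * ann_spr, b"\x00"))
    return path


def _read_exact(fh, n: int, what: str) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise ParseError(f"file truncated while reading {what}")
    return buf


def _parse_number(raw: bytes, what: str) -> float:
    try:
        return float(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise ParseError(f"malformed numeric header field {what}: "
                         f"{raw!r}") from exc


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file written by :func:`write_edf` (or any file
    with one fixed record duration and an optional annotations signal)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = _read_exact(fh, 256, "fixed header")
        patient = head[8:88].decode("ascii", "replace").strip()
        reserved = head[192:236].decode("ascii", "replace")
        n_records = int(_parse_number(head[236:244], "number of records"))
        record_duration = _parse_number(head[244:252], "record duration")
        ns = int(_parse_number(head[252:256], "number of signals"))
        if ns < 1:
            raise ParseError("number of signals must be >= 1")
        if record_duration <= 0:
            raise ParseError("record duration must be positive")

        sig = _read_exact(fh, 256 * ns, "signal headers")

        def col(offset, width, i):
            start = offset * ns + i * width
            return sig[start:start + width]

        labels, pmin, pmax, dmin, dmax, spr = [], [], [], [], [], []
        for i in range(ns):
            labels.append(col(0, 16, i).decode("ascii", "replace").strip())
            pmin.append(_parse_number(col(16 + 80 + 8, 8, i),
                                      f"physical minimum of signal {i}"))
            pmax.append(_parse_number(col(16 + 80 + 16, 8, i),
                                      f"physical maximum of signal {i}"))
            dmin.append(_parse_number(col(16 + 80 + 24, 8, i),
                                      f"digital minimum of signal {i}"))
            dmax.append(_parse_number(col(16 + 80 + 32, 8, i),
                                      f"digital maximum of signal {i}"))
            spr.append(int(_parse_number(col(16 + 80 + 40 + 80, 8, i),
                                         f"samples per record of signal {i}")))
        record_len = sum(spr)
        body = fh.read()
    if len(body) < n_records * record_len * 2:
        raise ParseError(
            f"data section truncated: expected {n_records * record_len * 2} "
            f"bytes, found {len(body)}")

    raw = np.frombuffer(body[:n_records * record_len * 2], dtype="<i2")
    raw = raw.reshape(n_records, record_len)
    offsets = np.cumsum([0] + spr)

    ann_idx = labels.index(_ANNOTATION_LABEL) if _ANNOTATION_LABEL in labels \
        else None
    chan_idx = [i for i in range(ns) if i != ann_idx]
    if not chan_idx:
        raise ParseError("no data signals present")
    rates = {spr[i] / record_duration for i in chan_idx}
    if len(rates) != 1:
        raise ParseError("differing per-signal sampling rates are unsupported")
    fs = rates.pop()

    channels = []
    for i in chan_idx:
        dig = raw[:, offsets[i]:offsets[i + 1]].reshape(-1).astype(np.float64)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        channels.append((dig - dmin[i]) * gain + pmin[i])
    samples = np.vstack(channels)

    # True sample count stashed after the EDF+C tag (records are padded).
    if "NS=" in reserved:
        try:
            true_n = int(reserved.split("NS=")[1].split()[0])
        except (ValueError, IndexError) as exc:
            raise ParseError("malformed NS= tag in reserved field") from exc
        samples = samples[:, :true_n]

    annotations = []
    if ann_idx is not None:
        for r in range(n_records):
            chunk = raw[r, offsets[ann_idx]:offsets[ann_idx + 1]].tobytes()
            for tal in chunk.split(b"\x00"):
                if not tal:
                    continue
                fields = tal.split(b"\x14")
                if len(fields) < 2:
                    continue
                head_f = fields[0]
                lab = fields[1].decode("utf-8", "replace")
                if not lab:
                    continue  # record timestamp TAL
                if b"\x15" in head_f:
                    onset_b, dur_b = head_f.split(b"\x15")
                    duration = _parse_number(dur_b, "annotation duration")
                else:
                    onset_b, duration = head_f, 0.0
                onset = _parse_number(onset_b, "annotation onset")
                annotations.append((onset, duration, lab))

    return Recording(
        participant_id=patient,
        channel_labels=tuple(labels[i] for i in chan_idx),
        sampling_rate=fs,
        samples=samples.astype(np.float32),
        annotations=annotations,
    )


def write_results(results, path) -> Path:
    """Write decoding/coupling results as schema-versioned JSON lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for res in results:
            if isinstance(res, DecodingResult):
                kind = "decoding"
            elif isinstance(res, CouplingResult):
                kind = "coupling"
            else:
                raise SchemaError(f"cannot serialize {type(res).__name__}")
            fh.write(json.dumps({"schema": RESULTS_SCHEMA, "kind": kind,
                                 "data": res.to_dict()}) + "\n")
    return path


def read_results(path) -> list:
    path = Path(path)
    out = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"line {lineno}: invalid JSON") from exc
        if rec.get("schema") != RESULTS_SCHEMA:
            raise SchemaError(
                f"line {lineno}: unsupported schema {rec.get('schema')!r} "
                f"(expected {RESULTS_SCHEMA})")
        kind = rec.get("kind")
        if kind not in _RESULT_KINDS:
            raise SchemaError(f"line {lineno}: unknown result kind {kind!r}")
        out.append(_RESULT_KINDS[kind].from_dict(rec["data"]))
    return out
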