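"""Session server: membership, paradigm synchronization, route-dispatched
analysis of streamed EEG, closed-loop feedback, and archival.

Analyses run through :mod:`cobci.pipeline` on the exact float32 samples
decoded from the wire, so online results are bit-identical to the
offline pipeline on the same data.
"""

from __future__ import annotations

import asyncio
import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .. import decoding, pipeline
from ..errors import CobciError, ProtocolError
from ..synth import Recording, annotation_label
from .messages import (MessageType, SessionMessage, StimulusState,
                       decode_samples)

logger = logging.getLogger(__name__)

__all__ = ["CollabServer", "SessionState", "dispatch_analysis",
           "wall_clock_ms", "counter_clock", "STREAM_LIMIT"]

#: Per-line buffer limit; one message must hold a full encoded trial.
STREAM_LIMIT = 256 * 1024 * 1024


def wall_clock_ms() -> int:
    return int(time.time() * 1000)


def counter_clock(start: int = 0):
    """Deterministic logical clock (for reproducible transcripts)."""
    counter = itertools.count(start)
    return lambda: next(counter)


@dataclass
class SessionState:
    session_id: str
    members: dict = field(default_factory=dict)  # pid -> StreamWriter
    paradigm: dict | None = None
    started: bool = False
    stopped: bool = False
    stimulus: StimulusState | None = None
    trials: dict = field(default_factory=dict)  # pid -> list of trial dicts
    trial_psds: dict = field(default_factory=dict)  # pid -> [(freq, [PSD])]
    results: list = field(default_factory=list)
    transcript: list = field(default_factory=list)
    out_seq: dict = field(default_factory=dict)  # pid -> last seq sent
    in_seq: dict = field(default_factory=dict)  # pid -> last seq received
    archived: bool = False

    def candidates(self, default):
        if self.paradigm and self.paradigm.get("targets"):
            return tuple(float(f) for f in self.paradigm["targets"])
        return default


def _ssvep_route(payload: dict, session: SessionState, server: "CollabServer",
                 participant_id: str) -> dict:
    """Per-trial SSVEP decoding; buffers the trial's epoch PSDs so the
    coupling route can consume them later."""
    samples = decode_samples(payload["samples"])
    rate = float(payload["sampling_rate"])
    labels = tuple(payload["channel_labels"])
    trial_index = int(payload.get("trial_index", 0))
    true_freq = payload.get("true_frequency")
    if session.paradigm:
        want_ch = session.paradigm.get("channel_labels")
        if want_ch and tuple(want_ch) != labels:
            raise ProtocolError("channel labels do not match the paradigm")
        want_rate = session.paradigm.get("sampling_rate")
        if want_rate and float(want_rate) != rate:
            raise ProtocolError("sampling rate does not match the paradigm")
    duration = samples.shape[1] / rate
    label = annotation_label(true_freq) if true_freq is not None else "target:0"
    trial = Recording(
        participant_id=participant_id, channel_labels=labels,
        sampling_rate=rate, samples=samples,
        annotations=[(0.0, duration, label)])
    settings = server.settings_for(session)
    epochs = pipeline.process_trial(trial, settings)
    psds = pipeline.trial_psds(epochs)
    results = []
    for k, psd in enumerate(psds):
        results.append(decoding.decode_individual(
            psd, settings.occipital_channels, settings.candidates,
            true_frequency=true_freq,
            epoch_id=f"{participant_id}/t{trial_index}/e{k}"))
    session.trials.setdefault(participant_id, []).append({
        "trial_index": trial_index, "true_frequency": true_freq,
        "sampling_rate": rate, "channel_labels": list(labels),
        "samples": samples, "duration": duration,
    })
    session.trial_psds.setdefault(participant_id, []).append(
        (true_freq, psds))
    session.results.extend(results)
    predictions = [r.predicted_frequency for r in results]
    majority = max(set(predictions), key=lambda f: (predictions.count(f), -f))
    return {
        "kind": "ssvep",
        "trial_index": trial_index,
        "epochs": [r.to_dict() for r in results],
        "majority_prediction": majority,
    }


def _coupling_route(payload: dict, session: SessionState,
                    server: "CollabServer", participant_id: str) -> dict:
    """Coupling over the buffered trials of every participant pair."""
    from ..coupling import coupling_analysis

    settings = server.settings_for(session)
    target = payload.get("target_frequency")
    targets = ([float(target)] if target is not None
               else list(settings.candidates))
    pids = sorted(session.trial_psds)
    out, errors = [], []
    for a, b in itertools.combinations(pids, 2):
        for f in targets:
            sel_a = [p for tf, p in session.trial_psds[a] if tf == f]
            sel_b = [p for tf, p in session.trial_psds[b] if tf == f]
            if not sel_a or not sel_b:
                sel_a = [p for _tf, p in session.trial_psds[a]]
                sel_b = [p for _tf, p in session.trial_psds[b]]
            try:
                res = coupling_analysis(sel_a, sel_b, f,
                                        participant_pair=(a, b))
            except CobciError as exc:
                errors.append({"pair": [a, b], "target_frequency": f,
                               "error": str(exc)})
                continue
            session.results.append(res)
            out.append(res.to_dict())
    return {"kind": "coupling", "pairs": out, "errors": errors}


def dispatch_analysis(route: str, payload: dict, session: SessionState,
                      server: "CollabServer", participant_id: str) -> dict:
    """Invoke the algorithm registered at ``route``."""
    handler = server.routes.get(route)
    if handler is None:
        raise ProtocolError(f"unknown route {route!r}")
    return handler(payload, session, server, participant_id)


class CollabServer:
    """Asyncio TCP server speaking newline-delimited JSON messages."""

    def __init__(self, host: str = "127.0.0.1", port: int = 0,
                 settings: pipeline.AnalysisSettings | None = None,
                 archive_root=None, clock=wall_clock_ms):
        self.host = host
        self._requested_port = port
        self.settings = settings or pipeline.AnalysisSettings()
        self.archive_root = Path(archive_root) if archive_root else None
        self.clock = clock
        self.sessions: dict[str, SessionState] = {}
        self.routes = {
            "/analysis/ssvep": _ssvep_route,
            "/analysis/coupling": _coupling_route,
        }
        self._server: asyncio.AbstractServer | None = None

    # -- lifecycle -----------------------------------------------------

    async def start(self) -> None:
        try:
            self._server = await asyncio.start_server(
                self._handle_connection, self.host, self._requested_port,
                limit=STREAM_LIMIT)
        except OSError as exc:
            raise ProtocolError(
                f"cannot bind {self.host}:{self._requested_port}: {exc}"
            ) from exc

    @property
    def port(self) -> int:
        if self._server is None:
            raise ProtocolError("server is not running")
        return self._server.sockets[0].getsockname()[1]

    async def stop(self) -> None:
        """Shut down, flushing archives for every session."""
        if self.archive_root is not None:
            from .archive import archive_session
            for session in self.sessions.values():
                if not session.archived:
                    archive_session(session, self.archive_root / session.session_id,
                                    settings=self.settings)
                    session.archived = True
        if self._server is not None:
            self._server.close()
            await self._server.wait_closed()
            self._server = None

    def register_route(self, route: str, handler) -> None:
        self.routes[route] = handler

    def settings_for(self, session: SessionState) -> pipeline.AnalysisSettings:
        cand = session.candidates(self.settings.candidates)
        if cand == self.settings.candidates:
            return self.settings
        return pipeline.AnalysisSettings(
            rate=self.settings.rate, band=self.settings.band,
            epoch_duration=self.settings.epoch_duration,
            occipital_channels=self.settings.occipital_channels,
            candidates=cand)

    # -- messaging -----------------------------------------------------

    def _send(self, session: SessionState, writer, pid: str,
              message_type: MessageType, route: str = "",
              payload: dict | None = None) -> None:
        seq = session.out_seq.get(pid, 0) + 1
        session.out_seq[pid] = seq
        msg = SessionMessage(
            message_type=message_type, session_id=session.session_id,
            participant_id=pid, sequence_number=seq,
            timestamp_ms=self.clock(), route=route, payload=payload or {})
        session.transcript.append({"direction": "out", "peer": pid,
                                   "message": msg.to_dict()})
        writer.write(msg.to_line())

    def _broadcast(self, session: SessionState, message_type: MessageType,
                   route: str = "", payload: dict | None = None) -> None:
        for pid, writer in session.members.items():
            self._send(session, writer, pid, message_type, route, payload)

    # -- connection handling -------------------------------------------

    async def _handle_connection(self, reader, writer) -> None:
        bound: tuple[str, str] | None = None  # (session_id, participant_id)
        try:
            while True:
                line = await reader.readline()
                if not line:
                    break
                if not line.strip():
                    continue
                try:
                    msg = SessionMessage.from_line(line)
                except ProtocolError as exc:
                    self._reply_error(bound, writer, str(exc))
                    continue
                bound = await self._handle_message(msg, writer, bound)
                await writer.drain()
        except (ConnectionError, asyncio.IncompleteReadError):
            logger.info("connection lost")
        finally:
            if bound is not None:
                session = self.sessions.get(bound[0])
                if session is not None:
                    session.members.pop(bound[1], None)
            writer.close()

    def _reply_error(self, bound, writer, reason: str) -> None:
        if bound is not None:
            session = self.sessions[bound[0]]
            self._send(session, writer, bound[1], MessageType.ERROR,
                       payload={"reason": reason})
        else:
            msg = SessionMessage(
                message_type=MessageType.ERROR, session_id="",
                participant_id="", sequence_number=1,
                timestamp_ms=self.clock(), payload={"reason": reason})
            writer.write(msg.to_line())

    async def _handle_message(self, msg: SessionMessage, writer, bound):
        session = self.sessions.setdefault(
            msg.session_id, SessionState(session_id=msg.session_id))
        session.transcript.append({"direction": "in",
                                   "peer": msg.participant_id,
                                   "message": msg.to_dict()})
        pid = msg.participant_id

        last = session.in_seq.get(pid, 0)
        if msg.sequence_number <= last:
            self._send(session, writer, pid, MessageType.ERROR, payload={
                "reason": f"sequence number {msg.sequence_number} is not "
                          f"greater than {last}"})
            return bound
        session.in_seq[pid] = msg.sequence_number

        mtype = msg.message_type
        if mtype == MessageType.JOIN:
            session.members[pid] = writer
            self._broadcast(session, MessageType.ACK, payload={
                "event": "join", "joined": pid,
                "participants": sorted(session.members)})
            return (msg.session_id, pid)

        if bound is None or pid not in session.members:
            self._send(session, writer, pid, MessageType.ERROR,
                       payload={"reason": "JOIN the session first"})
            return bound

        if mtype == MessageType.START_PARADIGM:
            session.paradigm = dict(msg.payload)
            targets = session.paradigm.get("targets") or list(
                self.settings.candidates)
            session.stimulus = StimulusState.default(targets)
            session.stimulus.active = True
            session.started = True
            self._broadcast(session, MessageType.START_PARADIGM,
                            payload=session.paradigm)
            self._broadcast(session, MessageType.STIM_SYNC,
                            payload=session.stimulus.to_dict())
        elif mtype == MessageType.EEG_DATA:
            if not session.started:
                self._send(session, writer, pid, MessageType.ERROR,
                           payload={"reason": "paradigm not started"})
                return bound
            t0 = time.perf_counter()
            try:
                result = dispatch_analysis(msg.route, msg.payload, session,
                                           self, pid)
            except (CobciError, KeyError) as exc:
                self._send(session, writer, pid, MessageType.ERROR,
                           payload={"reason": str(exc)})
                return bound
            latency_ms = (time.perf_counter() - t0) * 1000.0
            logger.debug("route %s handled in %.2f ms", msg.route, latency_ms)
            self._send(session, writer, pid, MessageType.ANALYSIS_RESULT,
                       route=msg.route, payload=result)
            if result.get("kind") == "ssvep":
                self._send(session, writer, pid, MessageType.FEEDBACK,
                           route=msg.route, payload={
                               "highlight": result["majority_prediction"],
                               "trial_index": result["trial_index"]})
        elif mtype == MessageType.STOP_PARADIGM:
            if session.started and not session.stopped:
                if len(session.trial_psds) >= 2:
                    result = _coupling_route({}, session, self, pid)
                    self._broadcast(session, MessageType.ANALYSIS_RESULT,
                                    route="/analysis/coupling", payload=result)
                session.stopped = True
                if session.stimulus is not None:
                    session.stimulus.active = False
                if self.archive_root is not None and not session.archived:
                    from .archive import archive_session
                    archive_session(
                        session, self.archive_root / session.session_id,
                        settings=self.settings)
                    session.archived = True
            self._broadcast(session, MessageType.STOP_PARADIGM,
                            payload={"stopped_by": pid})
        elif mtype == MessageType.ERROR:
            logger.warning("client %s reported: %s", pid,
                           msg.payload.get("reason"))
        else:
            self._send(session, writer, pid, MessageType.ERROR, payload={
                "reason": f"clients may not send {mtype.value}"})
        return bound

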