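"""Simulated client: streams a Recording trial-by-trial, applies
closed-loop feedback to its local stimulus state, and records a full
ordered transcript."""

from __future__ import annotations

import asyncio
from dataclasses import dataclass, field

from ..errors import ProtocolError
from ..synth import Recording, parse_annotation_label
from . import server as server_mod
from .messages import (MessageType, SessionMessage, StimulusState,
                       encode_samples)

__all__ = ["ClientTranscript", "simulate_client", "run_group_session",
           "highlight_policy"]


def highlight_policy(stimulus: StimulusState, result_payload: dict) -> None:
    """Feedback policy: highlight (and enlarge) the decoded target."""
    pick = result_payload.get("majority_prediction")
    for freq, desc in stimulus.targets.items():
        hit = (freq == pick)
        desc["highlighted"] = hit
        desc["size"] = 1.25 if hit else 1.0


@dataclass
class ClientTranscript:
    participant_id: str
    messages: list = field(default_factory=list)  # {"direction", "message"}
    stimulus: StimulusState | None = None
    analysis_payloads: list = field(default_factory=list)
    feedback_log: list = field(default_factory=list)
    truncated: bool = False

    def sent(self):
        return [m["message"] for m in self.messages
                if m["direction"] == "sent"]

    def received(self):
        return [m["message"] for m in self.messages
                if m["direction"] == "received"]

    def received_of_type(self, message_type: MessageType):
        return [m for m in self.received()
                if m["message_type"] == message_type.value]


class _Connection:
    def __init__(self, reader, writer, transcript: ClientTranscript,
                 session_id: str, participant_id: str, clock):
        self.reader = reader
        self.writer = writer
        self.transcript = transcript
        self.session_id = session_id
        self.participant_id = participant_id
        self.clock = clock
        self._seq = 0

    async def send(self, message_type: MessageType, route: str = "",
                   payload: dict | None = None) -> None:
        self._seq += 1
        msg = SessionMessage(
            message_type=message_type, session_id=self.session_id,
            participant_id=self.participant_id, sequence_number=self._seq,
            timestamp_ms=self.clock(), route=route, payload=payload or {})
        self.transcript.messages.append(
            {"direction": "sent", "message": msg.to_dict()})
        self.writer.write(msg.to_line())
        await self.writer.drain()

    async def recv(self) -> SessionMessage:
        line = await self.reader.readline()
        if not line:
            raise ConnectionError("server closed the connection")
        msg = SessionMessage.from_line(line)
        self.transcript.messages.append(
            {"direction": "received", "message": msg.to_dict()})
        return msg

    async def recv_until(self, predicate) -> SessionMessage:
        while True:
            msg = await self.recv()
            if msg.message_type == MessageType.ERROR:
                raise ProtocolError(
                    f"server error: {msg.payload.get('reason')}")
            if predicate(msg):
                return msg


async def simulate_client(host: str, port: int, session_id: str,
                          participant_id: str, recording: Recording,
                          feedback_policy=None,
                          route: str = "/analysis/ssvep",
                          leader: bool = False,
                          expected_participants: int = 1,
                          barrier: asyncio.Barrier | None = None,
                          paradigm: dict | None = None,
                          clock=server_mod.wall_clock_ms,
                          wait_to_join: asyncio.Event | None = None,
                          joined: asyncio.Event | None = None
                          ) -> ClientTranscript:
    """Join a session, stream every annotated trial, apply feedback, and
    return the ordered transcript.

    The ``leader`` starts and stops the paradigm; with multiple clients a
    shared ``barrier`` must be passed so STOP is only sent once everyone
    has finished streaming.
    """
    transcript = ClientTranscript(participant_id=participant_id)
    reader, writer = await asyncio.open_connection(
        host, port, limit=server_mod.STREAM_LIMIT)
    conn = _Connection(reader, writer, transcript, session_id,
                       participant_id, clock)
    try:
        if wait_to_join is not None:
            await wait_to_join.wait()
        await conn.send(MessageType.JOIN)
        while True:
            msg = await conn.recv_until(
                lambda m: m.message_type == MessageType.ACK)
            members = msg.payload.get("participants", [])
            if participant_id not in members:
                continue
            if joined is not None and not joined.is_set():
                joined.set()
            if len(members) >= expected_participants:
                break

        if paradigm is None:
            targets = sorted({parse_annotation_label(lab)
                              for _o, _d, lab in recording.annotations})
            paradigm = {
                "paradigm_type": "ssvep",
                "targets": targets,
                "sampling_rate": recording.sampling_rate,
                "channel_labels": list(recording.channel_labels),
                "trial_duration": recording.annotations[0][1]
                if recording.annotations else None,
            }
        if leader:
            await conn.send(MessageType.START_PARADIGM, payload=paradigm)
        await conn.recv_until(
            lambda m: m.message_type == MessageType.START_PARADIGM)
        sync = await conn.recv_until(
            lambda m: m.message_type == MessageType.STIM_SYNC)
        transcript.stimulus = StimulusState.from_dict(sync.payload)

        for trial_index, (onset, duration, label) in enumerate(
                recording.annotations):
            fs = recording.sampling_rate
            start = int(round(onset * fs))
            stop = start + int(round(duration * fs))
            payload = {
                "samples": encode_samples(recording.samples[:, start:stop]),
                "channel_labels": list(recording.channel_labels),
                "sampling_rate": fs,
                "n_channels": recording.n_channels,
                "n_samples": stop - start,
                "trial_index": trial_index,
                "true_frequency": parse_annotation_label(label),
            }
            await conn.send(MessageType.EEG_DATA, route=route,
                            payload=payload)
            result = await conn.recv_until(
                lambda m: m.message_type == MessageType.ANALYSIS_RESULT
                and m.payload.get("kind") == "ssvep"
                and m.payload.get("trial_index") == trial_index)
            transcript.analysis_payloads.append(result.payload)
            feedback = await conn.recv_until(
                lambda m: m.message_type == MessageType.FEEDBACK)
            if feedback_policy is not None:
                feedback_policy(transcript.stimulus, result.payload)
                transcript.feedback_log.append({
                    "trial_index": trial_index,
                    "stimulus": transcript.stimulus.to_dict(),
                })

        if barrier is not None:
            await barrier.wait()
        if leader:
            await conn.send(MessageType.STOP_PARADIGM)
        stop_msg = await conn.recv_until(
            lambda m: m.message_type == MessageType.STOP_PARADIGM)
        del stop_msg
        for m in transcript.received():
            if (m["message_type"] == MessageType.ANALYSIS_RESULT.value
                    and m["payload"].get("kind") == "coupling"):
                transcript.analysis_payloads.append(m["payload"])
    except (ConnectionError, asyncio.IncompleteReadError):
        transcript.truncated = True
    finally:
        writer.close()
        try:
            await writer.wait_closed()
        except (ConnectionError, OSError):
            pass
    return transcript


def run_group_session(recordings: list[Recording],
                      settings=None,
                      session_id: str = "session-0",
                      feedback_policy=None,
                      archive_root=None,
                      deterministic: bool = False) -> dict:
    """Run a complete in-process session: start a server on an ephemeral
    port, stream every recording concurrently, stop, and shut down.

    Returns ``{"transcripts": {pid: ClientTranscript}, "results": [...],
    "session": SessionState}``.
    """
    from .. import pipeline

    settings = settings or pipeline.AnalysisSettings()
    # Deterministic mode: constant logical clock and serialized joins, so
    # transcripts and archives are byte-stable across reruns.
    clock = (lambda: 0) if deterministic else server_mod.wall_clock_ms

    async def _run():
        srv = server_mod.CollabServer(settings=settings,
                                      archive_root=archive_root, clock=clock)
        await srv.start()
        barrier = asyncio.Barrier(len(recordings))
        gates = [asyncio.Event() for _ in recordings]
        gates[0].set()
        tasks = [
            simulate_client(
                srv.host, srv.port, session_id, rec.participant_id, rec,
                feedback_policy=feedback_policy, leader=(i == 0),
                expected_participants=len(recordings), barrier=barrier,
                clock=clock,
                wait_to_join=gates[i] if deterministic else None,
                joined=(gates[i + 1] if deterministic
                        and i + 1 < len(recordings) else None))
            for i, rec in enumerate(recordings)
        ]
        transcripts = await asyncio.gather(*tasks)
        session = srv.sessions[session_id]
        await srv.stop()
        return transcripts, session

    transcripts, session = asyncio.run(_run())
    return {
        "transcripts": {t.participant_id: t for t in transcripts},
        "results": list(session.results),
        "session": session,
    }
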