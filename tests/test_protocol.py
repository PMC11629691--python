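import asyncio
import json

import numpy as np
import pytest

from cobci import pipeline
from cobci.decoding import DecodingResult
from cobci.coupling import CouplingResult
from cobci.protocol import (CollabServer, MessageType, SessionMessage,
                            StimulusState, decode_samples, encode_samples,
                            read_archive, run_group_session, simulate_client)
from cobci.protocol.client import highlight_policy
from cobci.protocol.server import STREAM_LIMIT, counter_clock
from cobci.synth import SyntheticConfig, generate_group_session


@pytest.fixture
def group_recordings():
    cfg = SyntheticConfig(seed=3, n_participants=2, trials_per_target=2,
                          trial_duration=3.0, sampling_rate=512.0,
                          noise_amplitude=1.0, coupling_gain=1.0)
    return cfg, generate_group_session(cfg)


@pytest.fixture
def noiseless_recordings():
    cfg = SyntheticConfig(seed=1, n_participants=2, trials_per_target=1,
                          trial_duration=2.0, sampling_rate=512.0,
                          noise_amplitude=0.0)
    return cfg, generate_group_session(cfg)


def _settings(cfg):
    return pipeline.AnalysisSettings(candidates=cfg.target_frequencies)


class _RawClient:
    """Hand-driven connection for error-contract tests."""

    def __init__(self, reader, writer):
        self.reader, self.writer = reader, writer
        self.seq = 0

    async def send(self, message_type, session_id="s", participant_id="p",
                   route="", payload=None, seq=None):
        if seq is None:
            self.seq += 1
            seq = self.seq
        msg = SessionMessage(message_type=message_type, session_id=session_id,
                             participant_id=participant_id,
                             sequence_number=seq, timestamp_ms=0, route=route,
                             payload=payload or {})
        self.writer.write(msg.to_line())
        await self.writer.drain()

    async def recv(self):
        line = await asyncio.wait_for(self.reader.readline(), timeout=10)
        return SessionMessage.from_line(line)


async def _with_server(fn, **server_kw):
    srv = CollabServer(clock=counter_clock(), **server_kw)
    await srv.start()
    try:
        reader, writer = await asyncio.open_connection(
            srv.host, srv.port, limit=STREAM_LIMIT)
        try:
            return await fn(_RawClient(reader, writer), srv)
        finally:
            writer.close()
    finally:
        await srv.stop()


class TestSampleCodec:
    def test_roundtrip_bit_exact(self):
        x = np.random.default_rng(0).normal(size=(4, 100)).astype(np.float32)
        assert np.array_equal(decode_samples(encode_samples(x)), x)

    def test_shape_mismatch_rejected(self):
        from cobci.errors import ProtocolError
        payload = encode_samples(np.zeros((2, 4), dtype=np.float32))
        payload["shape"] = [3, 4]
        with pytest.raises(ProtocolError, match="shape"):
            decode_samples(payload)


class TestServerContracts:
    def test_join_ack_lists_members(self):
        async def scenario(c, srv):
            await c.send(MessageType.JOIN, participant_id="a")
            ack = await c.recv()
            assert ack.message_type == MessageType.ACK
            assert ack.payload["participants"] == ["a"]

            r2, w2 = await asyncio.open_connection(srv.host, srv.port,
                                                   limit=STREAM_LIMIT)
            c2 = _RawClient(r2, w2)
            await c2.send(MessageType.JOIN, participant_id="b")
            ack_b = await c2.recv()
            ack_a = await c.recv()
            assert ack_b.payload["participants"] == ["a", "b"]
            assert ack_a.payload["participants"] == ["a", "b"]
            w2.close()

        asyncio.run(_with_server(scenario))

    def test_eeg_before_start_rejected(self):
        async def scenario(c, srv):
            await c.send(MessageType.JOIN)
            await c.recv()
            await c.send(MessageType.EEG_DATA, route="/analysis/ssvep",
                         payload={})
            err = await c.recv()
            assert err.message_type == MessageType.ERROR
            assert err.payload["reason"] == "paradigm not started"

        asyncio.run(_with_server(scenario))

    def test_unknown_route_rejected(self):
        async def scenario(c, srv):
            await c.send(MessageType.JOIN)
            await c.recv()
            await c.send(MessageType.START_PARADIGM,
                         payload={"targets": [8.0, 10.0, 13.0]})
            await c.recv()  # START broadcast
            await c.recv()  # STIM_SYNC
            await c.send(MessageType.EEG_DATA, route="/analysis/foo",
                         payload={})
            err = await c.recv()
            assert err.message_type == MessageType.ERROR
            assert "unknown route" in err.payload["reason"]

        asyncio.run(_with_server(scenario))

    def test_malformed_line_keeps_connection_alive(self):
        async def scenario(c, srv):
            c.writer.write(b"this is not json\n")
            await c.writer.drain()
            err = await c.recv()
            assert err.message_type == MessageType.ERROR
            await c.send(MessageType.JOIN)
            ack = await c.recv()
            assert ack.message_type == MessageType.ACK

        asyncio.run(_with_server(scenario))

    def test_non_monotone_sequence_rejected(self):
        async def scenario(c, srv):
            await c.send(MessageType.JOIN, seq=5)
            await c.recv()
            await c.send(MessageType.STOP_PARADIGM, seq=5)
            err = await c.recv()
            assert err.message_type == MessageType.ERROR
            assert "sequence" in err.payload["reason"]

        asyncio.run(_with_server(scenario))

    def test_noiseless_trial_decoded_online(self, noiseless_recordings):
        cfg, (rec, _other) = noiseless_recordings

        async def scenario(c, srv):
            await c.send(MessageType.JOIN)
            await c.recv()
            await c.send(MessageType.START_PARADIGM,
                         payload={"targets": list(cfg.target_frequencies)})
            await c.recv(); await c.recv()
            onset, duration, _label = rec.annotations[0]
            await c.send(MessageType.EEG_DATA, route="/analysis/ssvep",
                         payload={
                             "samples": encode_samples(
                                 rec.samples[:, :int(duration * 512)]),
                             "channel_labels": list(rec.channel_labels),
                             "sampling_rate": 512.0,
                             "trial_index": 0,
                             "true_frequency": 8.0,
                         })
            result = await c.recv()
            assert result.message_type == MessageType.ANALYSIS_RESULT
            assert result.payload["majority_prediction"] == 8.0
            feedback = await c.recv()
            assert feedback.message_type == MessageType.FEEDBACK
            assert feedback.payload["highlight"] == 8.0

        asyncio.run(_with_server(scenario))


class TestOnlineOfflineEquivalence:
    def test_decoding_and_coupling_bit_identical(self, group_recordings):
        cfg, recs = group_recordings
        settings = _settings(cfg)
        live = run_group_session(recs, settings=settings, deterministic=True)

        online_dec = {r.epoch_id: r.to_dict() for r in live["results"]
                      if isinstance(r, DecodingResult)}
        offline_dec = {r.epoch_id: r.to_dict() for rec in recs
                       for r in pipeline.decode_recording(rec, settings)}
        assert online_dec == offline_dec

        online_coup = [r.to_dict() for r in live["results"]
                       if isinstance(r, CouplingResult)]
        offline_coup = [pipeline.coupling_from_recordings(
            recs[0], recs[1], f, settings).to_dict()
            for f in cfg.target_frequencies]
        assert online_coup == offline_coup

    def test_sequence_numbers_gapless(self, group_recordings):
        cfg, recs = group_recordings
        live = run_group_session(recs, settings=_settings(cfg),
                                 deterministic=True)
        for t in live["transcripts"].values():
            sent = [m["sequence_number"] for m in t.sent()]
            assert sent == list(range(1, len(sent) + 1))
            recv = [m["sequence_number"] for m in t.received()]
            assert recv == sorted(recv)
            assert recv == list(range(recv[0], recv[0] + len(recv)))

    def test_stim_sync_identical_across_clients(self, group_recordings):
        cfg, recs = group_recordings
        live = run_group_session(recs, settings=_settings(cfg),
                                 deterministic=True)
        syncs = []
        for t in live["transcripts"].values():
            syncs.append([m["payload"] for m in
                          t.received_of_type(MessageType.STIM_SYNC)])
        assert syncs[0] == syncs[1]
        assert len(syncs[0]) == 1


class TestFeedback:
    def test_identity_policy_leaves_stimulus_unchanged(self,
                                                       noiseless_recordings):
        cfg, recs = noiseless_recordings
        live = run_group_session(recs, settings=_settings(cfg),
                                 feedback_policy=None, deterministic=True)
        for t in live["transcripts"].values():
            baseline = StimulusState.default(cfg.target_frequencies)
            baseline.active = True
            assert t.stimulus.to_dict() == baseline.to_dict()

    def test_highlight_policy_tracks_true_target_noiseless(
            self, noiseless_recordings):
        cfg, recs = noiseless_recordings
        live = run_group_session(recs, settings=_settings(cfg),
                                 feedback_policy=highlight_policy,
                                 deterministic=True)
        for t in live["transcripts"].values():
            assert len(t.feedback_log) == len(recs[0].annotations)
            for entry, (_, _, label) in zip(t.feedback_log,
                                            recs[0].annotations):
                true_f = float(label.split(":")[1])
                stim = StimulusState.from_dict(entry["stimulus"])
                highlighted = [f for f, d in stim.targets.items()
                               if d["highlighted"]]
                assert highlighted == [true_f]


class TestArchive:
    def test_roundtrip_results_and_samples(self, group_recordings, tmp_path):
        cfg, recs = group_recordings
        live = run_group_session(recs, settings=_settings(cfg),
                                 archive_root=tmp_path, deterministic=True)
        arc = read_archive(tmp_path / "session-0")

        live_results = sorted((r.to_dict() for r in live["results"]),
                              key=json.dumps)
        arch_results = sorted((r.to_dict() for r in arc["results"]),
                              key=json.dumps)
        assert live_results == arch_results

        for rec in recs:
            back = arc["recordings"][rec.participant_id]
            assert back.n_samples == rec.n_samples
            assert back.channel_labels == rec.channel_labels
            # streamed float32 samples survive within EDF quantization
            assert np.abs(back.samples - rec.samples).max() < 0.01

        assert arc["manifest"]["participants"] == ["P00", "P01"]
        assert len(arc["messages"]) > 0

    def test_empty_session_archives_manifest(self, tmp_path):
        async def scenario(c, srv):
            await c.send(MessageType.JOIN, participant_id="solo")
            await c.recv()

        asyncio.run(_with_server(scenario, archive_root=tmp_path))
        arc = read_archive(tmp_path / "s")
        assert arc["manifest"]["participants"] == ["solo"]
        assert arc["results"] == []
        assert arc["recordings"] == {}

    def test_missing_manifest_rejected(self, tmp_path):
        from cobci.errors import ParseError
        with pytest.raises(ParseError, match="manifest"):
            read_archive(tmp_path)


class TestCustomRoutes:
    def test_registered_route_invoked(self, noiseless_recordings):
        cfg, (rec, _b) = noiseless_recordings

        def echo_route(payload, session, server, participant_id):
            return {"kind": "echo", "participant": participant_id,
                    "got": sorted(payload)}

        async def scenario(c, srv):
            srv.register_route("/analysis/echo", echo_route)
            await c.send(MessageType.JOIN, participant_id="p")
            await c.recv()
            await c.send(MessageType.START_PARADIGM, payload={})
            await c.recv(); await c.recv()
            await c.send(MessageType.EEG_DATA, route="/analysis/echo",
                         payload={"x": 1})
            result = await c.recv()
            assert result.payload == {"kind": "echo", "participant": "p",
                                      "got": ["x"]}

        asyncio.run(_with_server(scenario))
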