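"""Session archival: EEG as EDF, transcript and results as JSON lines,
paradigm/stimulus configuration as JSON.  A read-back reconstructs all
three."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..errors import ParseError
from ..synth import Recording, annotation_label

__all__ = ["archive_session", "read_archive"]

MANIFEST_NAME = "manifest.json"
TRANSCRIPT_NAME = "transcript.jsonl"
RESULTS_NAME = "results.jsonl"


def _recording_from_trials(pid: str, trials: list) -> Recording | None:
    if not trials:
        return None
    labels = tuple(trials[0]["channel_labels"])
    rate = trials[0]["sampling_rate"]
    chunks, annotations, onset = [], [], 0.0
    for trial in trials:
        chunks.append(np.asarray(trial["samples"], dtype=np.float32))
        freq = trial.get("true_frequency")
        if freq is not None:
            annotations.append((onset, trial["duration"],
                                annotation_label(freq)))
        onset += trial["duration"]
    return Recording(participant_id=pid, channel_labels=labels,
                     sampling_rate=rate,
                     samples=np.concatenate(chunks, axis=1),
                     annotations=annotations)


def archive_session(session, directory, settings=None) -> Path:
    """Write a session's EEG, transcript, results and configuration."""
    from .. import io_formats

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ParseError(f"cannot create archive directory: {exc}") from exc

    eeg_files = {}
    for pid in sorted(session.trials):
        rec = _recording_from_trials(pid, session.trials[pid])
        if rec is not None:
            path = directory / f"{pid}.edf"
            io_formats.write_edf(rec, path)
            eeg_files[pid] = path.name

    # Canonical ordering: concurrent clients interleave
    # nondeterministically, so the archive sorts by (peer, direction,
    # sequence number) — lossless, and byte-stable across reruns.
    transcript = sorted(
        session.transcript,
        key=lambda e: (e["peer"], e["direction"],
                       e["message"]["sequence_number"]))
    with open(directory / TRANSCRIPT_NAME, "w") as fh:
        for entry in transcript:
            fh.write(json.dumps(entry, separators=(",", ":")) + "\n")

    def _result_key(res):
        d = res.to_dict()
        if "epoch_id" in d:
            return (0, d["epoch_id"], "")
        return (1, "/".join(d["participant_pair"]),
                d["target_frequency"])

    io_formats.write_results(sorted(session.results, key=_result_key),
                             directory / RESULTS_NAME)

    manifest = {
        "session_id": session.session_id,
        "participants": sorted(set(session.trials)
                               | set(session.out_seq)),
        "paradigm": session.paradigm,
        "stimulus": session.stimulus.to_dict() if session.stimulus else None,
        "eeg_files": eeg_files,
        "analysis_settings": settings.to_dict() if settings else None,
    }
    (directory / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return directory


def read_archive(directory) -> dict:
    """Load a session archive back: manifest, recordings, transcript
    messages, and results."""
    from .. import io_formats

    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise ParseError(f"no {MANIFEST_NAME} in {directory}")
    manifest = json.loads(manifest_path.read_text())

    recordings = {}
    for pid, name in (manifest.get("eeg_files") or {}).items():
        recordings[pid] = io_formats.read_edf(directory / name)

    messages = []
    transcript_path = directory / TRANSCRIPT_NAME
    if transcript_path.exists():
        for line in transcript_path.read_text().splitlines():
            if line.strip():
                messages.append(json.loads(line))

    results = []
    results_path = directory / RESULTS_NAME
    if results_path.exists():
        results = io_formats.read_results(results_path)

    return {"manifest": manifest, "recordings": recordings,
            "messages": messages, "results": results}
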