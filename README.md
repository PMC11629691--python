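# cobci

Collaborative SSVEP brain-computer interface toolkit — a hardware-free
analysis and collaboration stack for multi-user EEG experiments:

- **`cobci.synth`** — synthetic multi-participant SSVEP EEG: occipital
  sinusoids at 8/10/13 Hz flicker targets embedded in 1/f + white noise,
  with a tunable broadband component shared across participants that
  induces inter-brain band-power coupling (`coupling_gain`). Fully
  deterministic per `(seed, participant, trial)` substream.
- **`cobci.preprocessing`** — resample to 512 Hz (polyphase, anti-aliased),
  zero-phase 4–45 Hz Butterworth band-pass, segmentation into 1-s epochs
  aligned to trial annotations.
- **`cobci.spectral`** — Welch PSD (default: single full-length Hann
  segment, 1 Hz grid) and nearest-bin band-power lookup.
- **`cobci.decoding`** — individual decoding (argmax over candidate
  frequencies of band power averaged over O1/O2/Oz) and collaborative
  decoding (grand mean over channels × participants); recognition
  accuracy, Cohen's d, and an II/CI/CC regime benchmark.
- **`cobci.coupling`** — inter-brain coupling: per-trial Pearson
  correlation of two participants' channel-wise band-power vectors,
  Fisher-Z aggregation over trials, one-sided normal-theory p-value with
  SE = 1/√(m·(n_channels − 3)).
- **`cobci.protocol`** — an asyncio TCP session server speaking
  newline-delimited JSON (JOIN / START_PARADIGM / STIM_SYNC / EEG_DATA /
  ANALYSIS_RESULT / FEEDBACK / STOP_PARADIGM), with route-dispatched
  analyses (`/analysis/ssvep`, `/analysis/coupling`, user-registrable),
  closed-loop stimulus feedback, simulated clients, and lossless session
  archives (EDF + JSONL). Streamed results are bit-identical to the
  offline pipeline on the same samples.
- **`cobci.io_formats`** — EDF+C reader/writer (16-bit quantization,
  ±200 µV default physical range, EDF+ annotations) and schema-versioned
  JSONL result files.

## CLI

```bash
cobci simulate  --seed 0 --participants 2 --coupling-gain 1 --out sess/
cobci decode    --session sess/ [--collaborative] --out results.jsonl
cobci couple    --session sess/ --target 8 --out coupling.json
cobci benchmark --seed 0 --noise 5 --replicates 20 --trials 3
cobci serve     --port 8765 --archive archives/
cobci client    --port 8765 --edf sess/P00.edf --leader
cobci demo      --seed 0 --out demo/
```

`cobci demo` runs a complete 2-participant session end-to-end (simulate
→ stream through an in-process server → decode + couple offline →
archive) and verifies that online and offline results match; its output
is byte-identical across runs with the same seed.

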