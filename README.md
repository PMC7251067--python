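# rtpeth

Streaming spike detection and real-time peri-event time histograms
(PETH) for extracellular electrophysiology, rebuilt as a headless,
fully testable library and CLI. The package covers the complete
online chain — packet ingestion, ring-buffered sample collection,
event-aligned threshold detection with censoring, and PETH
accumulation — together with the offline validation chain (zero-phase
Butterworth band-pass filtering, tetrode-wide spike merging with
largest-spike censoring, cross-correlation PETH, online/offline
concordance statistics and experiment-time accounting) and a synthetic
extracellular-recording simulator that provides ground truth for every
algorithm.

## Modules

| module | role |
| --- | --- |
| `rtpeth.stream_protocol` | JSON-lines wire format (`opeth-jsonl/1`): sample packets, TTL events, heartbeats; encode/decode and file replay |
| `rtpeth.collector` | ring buffer, trigger-event queue, event-aligned ROI extraction, display decimation |
| `rtpeth.spike_detect` | threshold-crossing detection with holdoff/censoring, waveform extraction, channel-range parsing |
| `rtpeth.peth` | event-loop PETH accumulator, channel grouping, binary cross-correlation PETH |
| `rtpeth.offline_validation` | zero-phase band-pass, merge+censor, light-response criterion, concordance tables, time-savings accounting |
| `rtpeth.simulator` | synthetic recordings: noise, spike/artifact templates, pulse trains with duty cycle, behavioral sessions, ground truth |
| `rtpeth.cli_config` / `rtpeth.cli` | per-subject ini persistence and the `rtpeth` command-line entry points |

## CLI

```sh
# generate a synthetic tagged recording as a replayable stream file
rtpeth simulate --seed 1 --duration 10 --out stream.jsonl

# run the online detection chain over it
rtpeth detect stream.jsonl --out spikes.csv --events-out events.csv

# accumulate a histogram from the spike/event CSVs
rtpeth peth --spikes spikes.csv --events events.csv --out peth.csv

# online vs offline concordance on synthetic sessions
rtpeth validate --seed 0 --sessions 12 --out concordance.csv

# experiment-time savings report (bundled study data by default)
rtpeth timesave
```

`rtpeth detect` also accepts raw little-endian int16 recordings with a
JSON metadata sidecar (see `rtpeth.rawio`).

## Notes

* All computation is transport-free: streams are plain JSON-lines
  files, and live transports can be layered on without touching core
  logic.
* Timestamps are 0-based integer sample counts on the acquisition
  clock; channel ids are 1-based in user-facing text and files,
  0-based internally.
* The simulator is deterministic: identical configuration and seed
  give bit-identical recordings.
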