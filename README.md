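# spikeramp

Spike-train analysis of tonic and phasic neural value coding in reward
value-ramp tasks, together with a synthetic-data generator that emulates the
task and the firing phenomenology, so the whole pipeline is testable without
recorded data.

The task model is a Pavlovian procedure with three blocked conditions: the
cued reward value ramps up, ramps down (0.082 ml/s between 0.1 and 0.3 ml,
stopping at a random time uniform on 0–2450 ms), or stays fixed (four cue
types at 25% each). The analysis quantifies

* **tonic activity** — the slope of binned firing rate (200 ms bins,
  650–2450 ms after cue onset, stop-truncated) against time;
* **phasic value coding** — regressions of cue-window (100–400 ms) rates on
  cued value and of stop-window (150–500 ms) rates on the fixed reward value
  (small/medium/large trial groups);
* **firing modes** — ISI-based burst detection (onset ≤ 80 ms, offset
  > 160 ms) and a neuron-resampling bootstrap (1000 repetitions, >975
  criterion) comparing burst and non-burst baseline-subtracted rates over
  initial/middle/late periods;
* supporting checks — spike density functions (Gaussian kernel, σ = 15 ms),
  baseline rates (500–0 ms before fixation onset), saccade detection
  (40°/s threshold at 240 Hz), gaze–rate correlations, lick-aligned
  activity, and a logistic choice model on value differences.

## Layout

| module | contents |
| --- | --- |
| `spikeramp.task` | task constants, value trajectories, trial sampling, reward expectations |
| `spikeramp.synth` | ground-truth neurons, spike/gaze/lick/choice simulation |
| `spikeramp.processing` | alignment, stop truncation, SDFs, binned rates, saccade detection |
| `spikeramp.bursts` | ISI burst labeling and mode splitting |
| `spikeramp.stats` | regressions, slope comparison, bootstrap, logistic fit, classification |
| `spikeramp.io` / `spikeramp.study` / `spikeramp.cli` | CSV interchange, study orchestration, CLI |

## Command line

```bash
spikeramp write-config --out study.yaml        # default configuration
spikeramp generate --config study.yaml --seed 1 --out session/
spikeramp analyze  --config study.yaml --session-dir session/ --out analysis/
spikeramp run      --config study.yaml --seed 1 --out study_out/
```

`run` executes generate → analyze → bootstrap → report and writes the
session CSVs, a per-neuron summary table, cross-neuron correlation and
bootstrap tables, figures, and a markdown report. Outputs are deterministic
in the configured master seed (per-stage seeds are derived from it).

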