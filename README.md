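# swdkit

Detection of seizure-like **spike-and-wave discharges (SWDs)** in rodent
EEG, with a seeded synthetic-EEG benchmark for validating the detector by
parameter recovery, plus a small set of behavioral/metabolic assay
metrics (pre-pulse inhibition, resting metabolic rate, hole-board
repetition, footslip normalization, 120-s synaptic charge).

It is written for electrophysiologists who record chronic video-EEG in
mouse models of neurodevelopmental disease (e.g. *Mecp2* mutants, where
focal SWDs occur at a few episodes per hour with ~4 s duration) and want
a transparent, reproducible first-pass screen that turns hours of signal
into a short ranked list of seizure candidates for visual review.

## The detection algorithm

Each channel is divided into 10-minute segments and bandpass filtered
with a 3rd-order Butterworth (0.5–400 Hz cutoffs, zero-phase by
default). The filtered signal is cut into 500-ms non-overlapping epochs
and four features are computed per epoch:

| feature | definition | what it captures |
|---|---|---|
| `amp_corr` | Pearson correlation between epoch *i* and *i*+1 | rhythmicity: a 6 Hz spike-wave pattern repeats almost identically across consecutive 500-ms windows |
| `rms` | √mean(x²) of the epoch (µV) | amplitude surge during a discharge |
| `spike_density` | sharp extrema > 5 robust SD of the segment, 30 ms refractory, per second | the spike component |
| `band_ratio` | spectral power in 20–50 Hz / power in 0.5–20 Hz | harmonics of the spike train in the upper band |

An epoch is flagged when it exceeds the threshold for **all four**
features. Thresholds default to robust z-scores estimated per recording,

> threshold = median + z · 1.4826 · MAD  (z = 3; `amp_corr` uses an
> absolute threshold of 0.5),

so per-animal baseline differences are absorbed and the statistics are
not contaminated by the seizures themselves. Runs of flagged epochs
(bridging single-epoch gaps, minimum 1 s) become seizure candidates,
reported with per-feature peak values for audit, episode statistics
(episodes/hour, mean ± SEM duration), and — when ground truth is
available — sensitivity, false-discovery rate and timing errors under
one-to-one interval matching.

The synthetic benchmark generates background cortical EEG as colored
Gaussian noise with the aperiodic spectrum S(f) = 1/(1+(f/f_knee)^α)
(α = 2, knee 1 Hz, 50 µV RMS) and injects SWDs — a 6 Hz slow wave
carrying one sharp biphasic spike per cycle — at Poisson times
(3.3 episodes/hour) with truncated-normal durations (4.1 ± 0.4 s,
minimum 2 s) at 4× the background RMS. Every stage is seeded and
bit-reproducible.

## Worked example

```python
from swdkit import SimConfig, SWDDetector, simulate_recording

config = SimConfig(duration=900.0, seed=101, n_events=4)
recording, truth = simulate_recording(config)   # 15 min, 4 known SWDs

results = SWDDetector(recording).fit()
print(results.summary())

acc = results.evaluate(truth)
print(f"sensitivity: {acc.sensitivity:.2f}   FDR: {acc.false_discovery_rate:.2f}")
```

prints

```
Spike-and-wave discharge detection
==================================================
Recording: 1 channel(s), 900.0 s at 2000 Hz
Config hash: d51cf56fa40f

Per-channel thresholds (epoch flagged iff all exceeded):
  ch0: amp_corr=0.5, rms=70.39, spike_density=0, band_ratio=0.218

Candidates: 4
Episode rate: 16.00 /h over 0.25 channel-hours
Mean duration: 4.00 s (SEM 0.35 s)

sensitivity: 1.00   FDR: 0.00
```

All four injected discharges are recovered with no false positives; the
thresholds shown were estimated from this recording's own epoch-feature
distributions. `results.candidates_frame` gives the candidate table,
`results.features` the per-epoch audit table, and `results.plot()` a
quick-look trace with candidates shaded.

The same pipeline is available from the shell:

```bash
swdkit simulate --duration 900 --seed 101 --out rec.edf --truth truth.csv
swdkit detect --in rec.edf --out candidates.csv --features features.csv
swdkit evaluate --candidates candidates.csv --truth truth.csv
swdkit stats --candidates candidates.csv --hours 0.25
swdkit behavior ppi --in startle_session.csv
```

Recordings are exchanged as 16-bit EDF, events as plain CSV
(`channel,start_s,end_s,label`).

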